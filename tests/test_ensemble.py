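import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmdselect.ensemble import (
    PairwiseMatrix,
    average_contact_map,
    cluster_neighbors,
    cluster_stats,
    contact_map,
    pairwise_rmsd,
    superpose,
    tm_d0,
    tm_score,
)
from tmdselect.structure import slice_ensemble
from tmdselect.synth import BundleSpec, make_bundle, make_helix

from conftest import toy_model


class TestSuperpose:
    def test_translation_gives_zero(self, rng):
        A = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(A, A + [5.0, 0.0, 0.0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_gives_zero(self, rng):
        A = rng.normal(size=(10, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        _, _, rmsd = superpose(A, A @ R90.T)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom(self, rng):
        A = rng.normal(scale=10.0, size=(10, 3))
        B = A.copy()
        B[0] += [1.0, 0.0, 0.0]
        _, _, rmsd = superpose(A, B)
        # optimal alignment does no worse than the identity transform and
        # cannot beat it by much for a single displaced atom in a spread set
        assert rmsd <= np.sqrt(1.0 / 10.0) + 1e-12
        assert rmsd == pytest.approx(np.sqrt(1.0 / 10.0), rel=0.15)

    def test_proper_rotation_and_transform_applies(self, rng):
        A = rng.normal(size=(7, 3))
        B = rng.normal(size=(7, 3))
        R, t, rmsd = superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        moved = B @ R.T + t
        direct = np.sqrt(np.mean(np.sum((A - moved) ** 2, axis=1)))
        assert direct == pytest.approx(rmsd, rel=1e-9)

    def test_mismatched_lengths(self, rng):
        with pytest.raises(ValueError, match="shape"):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestPairwiseRmsd:
    def test_duplicate_models_zero_matrix(self):
        m1 = make_bundle(BundleSpec(seed=4), "a")
        m2 = make_bundle(BundleSpec(seed=4), "b")
        ens = slice_ensemble([m1, m2], 1, 98)
        mat = pairwise_rmsd(ens)
        np.testing.assert_allclose(mat.d, 0.0, atol=1e-9)

    def test_matches_direct_superpose(self):
        models = [make_bundle(BundleSpec(seed=s), f"m{s}") for s in range(3)]
        ens = slice_ensemble(models, 1, 98)
        mat = pairwise_rmsd(ens)
        coords = ens.ca_matrix()
        for a, b in itertools.combinations(range(3), 2):
            assert mat.d[a, b] == pytest.approx(
                superpose(coords[a], coords[b])[2], rel=1e-9
            )
            assert mat.d[a, b] == mat.d[b, a]

    def test_order_invariance(self):
        models = [make_bundle(BundleSpec(seed=s), f"m{s}") for s in range(4)]
        m1 = pairwise_rmsd(slice_ensemble(models, 1, 98))
        m2 = pairwise_rmsd(slice_ensemble(models[::-1], 1, 98))
        perm = [m2.ids.index(i) for i in m1.ids]
        np.testing.assert_allclose(m1.d, m2.d[np.ix_(perm, perm)], atol=1e-9)


def _matrix_from_points(points):
    pts = np.asarray(points, float)
    d = np.abs(pts[:, None] - pts[None, :])
    return PairwiseMatrix([f"m{k}" for k in range(len(pts))], d)


class TestClusterNeighbors:
    def test_two_tight_groups(self):
        mat = _matrix_from_points([0.0, 0.5, 0.9, 20.0, 20.4])
        cs = cluster_neighbors(mat, threshold=3.0)
        assert sorted(len(c.members) for c in cs.clusters) == [2, 3]
        assert set(cs.largest.members) == {"m0", "m1", "m2"}

    def test_singleton(self):
        mat = PairwiseMatrix(["only"], np.zeros((1, 1)))
        cs = cluster_neighbors(mat, threshold=2.0)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].centroid == "only"

    def test_threshold_above_max_single_cluster(self):
        mat = _matrix_from_points([0.0, 3.0, 7.0, 11.0])
        cs = cluster_neighbors(mat, threshold=100.0)
        assert len(cs.clusters) == 1
        assert len(cs.clusters[0].members) == 4

    def test_partition_property_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            pts = rng.uniform(0, 30, size=n)
            mat = _matrix_from_points(pts)
            cs = cluster_neighbors(mat, threshold=float(rng.uniform(0.5, 10)))
            seen = [m for c in cs.clusters for m in c.members]
            assert sorted(seen) == sorted(mat.ids)
            for c in cs.clusters:
                assert c.centroid in c.members

    def test_score_tiebreak_deterministic(self):
        mat = _matrix_from_points([0.0, 1.0, 10.0, 11.0])  # two equal pairs
        scores = {"m0": -5.0, "m1": -1.0, "m2": -9.0, "m3": -2.0}
        cs = cluster_neighbors(mat, threshold=2.0, scores=scores)
        assert {c.centroid for c in cs.clusters} == {"m2", "m0"}


class TestClusterStats:
    def test_quadratic_mean_hand_value(self):
        # cluster of 3 models with pairwise RMSDs {3, 4, 5}
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        mat = PairwiseMatrix(["a", "b", "c"], d)
        cs = cluster_neighbors(mat, threshold=10.0)
        st = cluster_stats(mat, cs)
        assert st.qm_rmsd[0] == pytest.approx(np.sqrt((9 + 16 + 25) / 3))

    def test_pair_cluster_value(self):
        d = np.array([[0, 3.0], [3.0, 0]])
        mat = PairwiseMatrix(["a", "b"], d)
        cs = cluster_neighbors(mat, threshold=10.0)
        st = cluster_stats(mat, cs)
        assert st.qm_rmsd[0] == pytest.approx(3.0)

    def test_identical_cluster_zero(self):
        mat = PairwiseMatrix(["a", "b"], np.zeros((2, 2)))
        st = cluster_stats(mat, cluster_neighbors(mat, threshold=1.0))
        assert st.qm_rmsd[0] == 0.0

    def test_singleton_flag_and_centroid_distance(self):
        mat = _matrix_from_points([0.0, 5.0])
        cs = cluster_neighbors(mat, threshold=1.0)
        st = cluster_stats(mat, cs)
        assert st.singleton == [True, True]
        assert st.qm_rmsd == [0.0, 0.0]
        assert list(st.centroid_rmsds.values()) == [5.0]


def _tm_bruteforce(A, B, d0, max_iter=30):
    """Independent oracle: seed from every contiguous fragment (len >= 4)."""
    L = A.shape[0]

    def score_at(Bt):
        d = np.linalg.norm(A - Bt, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    best = 0.0
    for length in range(4, L + 1):
        for start in range(0, L - length + 1):
            idx = np.arange(start, start + length)
            prev = None
            for _ in range(max_iter):
                R, t, _ = superpose(A[idx], B[idx])
                Bt = B @ R.T + t
                best = max(best, score_at(Bt))
                d = np.linalg.norm(A - Bt, axis=1)
                sel = np.where(d < max(d0, 0.5))[0]
                if sel.size < 3:
                    sel = np.argsort(d, kind="stable")[:4]
                cur = frozenset(sel.tolist())
                if cur == prev:
                    break
                prev = cur
                idx = np.sort(sel)
    return best


class TestTmScore:
    def test_self_is_one(self):
        m = make_bundle(BundleSpec(seed=5), "m")
        assert tm_score(m, m) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_displacement_at_fixed_superposition(self):
        L = 30
        d0 = tm_d0(L)
        A = np.random.default_rng(0).normal(scale=8.0, size=(L, 3))
        B = A + np.array([d0, 0.0, 0.0])  # every d_i == d0
        assert tm_score(B, A, superposition=False) == pytest.approx(0.5, abs=1e-12)

    def test_short_chain_rejected(self):
        A = np.random.default_rng(0).normal(size=(18, 3))
        with pytest.raises(ValueError, match="d0"):
            tm_score(A, A)

    def test_bounds(self, rng):
        for seed in range(3):
            a = make_bundle(BundleSpec(seed=seed), "a")
            b = make_bundle(BundleSpec(seed=seed + 10), "b")
            v = tm_score(a, b)
            assert 0.0 < v <= 1.0

    def test_matches_exhaustive_seed_bruteforce(self, rng):
        L = 30
        d0 = tm_d0(L)
        ca, _ = make_helix(L)
        A = ca + rng.normal(scale=1.0, size=(L, 3))
        B = ca[::-1] * [1.0, 1.0, -1.0] + rng.normal(scale=1.5, size=(L, 3))
        mine = tm_score(B, A)
        oracle = _tm_bruteforce(A, B, d0)
        assert mine == pytest.approx(oracle, abs=0.01)


class TestContactMap:
    def test_distance_boundary(self):
        near = toy_model([[0, 0, 0], [7.9, 0, 0]])
        far = toy_model([[0, 0, 0], [8.1, 0, 0]])
        assert contact_map(near, min_sep=1).values[0, 1] == 1.0
        assert contact_map(far, min_sep=1).values[0, 1] == 0.0

    def test_straight_helix_band_structure(self):
        ca, cb = make_helix(30)
        m = toy_model(ca, cb=list(cb))
        short = contact_map(m, min_sep=1)
        assert short.values.sum() > 0  # near-diagonal band exists
        empty = contact_map(m, min_sep=12)
        assert empty.values.sum() == 0  # helix has no long-range contacts

    def test_rigid_invariance_and_symmetry(self, rng):
        m = make_bundle(BundleSpec(seed=6), "m")
        base = contact_map(m, min_sep=5)
        R = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
        moved = toy_model(
            m.representative_coords() @ R.T + [3.0, 4.0, 5.0]
        )
        np.testing.assert_array_equal(
            contact_map(moved, min_sep=5).values, base.values
        )
        np.testing.assert_array_equal(base.values, base.values.T)


class TestAverageContactMap:
    def test_single_model_equals_binary(self):
        m = make_bundle(BundleSpec(seed=1), "m")
        np.testing.assert_array_equal(
            average_contact_map([m], min_sep=5).values,
            contact_map(m, min_sep=5).values,
        )

    def test_half_frequency_cell(self):
        a = toy_model([[0, 0, 0], [6.0, 0, 0], [50, 0, 0]])
        b = toy_model([[0, 0, 0], [20.0, 0, 0], [50, 0, 0]])
        avg = average_contact_map([a, b], min_sep=1)
        assert avg.values[0, 1] == 0.5

    def test_frequencies_match_recount(self):
        models = [make_bundle(BundleSpec(seed=s), f"m{s}") for s in range(4)]
        avg = average_contact_map(models, min_sep=5)
        recount = sum(contact_map(m, min_sep=5).values for m in models) / 4
        np.testing.assert_allclose(avg.values, recount)
        assert avg.values.min() >= 0 and avg.values.max() <= 1

    def test_length_mismatch_rejected(self):
        a = toy_model(np.zeros((3, 3)) + np.arange(3)[:, None])
        b = toy_model(np.zeros((4, 3)) + np.arange(4)[:, None])
        with pytest.raises(ValueError, match="length"):
            average_contact_map([a, b])
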