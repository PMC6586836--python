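import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmdselect.contacts import (
    ContactList,
    ContactPrediction,
    ScoreTable,
    contact_term,
    read_contacts,
    score_ensemble,
    score_model,
    write_contacts,
    zscore_filter,
)
from tmdselect.synth import (
    BundleSpec,
    EnsembleSpec,
    contacts_from_structure,
    make_bundle,
    make_ensemble,
    template_spec,
)

from conftest import toy_model


class TestContactTerm:
    @pytest.mark.parametrize(
        "c,r,expected",
        [
            (1.0, 8.0, -0.5),  # sigmoid midpoint
            (0.5, 8.0, -0.25),  # linear in confidence
            (1.0, 8.0 + math.log(3.0) / 3.0, -0.25),  # exp term = 1/3
        ],
    )
    def test_hand_values(self, c, r, expected):
        assert contact_term(c, r) == pytest.approx(expected, abs=1e-12)

    def test_saturation(self):
        assert contact_term(1.0, 30.0) == pytest.approx(0.0, abs=1e-9)
        assert contact_term(1.0, 0.0) == pytest.approx(-1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(
        c=st.floats(0.01, 1.0),
        r1=st.floats(0.0, 40.0),
        r2=st.floats(0.0, 40.0),
    )
    def test_monotone_in_distance_linear_in_confidence(self, c, r1, r2):
        lo, hi = sorted((r1, r2))
        assert contact_term(c, lo) <= contact_term(c, hi)
        assert contact_term(c, r1) == pytest.approx(
            c * contact_term(1.0, r1), rel=1e-12
        )


class TestReadContacts:
    def test_threshold_and_columns(self, tmp_path):
        p = tmp_path / "c.rr"
        p.write_text(
            "# comment\n"
            "1 10 0 8 0.9\n"
            "2 11 0.5\n"
            "3 40 0 8 0.05\n"
            "4 30 0.2\n"
            "5 50 0.3\n"
        )
        cl = read_contacts(p, min_confidence=0.1)
        assert len(cl) == 4
        assert all(ct.c >= 0.1 for ct in cl)

    def test_duplicates_keep_max_and_normalize(self, tmp_path):
        p = tmp_path / "d.rr"
        p.write_text("3 40 0.2\n40 3 0.8\n")
        cl = read_contacts(p)
        assert len(cl) == 1
        ct = cl.contacts[0]
        assert (ct.i, ct.j, ct.c) == (3, 40, 0.8)

    def test_self_contact_rejected(self, tmp_path):
        p = tmp_path / "s.rr"
        p.write_text("7 7 0.5\n")
        with pytest.raises(ValueError, match="self-contact"):
            read_contacts(p)

    def test_bad_confidence_reports_line(self, tmp_path):
        p = tmp_path / "b.rr"
        p.write_text("1 10 0.5\n2 11 zebra\n")
        with pytest.raises(ValueError, match="line 2"):
            read_contacts(p)

    def test_roundtrip(self, tmp_path):
        ref = make_bundle(template_spec(BundleSpec(seed=0)), "ref")
        cl = contacts_from_structure(ref, seed=0)
        p = tmp_path / "rt.rr"
        write_contacts(cl, p)
        back = read_contacts(p, min_confidence=0.1)
        assert len(back) == len(cl)
        for a, b in zip(cl, back):
            assert (a.i, a.j) == (b.i, b.j)
            assert a.c == pytest.approx(b.c, abs=1e-6)


class TestScoreModel:
    def test_fully_satisfied_limit(self):
        # all predicted pairs far closer than the sigmoid center
        coords = np.random.default_rng(1).normal(scale=1.0, size=(8, 3))
        m = toy_model(coords)
        cl = ContactList([ContactPrediction(1, 6, 0.8), ContactPrediction(2, 8, 0.4)])
        assert score_model(m, cl) == pytest.approx(-cl.total_confidence, abs=1e-5)

    def test_unsatisfied_limit(self):
        coords = np.arange(8)[:, None] * [30.0, 0.0, 0.0]
        m = toy_model(coords)
        cl = ContactList([ContactPrediction(1, 6, 0.8), ContactPrediction(2, 8, 0.4)])
        assert score_model(m, cl) == pytest.approx(0.0, abs=1e-6)

    def test_three_contact_toy_equals_hand_sum(self):
        coords = np.array(
            [[0, 0, 0], [8, 0, 0], [0, 7, 0], [10, 10, 0], [0, 0, 9]], float
        )
        m = toy_model(coords)
        cl = ContactList(
            [
                ContactPrediction(1, 2, 0.9),
                ContactPrediction(1, 3, 0.5),
                ContactPrediction(1, 5, 0.2),
            ]
        )
        expected = sum(
            c * (1.0 / (1.0 + math.exp(-3.0 * (r - 8.0))) - 1.0)
            for c, r in [(0.9, 8.0), (0.5, 7.0), (0.2, 9.0)]
        )
        assert score_model(m, cl) == pytest.approx(expected, rel=1e-12)

    def test_contact_order_and_rigid_invariance(self, rng):
        m = toy_model(rng.normal(scale=5.0, size=(12, 3)))
        preds = [
            ContactPrediction(1, 7, 0.9),
            ContactPrediction(2, 9, 0.3),
            ContactPrediction(4, 12, 0.6),
        ]
        s1 = score_model(m, ContactList(preds))
        s2 = score_model(m, ContactList(preds[::-1]))
        assert s1 == pytest.approx(s2, rel=1e-12)
        # rigid-body transform
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = toy_model(m.ca_coords() @ R.T + np.array([5.0, -3.0, 11.0]))
        assert score_model(moved, ContactList(preds)) == pytest.approx(s1, rel=1e-9)

    def test_missing_residue_listed(self):
        m = toy_model(np.zeros((3, 3)) + np.arange(3)[:, None])
        cl = ContactList([ContactPrediction(1, 99, 0.5)])
        with pytest.raises(KeyError, match="99"):
            score_model(m, cl)


class TestScoreEnsemble:
    def test_two_models_give_unit_z(self, rng):
        near = toy_model(rng.normal(scale=1.0, size=(8, 3)), "near")
        far = toy_model(np.arange(8)[:, None] * [30.0, 0.0, 0.0], "far")
        cl = ContactList([ContactPrediction(1, 6, 1.0), ContactPrediction(2, 8, 1.0)])
        table = score_ensemble([near, far], cl)
        # population z of two distinct values is always ±1
        assert sorted(np.round(table.z, 12)) == [-1.0, 1.0]
        assert table.z[table.model_ids.index("near")] == -1.0

    def test_degenerate_ensemble_rejected(self):
        m = toy_model(np.arange(8)[:, None] * [3.0, 0.0, 0.0])
        cl = ContactList([ContactPrediction(1, 6, 0.5)])
        with pytest.raises(ValueError, match="degenerate"):
            score_ensemble([m, m], cl)

    def test_z_is_standardized(self):
        ens, _ = make_ensemble(EnsembleSpec(counts={"left": 20, "right": 10}, seed=0))
        ref = make_bundle(template_spec(BundleSpec(seed=0)), "ref")
        cl = contacts_from_structure(ref, seed=0)
        table = score_ensemble(ens, cl)
        assert abs(table.z.mean()) < 1e-9
        assert table.z.std() == pytest.approx(1.0, abs=1e-9)
        assert (table.contact_scores <= 0).all()

    def test_matched_topology_scores_better(self):
        spec = EnsembleSpec(counts={"left": 30, "right": 30}, seed=2)
        ens, labels = make_ensemble(spec)
        ref = make_bundle(template_spec(spec.class_specs["left"]), "ref")
        cl = contacts_from_structure(ref, seed=2)
        table = score_ensemble(ens, cl)
        lab = np.array(labels)
        assert (
            table.contact_scores[lab == "left"].mean()
            < table.contact_scores[lab == "right"].mean()
        )


class TestZscoreFilter:
    def test_boundary_inclusive(self):
        table = ScoreTable(["a", "b", "c"], np.array([-30.0, -20.0, -5.0]),
                           np.array([-2.5, -2.0, 0.1]))
        assert zscore_filter(table, -2.0) == ["a", "b"]

    def test_minus_infinity_empty(self):
        table = ScoreTable(["a", "b"], np.array([-1.0, -2.0]),
                           np.array([1.0, -1.0]))
        assert zscore_filter(table, -np.inf) == []

    def test_normal_tail_fraction(self, rng):
        z = rng.standard_normal(10_000)
        z = (z - z.mean()) / z.std()
        table = ScoreTable([f"m{k}" for k in range(z.size)], -z, z)
        frac = len(zscore_filter(table, -2.0)) / z.size
        assert frac == pytest.approx(0.0228, abs=0.005)
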