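"""Decoy-ensemble geometry: superposition, pairwise RMSD, clustering,
TM-score and contact maps.

Clustering follows the greedy largest-neighborhood rule (the core of the
Calibur decoy-clustering tool): the model with the most neighbors within a
distance threshold seeds a cluster containing those neighbors, the cluster is
removed, and the rule repeats until the pool is empty.  Cluster precision is
summarized by the quadratic mean of the intra-cluster pairwise RMSD,
<RMSD²>^1/2, and by Cα RMSD distances between cluster centroids.

The TM-score is the standard length-normalized structural similarity in
(0, 1]: TM = max over superpositions of (1/L)·Σ 1/(1+(d_i/d0)²) with
d0 = 1.24·(L−15)^(1/3) − 1.8.  Scores above 0.5 indicate the same fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import EnsembleIndex, StructureModel

__all__ = [
    "PairwiseMatrix",
    "ClusterSet",
    "Cluster",
    "ClusterStats",
    "ContactMap",
    "superpose",
    "pairwise_rmsd",
    "cluster_neighbors",
    "cluster_stats",
    "tm_score",
    "tm_d0",
    "contact_map",
    "average_contact_map",
]


# ---------------------------------------------------------------------------
# Superposition and pairwise RMSD
# ---------------------------------------------------------------------------

def superpose(A: np.ndarray, B: np.ndarray):
    """Least-squares superposition of B onto A (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``B @ rotation.T + translation`` best matches ``A``; the rotation is
    proper (det = +1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, rssd = Rotation.align_vectors(A - ca, B - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd = float(rssd) / np.sqrt(A.shape[0])
    return R, t, rmsd


def _rmsd_only(A: np.ndarray, B: np.ndarray) -> float:
    return superpose(A, B)[2]


@dataclass
class PairwiseMatrix:
    ids: list[str]
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.4f")

    def submatrix(self, ids: Sequence[str]) -> "PairwiseMatrix":
        pos = [self.ids.index(i) for i in ids]
        return PairwiseMatrix(list(ids), self.d[np.ix_(pos, pos)])


def pairwise_rmsd(ensemble: EnsembleIndex) -> PairwiseMatrix:
    """All-vs-all superposed Cα RMSD over the ensemble's residue range."""
    coords = ensemble.ca_matrix()
    n = coords.shape[0]
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 models")
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = _rmsd_only(coords[a], coords[b])
    return PairwiseMatrix(ensemble.model_ids, d)


# ---------------------------------------------------------------------------
# Greedy largest-neighborhood clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: list[str]
    centroid: str


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    unassigned: list[str] = field(default_factory=list)

    @property
    def largest(self) -> Cluster:
        return self.clusters[0]

    def membership(self) -> dict[str, int]:
        return {
            mid: rank
            for rank, cl in enumerate(self.clusters, start=1)
            for mid in cl.members
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": mid,
                "cluster_rank": rank,
                "is_centroid": mid == cl.centroid,
            }
            for rank, cl in enumerate(self.clusters, start=1)
            for mid in cl.members
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_cluster_threshold(matrix: PairwiseMatrix) -> float:
    """Quarter of the ensemble's pairwise-RMSD range (documented example
    regime: a decoy pool spanning 1.1–22 Å)."""
    off = matrix.d[~np.eye(len(matrix.ids), dtype=bool)]
    return float((off.max() - off.min()) / 4.0) if off.size else 1.0


def cluster_neighbors(
    matrix: PairwiseMatrix,
    threshold: float | None = None,
    scores: dict[str, float] | None = None,
) -> ClusterSet:
    """Iterative greedy clustering on a pairwise RMSD matrix.

    At each round the model with the most neighbors within ``threshold``
    becomes the centroid of a cluster containing itself and those neighbors;
    the cluster is removed and the rule repeats.  Ties in neighbor count are
    broken by lower Contact score when ``scores`` is supplied, else by
    lexicographically lowest model id.  Clusters are ordered by decreasing
    size (same tie-break).
    """
    if threshold is None:
        threshold = default_cluster_threshold(matrix)
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    ids = list(matrix.ids)
    d = matrix.d
    alive = list(range(len(ids)))
    clusters: list[Cluster] = []

    def tiebreak(k: int):
        return (scores[ids[k]], ids[k]) if scores is not None else (ids[k],)

    while alive:
        counts = {
            k: sum(1 for m in alive if m != k and d[k, m] <= threshold) for k in alive
        }
        best = min(alive, key=lambda k: (-counts[k],) + tiebreak(k))
        members = [best] + [m for m in alive if m != best and d[best, m] <= threshold]
        clusters.append(Cluster([ids[m] for m in members], ids[best]))
        alive = [m for m in alive if m not in members]

    clusters.sort(key=lambda cl: (-len(cl.members), cl.centroid))
    return ClusterSet(clusters, threshold=float(threshold))


@dataclass
class ClusterStats:
    qm_rmsd: list[float]  # quadratic-mean pairwise RMSD per cluster
    singleton: list[bool]
    centroid_rmsds: dict[tuple[int, int], float]  # (rank_a, rank_b) -> Å


def cluster_stats(matrix: PairwiseMatrix, clusters: ClusterSet) -> ClusterStats:
    """Quadratic-mean intra-cluster RMSD and centroid-centroid distances.

    Singleton clusters report qm_rmsd = 0 and are flagged.
    """
    qm, single = [], []
    for cl in clusters.clusters:
        sub = matrix.submatrix(cl.members).d
        n = sub.shape[0]
        if n < 2:
            qm.append(0.0)
            single.append(True)
            continue
        pair = sub[np.triu_indices(n, k=1)]
        qm.append(float(np.sqrt(np.mean(pair**2))))
        single.append(False)
    cen = {}
    for a in range(len(clusters.clusters)):
        for b in range(a + 1, len(clusters.clusters)):
            ia = matrix.ids.index(clusters.clusters[a].centroid)
            ib = matrix.ids.index(clusters.clusters[b].centroid)
            cen[(a + 1, b + 1)] = float(matrix.d[ia, ib])
    return ClusterStats(qm, single, cen)


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(L: int) -> float:
    """Length-dependent normalization distance of the TM-score."""
    return 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8


def _tm_at(A: np.ndarray, B: np.ndarray, d0: float) -> float:
    d = np.linalg.norm(A - B, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def _superpose_apply(A: np.ndarray, B: np.ndarray, idx: np.ndarray) -> np.ndarray:
    R, t, _ = superpose(A[idx], B[idx])
    return B @ R.T + t


def _refine(A: np.ndarray, B: np.ndarray, seed_idx: np.ndarray, d0: float,
            max_iter: int = 30) -> float:
    """Iterative subset superposition from one seed; returns best TM seen."""
    L = A.shape[0]
    idx = seed_idx
    best = 0.0
    prev: set[int] | None = None
    for _ in range(max_iter):
        Bt = _superpose_apply(A, B, idx)
        best = max(best, _tm_at(A, Bt, d0))
        d = np.linalg.norm(A - Bt, axis=1)
        sel = np.where(d < max(d0, 0.5))[0]
        if sel.size < 3:  # fall back to the closest residues, deterministically
            sel = np.argsort(d, kind="stable")[:4]
        cur = set(sel.tolist())
        if prev is not None and cur == prev:
            break
        prev = cur
        idx = np.sort(sel)
    return best

def tm_score(
    model: StructureModel | np.ndarray,
    reference: StructureModel | np.ndarray,
    superposition: bool = True,
) -> float:
    """TM-score of ``model`` against ``reference`` (equal-length Cα traces).

    The score is maximized over superpositions seeded from contiguous
    fragments (full length, halves, quarters, down to 4 residues) followed by
    iterative re-superposition on the well-fitting residue subset.  With
    ``superposition=False`` the score is evaluated at the coordinates as
    given (no fitting) — the raw Σ 1/(1+(d_i/d0)²)/L.
    """
    A = reference.ca_coords() if isinstance(reference, StructureModel) else np.asarray(reference, float)
    B = model.ca_coords() if isinstance(model, StructureModel) else np.asarray(model, float)
    if A.shape != B.shape:
        raise ValueError("model and reference must have equal-length Cα traces")
    L = A.shape[0]
    d0 = tm_d0(L)
    if d0 <= 0:
        raise ValueError(f"chain of length {L} is below the TM-score d0 validity range")
    if not superposition:
        return _tm_at(A, B, d0)
    best = 0.0
    for frag in {L, max(L // 2, 4), max(L // 4, 4), 4}:
        starts = range(0, L - frag + 1, max(1, frag // 2))
        for s in starts:
            seed = np.arange(s, s + frag)
            best = max(best, _refine(A, B, seed, d0))
    return best


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    n: int
    cutoff: float
    min_sep: int
    values: np.ndarray

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, sep="\t", float_format="%.4f")


def contact_map(
    model: StructureModel, cutoff: float = 8.0, min_sep: int = 1
) -> ContactMap:
    """Binary representative-atom (Cβ/Cα) contact map at ``cutoff`` Å.

    A pair (i, j) is a contact when its representative-atom distance is
    ≤ cutoff and the sequence separation |i−j| ≥ min_sep, using positions
    within the model's residue ordering.
    """
    xyz = model.representative_coords()
    n = xyz.shape[0]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    values = ((d <= cutoff) & (sep >= min_sep)).astype(float)
    return ContactMap(n=n, cutoff=cutoff, min_sep=min_sep, values=values)


def average_contact_map(
    models: Sequence[StructureModel], cutoff: float = 8.0, min_sep: int = 1
) -> ContactMap:
    """Element-wise mean of the binary contact maps of a cluster's decoys."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    maps = [contact_map(m, cutoff=cutoff, min_sep=min_sep) for m in models]
    if len({m.n for m in maps}) != 1:
        raise ValueError("models differ in length; cannot average contact maps")
    values = np.mean([m.values for m in maps], axis=0)
    return ContactMap(n=maps[0].n, cutoff=cutoff, min_sep=min_sep, values=values)
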