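"""Synthetic inputs: helical-bundle decoy ensembles with known topology
labels, matched contact predictions, and calibration/titration series.

The decoy generator emulates the situation faced when selecting among
ab initio models of a three-helix transmembrane bundle: the sampled pool
contains both left- and right-handed packing arrangements of the same
sequence, distinguishable by their inter-helix residue-residue contact
pattern but not by any single-model energy.  Decoys of one topology class
share an ideal-geometry template (helices on a triangular cross-section,
tilted by a crossing angle whose tangential sense encodes the handedness,
antiparallel connectivity through short loop stubs) and differ by
per-decoy helix-placement jitter (phase, tilt, axial shift, axis offset)
plus per-atom Gaussian noise — reproducing the few-Å within-class pairwise
RMSD spread typical of clustered decoy pools, against a much larger
between-class separation.

Topology labels are returned alongside the ensemble for use by test oracles
only; no pipeline stage accepts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .contacts import ContactList, ContactPrediction
from .copper import (
    TitrationSeries,
    _hill_model,
    solve_competition_equilibrium,
)
from .structure import EnsembleIndex, ResidueRecord, StructureModel

__all__ = [
    "BundleSpec",
    "EnsembleSpec",
    "TitrationSpec",
    "make_helix",
    "make_bundle",
    "template_spec",
    "make_ensemble",
    "contacts_from_structure",
    "make_titration",
    "make_calibration_standards",
    "DEFAULT_SEQUENCE",
]

# Ideal α-helix geometry
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue (3.6 residues/turn)
HELIX_RADIUS = 2.3  # Å, Cα distance from the helix axis
CB_OFFSET = 1.5  # Å, radial Cβ offset from Cα

_HELIX_PATTERN = "LAIVFGMLSAWLIVTALFMC"
_LOOP_PATTERN = "GSGSGS"


def _default_sequence(n_helices: int, helix_len: int, loop_len: int) -> str:
    seq = []
    for h in range(n_helices):
        seq.append(
            (_HELIX_PATTERN * (helix_len // len(_HELIX_PATTERN) + 1))[:helix_len]
        )
        if h < n_helices - 1:
            seq.append((_LOOP_PATTERN * (loop_len // len(_LOOP_PATTERN) + 1))[:loop_len])
    return "".join(seq)


DEFAULT_SEQUENCE = _default_sequence(3, 30, 4)


def make_helix(
    n_res: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cα and Cβ traces of an ideal α-helix along +z.

    Returns ``(ca, cb)`` arrays of shape (n_res, 3); Cβ sits at a fixed
    radial offset outward from the axis.  ``phase`` (degrees) rotates the
    helix about its own axis, controlling which face points outward.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    k = np.arange(n_res)
    ang = np.deg2rad(twist * k + phase)
    ca = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * k])
    radial = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n_res)])
    cb = ca + CB_OFFSET * radial
    return ca, cb


@dataclass
class BundleSpec:
    """Geometry of one topology class of three-helix-bundle decoys."""

    n_helices: int = 3
    helix_len: int = 30
    loop_len: int = 4
    handedness: str = "left"  # left | right — tangential sense of the tilt
    crossing_angle_deg: float = 18.0
    axis_distance: float = 10.2  # Å between neighboring helix axes
    noise_sigma: float = 0.8  # Å per-atom Gaussian noise
    # per-decoy placement heterogeneity, calibrated to the dispersion of an
    # ab initio decoy pool: helix rotational phase largely unresolved,
    # several degrees of tilt spread, Å-scale register and axis offsets.
    phase_jitter_deg: float = 120.0
    tilt_jitter_deg: float = 8.0
    azimuth_jitter_deg: float = 4.0
    offset_jitter: float = 1.5  # Å, radial axis-position jitter
    z_jitter: float = 2.5  # Å, axial register jitter
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.axis_distance < 2 * HELIX_RADIUS:
            raise ValueError("inter-axis distance would clash helices")
        if self.sequence is None:
            self.sequence = _default_sequence(
                self.n_helices, self.helix_len, self.loop_len
            )

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.helix_len + (self.n_helices - 1) * self.loop_len


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to ``axis`` (unit), about their common normal."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(z @ axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def make_bundle(spec: BundleSpec, model_id: str = "bundle") -> StructureModel:
    """One decoy built from ``spec`` (deterministic given ``spec.seed``).

    Helix axes sit on a regular polygon cross-section and are tilted by the
    crossing angle in the tangential direction, with the sign of that sense
    set by the handedness; consecutive helices run antiparallel and are
    joined by straight loop stubs.  Per-decoy jitter and per-atom Gaussian
    noise are then applied.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_helices
    ring_r = spec.axis_distance / (2.0 * np.sin(np.pi / n))
    sign = +1.0 if spec.handedness == "left" else -1.0
    height = (spec.helix_len - 1) * HELIX_RISE

    ca_all: list[np.ndarray] = []
    cb_all: list[np.ndarray | None] = []
    aa_all: list[str] = []
    seq = spec.sequence
    pos = 0
    prev_end: np.ndarray | None = None
    pending_loop: list[str] = []

    for h in range(n):
        psi = 2.0 * np.pi * h / n + rng.normal(
            0.0, np.deg2rad(spec.azimuth_jitter_deg)
        )
        center = np.array([ring_r * np.cos(psi), ring_r * np.sin(psi), 0.0])
        center[:2] += rng.normal(0.0, spec.offset_jitter, size=2)
        tangent = np.array([-np.sin(psi), np.cos(psi), 0.0])
        tilt = np.deg2rad(
            spec.crossing_angle_deg + rng.normal(0.0, spec.tilt_jitter_deg)
        )
        axis = np.cos(tilt) * np.array([0.0, 0.0, 1.0]) + sign * np.sin(tilt) * tangent
        up = h % 2 == 0  # antiparallel connectivity
        phase = rng.uniform(-spec.phase_jitter_deg, spec.phase_jitter_deg)
        ca, cb = make_helix(spec.helix_len, phase=phase)
        ca[:, 2] -= height / 2.0
        cb[:, 2] -= height / 2.0
        if not up:
            flip = np.diag([1.0, -1.0, -1.0])  # proper rotation, reverses z
            ca = ca @ flip.T
            cb = cb @ flip.T
        R = _rotation_from_z(axis if up else -axis)
        zshift = rng.normal(0.0, spec.z_jitter)
        ca = ca @ R.T + center + np.array([0.0, 0.0, zshift])
        cb = cb @ R.T + center + np.array([0.0, 0.0, zshift])

        helix_seq = seq[pos : pos + spec.helix_len]
        pos += spec.helix_len
        if prev_end is not None:
            # straight loop stub from the previous helix end to this start
            lp = len(pending_loop)
            for t in range(lp):
                f = (t + 1) / (lp + 1)
                point = prev_end * (1 - f) + ca[0] * f
                ca_all.append(point)
                cb_all.append(None if pending_loop[t] == "G" else point + np.array([0.9, 0.9, 0.0]))
                aa_all.append(pending_loop[t])
        for k in range(spec.helix_len):
            ca_all.append(ca[k])
            cb_all.append(None if helix_seq[k] == "G" else cb[k])
            aa_all.append(helix_seq[k])
        if h < n - 1:
            pending_loop = list(seq[pos : pos + spec.loop_len])
            pos += spec.loop_len
            prev_end = ca[-1]

    residues = []
    for idx, (ca_i, cb_i, aa) in enumerate(zip(ca_all, cb_all, aa_all), start=1):
        ca_noisy = ca_i + rng.normal(0.0, spec.noise_sigma, size=3)
        cb_noisy = (
            None if cb_i is None else cb_i + rng.normal(0.0, spec.noise_sigma, size=3)
        )
        residues.append(ResidueRecord(index=idx, aa=aa, ca=ca_noisy, cb=cb_noisy))
    return StructureModel(model_id, residues, source="synthetic")


def template_spec(spec: BundleSpec) -> BundleSpec:
    """Jitter- and noise-free copy of a bundle spec — the ideal topology
    template of its class (used as the contact-prediction ground truth)."""
    return replace(
        spec,
        noise_sigma=0.0,
        phase_jitter_deg=0.0,
        tilt_jitter_deg=0.0,
        azimuth_jitter_deg=0.0,
        offset_jitter=0.0,
        z_jitter=0.0,
    )


@dataclass
class EnsembleSpec:
    """A labeled mixture of topology classes sharing one sequence."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"left": 120, "right": 80}
    )
    class_specs: dict[str, BundleSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) < 2:
            raise ValueError("ensemble needs at least 2 models")
        if self.class_specs is None:
            self.class_specs = {
                label: BundleSpec(handedness=label)
                for label in self.counts
                if self.counts[label] > 0
            }


def make_ensemble(spec: EnsembleSpec) -> tuple[EnsembleIndex, list[str]]:
    """Generate the labeled decoy mixture.

    Returns ``(ensemble, labels)``; labels align with ``ensemble.models`` and
    exist for oracle-based evaluation only — pipeline stages accept the
    :class:`EnsembleIndex` alone.
    """
    ss = np.random.SeedSequence(spec.seed)
    models: list[StructureModel] = []
    labels: list[str] = []
    order = [
        label for label, cnt in spec.counts.items() for _ in range(cnt)
    ]
    children = ss.spawn(len(order))
    # interleave classes deterministically so ids carry no class information
    perm = np.random.default_rng(ss.spawn(1)[0]).permutation(len(order))
    for k, pidx in enumerate(perm):
        label = order[pidx]
        bspec = replace(
            spec.class_specs[label],
            seed=int(children[pidx].generate_state(1)[0] % (2**31)),
        )
        models.append(make_bundle(bspec, model_id=f"decoy_{k:04d}"))
        labels.append(label)
    nres = models[0].residues[-1].index
    return EnsembleIndex(models, (1, nres)), labels


def contacts_from_structure(
    reference: StructureModel,
    cutoff: float = 8.0,
    min_sep: int = 5,
    false_positive_rate: float = 0.10,
    confidence_jitter: float = 0.08,
    seed: int = 0,
) -> ContactList:
    """Ground-truth-derived contact predictions with optional contamination.

    Every representative-atom pair within ``cutoff`` (and sequence
    separation ≥ ``min_sep``) becomes a contact; confidence decreases with
    distance (1 near zero distance, 0.1 at the cutoff) plus seeded jitter.
    A fraction ``false_positive_rate`` of the true count is added as random
    non-contact pairs with low confidence.
    """
    rng = np.random.default_rng(seed)
    xyz = reference.representative_coords()
    idx = reference.indices
    n = len(idx)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    contacts: dict[tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            if abs(idx[b] - idx[a]) < min_sep or d[a, b] > cutoff:
                continue
            c = 0.1 + 0.9 * (cutoff - d[a, b]) / cutoff
            c += rng.normal(0.0, confidence_jitter)
            contacts[(idx[a], idx[b])] = float(np.clip(c, 0.1, 1.0))
    n_fp = int(round(false_positive_rate * len(contacts)))
    candidates = [
        (idx[a], idx[b])
        for a in range(n)
        for b in range(a + 1, n)
        if abs(idx[b] - idx[a]) >= min_sep
        and d[a, b] > cutoff
        and (idx[a], idx[b]) not in contacts
    ]
    if n_fp and candidates:
        pick = rng.choice(len(candidates), size=min(n_fp, len(candidates)),
                          replace=False)
        for p in pick:
            contacts[candidates[p]] = float(rng.uniform(0.1, 0.4))
    preds = [ContactPrediction(i, j, c) for (i, j), c in sorted(contacts.items())]
    return ContactList(preds, min_confidence=0.1)


# ---------------------------------------------------------------------------
# Titrations and calibration standards
# ---------------------------------------------------------------------------

@dataclass
class TitrationSpec:
    """Generative settings for a protein-into-chelate titration.

    Defaults emulate the experimental regime: protein serially diluted over
    0.06–122 µM into a fixed BCA₂-Cu(I) pool (125 µM BCA, 50 µM Cu after
    mixing), with noise expressed as a fraction of the absorbance amplitude.
    """

    route: str = "hill"  # hill | equilibrium
    protein_grid_uM: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.06, 122.0, 12)
    )
    # Hill-route truth
    h: float = 1.0
    k_half_uM: float = 10.0
    a0: float = 0.40
    delta_a: float = 0.35
    # equilibrium-route truth
    kd_dimer_M2: float = 1.7e-30
    beta2: float = 2.0e17
    bca_total_uM: float = 125.0
    cu_total_uM: float = 50.0
    eps_per_uM: float = 0.008  # A562 per µM of BCA₂-Cu(I) (path folded in)
    noise_frac: float = 0.02  # Gaussian sigma as fraction of the amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.protein_grid_uM, dtype=float)
        if (grid <= 0).any():
            raise ValueError("protein grid must be strictly positive")
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be >= 0")
        self.protein_grid_uM = grid


def make_titration(spec: TitrationSpec) -> tuple[TitrationSeries, dict]:
    """Noisy titration generated from the chosen model; returns the series
    and the generating truth for oracle use."""
    rng = np.random.default_rng(spec.seed)
    p = spec.protein_grid_uM
    if spec.route == "hill":
        a_clean = _hill_model(p, spec.a0, spec.delta_a, spec.h, spec.k_half_uM)
        truth = {"h": spec.h, "k_half_uM": spec.k_half_uM, "a0": spec.a0,
                 "delta_a": spec.delta_a}
        amplitude = spec.delta_a
    elif spec.route == "equilibrium":
        a_clean = np.empty_like(p)
        for k, p_uM in enumerate(p):
            state = solve_competition_equilibrium(
                p_total=p_uM * 1e-6 / 2.0,  # dimer molarity
                cu_total=spec.cu_total_uM * 1e-6,
                bca_total=spec.bca_total_uM * 1e-6,
                kd_dimer=spec.kd_dimer_M2,
                beta2=spec.beta2,
            )
            a_clean[k] = spec.eps_per_uM * state.bca2cu * 1e6
        truth = {"kd_dimer_M2": spec.kd_dimer_M2, "beta2": spec.beta2}
        amplitude = float(a_clean.max() - a_clean.min())
    else:
        raise ValueError(f"unknown route {spec.route!r}")
    noise = rng.normal(0.0, spec.noise_frac * amplitude, size=p.shape)
    series = TitrationSeries(
        protein_uM=p,
        a562=a_clean + noise,
        bca_total_uM=spec.bca_total_uM,
        cu_total_uM=spec.cu_total_uM,
        tags={"route": spec.route, "seed": spec.seed},
    )
    return series, truth


def make_calibration_standards(
    concentrations_uM: Sequence[float] = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0),
    slope: float = 0.008,
    intercept: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """(concentration, A562) standards on a known line with optional noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_uM, dtype=float)
    a = slope * conc + intercept + rng.normal(0.0, noise_sigma, size=conc.shape)
    return np.column_stack([conc, a])
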