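"""Solvent accessibility, buried-residue selection and helicity calls.

Solvent-accessible surface area (SASA) is computed by Shrake–Rupley sphere
sampling: test points are distributed on each atom's solvent-expanded sphere
(van der Waals radius + probe radius) on a deterministic Fibonacci lattice,
and the accessible area is the sphere area times the fraction of points not
occluded by any neighboring atom's expanded sphere.  Relative SASA divides a
residue's absolute SASA by its maximum exposure in an extended Gly-X-Gly
reference tripeptide (theoretical maxima of Tien et al. 2013, PLOS ONE
8:e80635).

Buried-candidate selection for tryptophan scanning ranks residues by mean
relative SASA over a model ensemble; positions at or below a threshold are
proposed for mutation, the rationale being that a bulky tryptophan at a
buried (core or interface) position distorts the helix bundle, which is read
out as a drop in α-helical content by circular dichroism.
``classify_helicity`` applies that readout: mutants are called neutral,
partially disruptive or disruptive from the drop in helical fraction
relative to a tryptophan-free reference construct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import EnsembleIndex, StructureModel

__all__ = [
    "SasaProfile",
    "TrpCandidateReport",
    "HelicityRecord",
    "sasa",
    "trp_candidates",
    "classify_helicity",
    "MAX_SASA_TIEN",
]

# Theoretical Gly-X-Gly maximum SASA (Å²), Tien et al. 2013 (PLOS ONE
# 8:e80635, "theoretical" column); used to normalize absolute SASA.
MAX_SASA_TIEN: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}

# van der Waals radii (Å) by element symbol (first letter of the atom name)
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_VDW = 1.70


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point lattice."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden-angle increment
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SasaProfile:
    model_id: str
    indices: list[int]
    aa: list[str]
    absolute: np.ndarray  # Å² per residue
    relative: np.ndarray  # absolute / reference(aa)
    probe_radius: float
    n_points: int
    reference_table: str = "tien2013-theoretical"

    @property
    def total(self) -> float:
        return float(self.absolute.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.indices,
                "aa": self.aa,
                "sasa_abs": self.absolute,
                "sasa_rel": self.relative,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    reference: dict[str, float] | None = None,
) -> SasaProfile:
    """Per-residue Shrake–Rupley SASA of one model.

    Deterministic given ``n_points`` (fixed Fibonacci lattice).  Residues
    carrying only a CA atom are scored from the CA sphere alone, with a
    warning.
    """
    if reference is None:
        reference = MAX_SASA_TIEN
    atoms_xyz: list[np.ndarray] = []
    atoms_rad: list[float] = []
    atoms_res: list[int] = []  # residue slot per atom
    for slot, res in enumerate(model.residues):
        named = res.atoms()
        if set(named) == {"CA"} and res.aa != "G":
            warnings.warn(
                f"residue {res.index} has only CA; SASA from CA sphere only",
                stacklevel=2,
            )
        for name, xyz in named.items():
            atoms_xyz.append(np.asarray(xyz, float))
            atoms_rad.append(_VDW.get(name[0], _DEFAULT_VDW) + probe)
            atoms_res.append(slot)
    xyz = np.array(atoms_xyz)
    rad = np.array(atoms_rad)
    res_of = np.array(atoms_res)

    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_rad = rad.max()
    per_res = np.zeros(len(model.residues))
    for a in range(xyz.shape[0]):
        pts = xyz[a] + rad[a] * sphere
        neigh = [b for b in tree.query_ball_point(xyz[a], rad[a] + max_rad) if b != a]
        if neigh:
            nb_xyz = xyz[neigh]
            nb_rad = rad[neigh]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_rad**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_res[res_of[a]] += frac * 4.0 * np.pi * rad[a] ** 2
    rel = np.array(
        [
            per_res[k] / reference.get(res.aa, reference["X"])
            for k, res in enumerate(model.residues)
        ]
    )
    return SasaProfile(
        model_id=model.model_id,
        indices=model.indices,
        aa=[r.aa for r in model.residues],
        absolute=per_res,
        relative=rel,
        probe_radius=probe,
        n_points=n_points,
    )


@dataclass
class TrpCandidateReport:
    index: int
    aa: str
    mean_relative_sasa: float
    selected: bool


def trp_candidates(
    ensemble: EnsembleIndex,
    threshold: float = 0.15,
    probe: float = 1.4,
    n_points: int = 960,
) -> list[TrpCandidateReport]:
    """Buried positions across an ensemble, sorted by mean relative SASA.

    A residue is selected as a tryptophan-scanning candidate when its mean
    relative SASA over the ensemble is ≤ ``threshold``.
    """
    first, last = ensemble.residue_range
    profiles = []
    for m in ensemble.models:
        residues = ensemble.residues(m)
        sub = StructureModel(m.model_id, residues, source=m.source)
        profiles.append(sasa(sub, probe=probe, n_points=n_points))
    rel = np.array([p.relative for p in profiles])  # (n_models, L)
    mean_rel = rel.mean(axis=0)
    aa = profiles[0].aa
    indices = profiles[0].indices
    reports = [
        TrpCandidateReport(idx, a, float(mr), bool(mr <= threshold))
        for idx, a, mr in zip(indices, aa, mean_rel)
    ]
    reports.sort(key=lambda r: r.mean_relative_sasa)
    return reports


@dataclass
class HelicityRecord:
    label: str
    helical_fraction: float  # percent
    delta: float  # percentage points vs reference
    classification: str  # neutral | partial | disruptive


def classify_helicity(
    mutants: Sequence[tuple[str, float]],
    reference: float,
    partial_cut: float = 3.0,
    disruptive_cut: float = 5.0,
) -> list[HelicityRecord]:
    """Call each mutant from its α-helical fraction (percent) relative to a
    tryptophan-free reference.

    Classification on delta = mutant − reference (percentage points):
    disruptive if delta ≤ −disruptive_cut, partial if
    −disruptive_cut < delta ≤ −partial_cut, else neutral.  Increases in
    helicity are always neutral.
    """
    if not 0.0 <= reference <= 100.0:
        raise ValueError("reference helical fraction must be a percentage")
    records = []
    for label, frac in mutants:
        if not 0.0 <= frac <= 100.0:
            raise ValueError(f"{label}: helical fraction must be a percentage")
        delta = frac - reference
        if delta <= -disruptive_cut:
            cls = "disruptive"
        elif delta <= -partial_cut:
            cls = "partial"
        else:
            cls = "neutral"
        records.append(HelicityRecord(label, frac, delta, cls))
    return records
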