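"""Confidence-weighted sigmoidal contact scoring and z-score filtering.

Coevolutionary contact predictors emit residue pairs (i, j) with a confidence
c in (0, 1].  A structural model is rewarded for placing the representative
atoms (Cβ, Cα for glycine) of a predicted pair close together through the
sigmoidal term

    f(c, r) = c * (1 / (1 + exp(-3 (r - 8))) - 1)

which is -c for a fully satisfied contact (r << 8 Å), -c/2 at the 8 Å contact
threshold, and approaches 0 for well-separated pairs.  The Contact score of a
model is the sum of f over all predicted contacts; lower (more negative) is
better.  Within a decoy ensemble, models are filtered on the z-score of their
Contact score, retaining models at least two population standard deviations
better than the ensemble mean (z ≤ -2) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import EnsembleIndex, StructureModel

__all__ = [
    "ContactPrediction",
    "ContactList",
    "ScoreTable",
    "read_contacts",
    "write_contacts",
    "contact_term",
    "score_model",
    "score_ensemble",
    "zscore_filter",
    "SIGMOID_CENTER",
    "SIGMOID_SLOPE",
]

SIGMOID_CENTER = 8.0  # Å, the contact-prediction distance convention
SIGMOID_SLOPE = 3.0  # 1/Å

DEFAULT_MIN_SEPARATION = 5  # |i-j| below this is discarded by convention


@dataclass(frozen=True)
class ContactPrediction:
    """A predicted residue-residue contact with confidence ``c`` in (0, 1]."""

    i: int
    j: int
    c: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-contact ({self.i},{self.j}) is not allowed")
        if self.i > self.j:  # normalize to i < j
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)
        if not self.c > 0:
            raise ValueError(f"confidence must be > 0, got {self.c}")


@dataclass
class ContactList:
    contacts: list[ContactPrediction]
    min_confidence: float = 0.0

    def __post_init__(self) -> None:
        seen = set()
        for ct in self.contacts:
            if (ct.i, ct.j) in seen:
                raise ValueError(f"duplicate contact ({ct.i},{ct.j})")
            seen.add((ct.i, ct.j))

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def total_confidence(self) -> float:
        return sum(ct.c for ct in self.contacts)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.array([ct.i for ct in self.contacts], dtype=int)
        j = np.array([ct.j for ct in self.contacts], dtype=int)
        c = np.array([ct.c for ct in self.contacts], dtype=float)
        return i, j, c


@dataclass
class ScoreTable:
    """Per-model Contact scores with ensemble z-scores."""

    model_ids: list[str]
    contact_scores: np.ndarray
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_id": self.model_ids,
                "contact_score": self.contact_scores,
                "z": self.z,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def score_of(self, model_id: str) -> float:
        return float(self.contact_scores[self.model_ids.index(model_id)])


def read_contacts(
    path: str | Path,
    min_confidence: float = 0.0,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactList:
    """Read a CASP-RR-like contact file.

    Data lines are whitespace-delimited ``i j [d_lo d_hi] confidence`` — the
    confidence is the last field, optional distance-bound columns are
    ignored, and ``#`` starts a comment.  Pairs are normalized to i < j,
    entries below ``min_confidence`` or closer in sequence than
    ``min_separation`` are dropped, and duplicates collapse keeping the
    maximum confidence.
    """
    best: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected 'i j [lo hi] conf'")
            try:
                i, j = int(fields[0]), int(fields[1])
                c = float(fields[-1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if i == j:
                raise ValueError(f"line {lineno}: self-contact ({i},{j})")
            i, j = min(i, j), max(i, j)
            if c < min_confidence or (j - i) < min_separation:
                continue
            best[(i, j)] = max(best.get((i, j), 0.0), c)
    contacts = [ContactPrediction(i, j, c) for (i, j), c in sorted(best.items())]
    return ContactList(contacts, min_confidence=min_confidence)


def write_contacts(contacts: ContactList, path: str | Path) -> None:
    """Write the same whitespace-delimited RR dialect the reader consumes."""
    lines = ["# i j d_lo d_hi confidence"]
    for ct in contacts:
        lines.append(f"{ct.i} {ct.j} 0 {SIGMOID_CENTER:.0f} {ct.c:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def contact_term(c: float, r: float) -> float:
    """Sigmoidal score of one predicted contact at representative-atom
    distance ``r`` (Å): c·(1/(1+exp(−3·(r−8))) − 1), in [−c, 0)."""
    return c * (1.0 / (1.0 + math.exp(-SIGMOID_SLOPE * (r - SIGMOID_CENTER))) - 1.0)


def score_model(
    model: StructureModel,
    contacts: ContactList,
    weight: float = 1.0,
    _coords: dict[int, np.ndarray] | None = None,
) -> float:
    """Contact score of one model: Σ f(c, r_ij) over predicted contacts.

    ``weight`` is an overall multiplier (1 for rescoring).  Raises if any
    contact references a residue absent from the model.
    """
    if _coords is None:
        _coords = {
            r.index: coord
            for r, coord in zip(model.residues, model.representative_coords())
        }
    i, j, c = contacts.arrays()
    missing = [
        (int(a), int(b))
        for a, b in zip(i, j)
        if a not in _coords or b not in _coords
    ]
    if missing:
        raise KeyError(
            f"model {model.model_id!r}: contacts reference missing residues {missing[:5]}"
        )
    a = np.array([_coords[int(k)] for k in i])
    b = np.array([_coords[int(k)] for k in j])
    r = np.linalg.norm(a - b, axis=1)
    terms = c * (1.0 / (1.0 + np.exp(-SIGMOID_SLOPE * (r - SIGMOID_CENTER))) - 1.0)
    return weight * float(terms.sum())


def score_ensemble(
    ensemble: EnsembleIndex | Sequence[StructureModel],
    contacts: ContactList,
    weight: float = 1.0,
) -> ScoreTable:
    """Score every model and attach ensemble z-scores.

    z uses the population standard deviation; an ensemble of identical scores
    is degenerate and raises.
    """
    models = ensemble.models if isinstance(ensemble, EnsembleIndex) else list(ensemble)
    if len(models) < 2:
        raise ValueError("z-scores need at least 2 models")
    scores = np.array([score_model(m, contacts, weight=weight) for m in models])
    sd = float(scores.std())  # population sd
    if sd == 0.0:
        raise ValueError("degenerate ensemble: all contact scores identical")
    z = (scores - scores.mean()) / sd
    return ScoreTable([m.model_id for m in models], scores, z)


def zscore_filter(table: ScoreTable, cutoff: float = -2.0) -> list[str]:
    """Model ids with z ≤ ``cutoff`` (inclusive), original order preserved."""
    if len(table.model_ids) == 0:
        raise ValueError("empty score table")
    return [
        mid for mid, z in zip(table.model_ids, table.z) if z <= cutoff
    ]
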