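"""Structural models: PDB input/output and coordinate views.

A decoy is represented as a :class:`StructureModel`, an ordered list of
residues carrying backbone (and, where present, Cβ) coordinates.  All
downstream stages — contact scoring, RMSD/TM-score comparison, contact maps
and solvent accessibility — consume the views exposed here, in particular the
representative-atom convention of coevolutionary contact scoring: the Cβ atom,
falling back to Cα for glycine (or for residues whose Cβ is missing, with a
warning).

The reader is a deliberately strict fixed-column PDB reader for single-chain
decoy files: HETATM records are ignored, altloc other than blank/'A' is
skipped, insertion codes are rejected, and every residue must carry a Cα.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ResidueRecord",
    "StructureModel",
    "EnsembleIndex",
    "StructureError",
    "read_structure",
    "write_structure",
    "representative_atom",
    "slice_ensemble",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class ResidueRecord:
    """One residue of a model.

    ``index`` is the residue number taken verbatim from the source file
    (1-based in all synthetic output); ``ca`` is always present, ``cb`` is
    ``None`` for glycine or incomplete residues; ``other_atoms`` maps atom
    names (N, C, O, ...) to coordinates for surface-area calculations.
    """

    index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray | None = None
    other_atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def atoms(self) -> dict[str, np.ndarray]:
        """All named heavy atoms including CA/CB."""
        out = {"CA": self.ca}
        if self.cb is not None:
            out["CB"] = self.cb
        out.update(self.other_atoms)
        return out


@dataclass
class StructureModel:
    model_id: str
    residues: list[ResidueRecord]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise StructureError(
                f"model {self.model_id!r}: needs >= 2 residues, got {len(self.residues)}"
            )
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(
                f"model {self.model_id!r}: residue indices must be strictly increasing"
            )

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, index: int) -> ResidueRecord:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"model {self.model_id!r}: no residue with index {index}")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def representative_coords(self) -> np.ndarray:
        """Cβ coordinates with Cα fallback, one row per residue."""
        return np.array([representative_atom(r) for r in self.residues], dtype=float)


def representative_atom(residue: ResidueRecord) -> np.ndarray:
    """Contact-scoring coordinate of a residue: Cβ, or Cα for glycine.

    A non-glycine residue lacking Cβ falls back to Cα with a warning — the
    structure is incomplete but still scoreable.
    """
    if residue.cb is not None:
        return residue.cb
    if residue.aa != "G":
        warnings.warn(
            f"residue {residue.index} ({residue.aa}) lacks CB; falling back to CA",
            stacklevel=2,
        )
    return residue.ca


@dataclass
class EnsembleIndex:
    """A view of equal-sequence models over an inclusive residue range."""

    models: list[StructureModel]
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        first, last = self.residue_range
        seqs = set()
        for m in self.models:
            rs = self._range_residues(m)
            seqs.add("".join(r.aa for r in rs))
        if len(seqs) > 1:
            raise StructureError(
                f"models disagree in sequence over range [{first},{last}]"
            )

    def _range_residues(self, model: StructureModel) -> list[ResidueRecord]:
        first, last = self.residue_range
        rs = [r for r in model.residues if first <= r.index <= last]
        have = {r.index for r in rs}
        missing = [i for i in range(first, last + 1) if i not in have]
        if missing:
            raise StructureError(
                f"model {model.model_id!r}: missing residues {missing[:5]} "
                f"in range [{first},{last}]"
            )
        return rs

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]

    @property
    def n_residues(self) -> int:
        first, last = self.residue_range
        return last - first + 1

    def residues(self, model: StructureModel | int) -> list[ResidueRecord]:
        if isinstance(model, int):
            model = self.models[model]
        return self._range_residues(model)

    def ca_matrix(self) -> np.ndarray:
        """(n_models, n_residues, 3) Cα coordinate stack over the range."""
        return np.array(
            [[r.ca for r in self.residues(m)] for m in self.models], dtype=float
        )

    def representative_matrix(self) -> np.ndarray:
        return np.array(
            [[representative_atom(r) for r in self.residues(m)] for m in self.models],
            dtype=float,
        )


def slice_ensemble(
    models: Sequence[StructureModel], first: int, last: int
) -> EnsembleIndex:
    """View an ensemble restricted to residues ``first``..``last`` inclusive.

    The original models are not modified; missing residues in any model raise
    an error naming it.
    """
    if last < first:
        raise StructureError(f"empty residue range [{first},{last}]")
    ens = EnsembleIndex(list(models), (first, last))
    for m in ens.models:  # force validation of every model up front
        ens._range_residues(m)
    return ens


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns, single chain, ATOM records only)
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O", "CB")


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise StructureError(
            f"insertion code {icode!r} at line {lineno} not supported"
        )
    return name, altloc, resname, chain, resseq, np.array([x, y, z])


def read_structure(
    path: str | Path,
    model_policy: str = "first",
    chain_id: str | None = None,
) -> StructureModel | list[StructureModel]:
    """Read one or all MODEL blocks of a single-chain PDB file.

    ``model_policy`` is ``"first"`` (return one :class:`StructureModel`) or
    ``"all"`` (return a list).  HETATM records are ignored; altloc other than
    blank/'A' is skipped; only the first chain is read unless ``chain_id`` is
    given.  Every residue must carry a CA atom.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    stem = path.stem

    models: list[StructureModel] = []
    current: dict[int, dict] = {}
    order: list[int] = []
    model_no = 0
    active_chain = chain_id

    def flush() -> None:
        nonlocal current, order, model_no
        if not order:
            return
        residues = []
        for resseq in order:
            rec = current[resseq]
            if "CA" not in rec["atoms"]:
                raise StructureError(
                    f"{path.name}: residue {rec['resname']} {resseq} has no CA atom"
                )
            atoms = rec["atoms"]
            residues.append(
                ResidueRecord(
                    index=resseq,
                    aa=AA3_TO_1.get(rec["resname"], "X"),
                    ca=atoms["CA"],
                    cb=atoms.get("CB"),
                    other_atoms={
                        k: v for k, v in atoms.items() if k not in ("CA", "CB")
                    },
                )
            )
        model_no += 1
        mid = stem if model_no == 1 else f"{stem}#{model_no}"
        models.append(StructureModel(mid, residues, source=str(path)))
        current, order = {}, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                flush()
            elif rec == "ENDMDL":
                flush()
                if model_policy == "first" and models:
                    break
            elif rec == "ATOM  ":
                name, altloc, resname, chain, resseq, xyz = _parse_atom_line(
                    line, lineno
                )
                if altloc not in (" ", "A"):
                    continue
                if active_chain is None:
                    active_chain = chain
                if chain != active_chain:
                    continue
                if resseq not in current:
                    current[resseq] = {"resname": resname, "atoms": {}}
                    order.append(resseq)
                current[resseq]["atoms"].setdefault(name, xyz)
    flush()
    if not models:
        raise StructureError(f"{path}: no ATOM records found")
    if model_policy == "first":
        return models[0]
    return models


def write_structure(
    model_or_models: StructureModel | Iterable[StructureModel],
    path: str | Path,
    chain_id: str = "A",
) -> None:
    """Write one model (or several, as MODEL/ENDMDL blocks) in PDB format."""
    models = (
        [model_or_models]
        if isinstance(model_or_models, StructureModel)
        else list(model_or_models)
    )
    multi = len(models) > 1
    lines: list[str] = []
    serial = 0
    for k, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        for res in model.residues:
            resname = AA1_TO_3.get(res.aa, "UNK")
            named = [("N", res.other_atoms.get("N")), ("CA", res.ca)]
            named += [(n, v) for n, v in res.other_atoms.items() if n not in ("N",)]
            if res.cb is not None:
                named.append(("CB", res.cb))
            for name, xyz in named:
                if xyz is None:
                    continue
                serial += 1
                element = name[0]
                name_field = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {resname:>3s} {chain_id}"
                    f"{res.index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00          {element:>2s}"
                )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
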