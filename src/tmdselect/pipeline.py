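"""End-to-end runs: decoy model selection and copper-binding analysis.

Two orchestrated arms mirror the two halves of the analysis:

* ``run_model_selection`` — score a decoy ensemble against predicted
  contacts, filter at a z-score cutoff, cluster the retained models, emit
  per-cluster averaged contact maps, TM-scores against the selected
  centroid, and buried-residue candidates for tryptophan scanning.
* ``run_copper_analysis`` — fit the BCA₂-Cu(I) calibration line, derive the
  released-copper concentration and metal:protein stoichiometry, fit the
  Hill isotherm to a titration, and convert the competition constant K_R
  into dimer and per-copper dissociation constants.

Every run writes TSV tables, a JSON summary and a manifest (inputs with
hashes, thresholds, seeds, package version) so that any reported number can
be regenerated from the manifest alone.  All randomness is routed through
one named seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .contacts import read_contacts, score_ensemble, zscore_filter
from .copper import (
    concentration_from_absorbance,
    fit_calibration,
    fit_hill,
    flatness_test,
    kd_from_KR,
    read_standards,
    read_titration,
    stoichiometry_ratio,
)
from .ensemble import (
    average_contact_map,
    cluster_neighbors,
    cluster_stats,
    pairwise_rmsd,
    tm_score,
)
from .sasa import trp_candidates
from .structure import read_structure, slice_ensemble
from .synth import (
    EnsembleSpec,
    TitrationSpec,
    contacts_from_structure,
    make_bundle,
    make_calibration_standards,
    make_ensemble,
    make_titration,
    template_spec,
)

__all__ = ["RunConfig", "run_model_selection", "run_copper_analysis"]


@dataclass
class RunConfig:
    """Declarative configuration for both pipeline arms.

    Threshold defaults follow the published analysis where one is stated
    (z ≤ −2 filter, 8 Å contact maps); the 4.0 Å clustering threshold is the
    upper end of the printed between-centroid RMSD scale, and the SASA
    threshold/helicity cuts are documented package defaults.
    """

    # inputs (model selection): a directory of PDB decoys + a contact file,
    # or synthetic=True to generate the benchmark ensemble
    decoy_dir: str | None = None
    contact_file: str | None = None
    synthetic: bool = False
    residue_range: tuple[int, int] | None = None

    # inputs (copper): delimited text files, or synthetic series
    standards_file: str | None = None
    titration_file: str | None = None
    control_file: str | None = None
    sample_a562: float | None = None
    protein_uM: float | None = None
    K_R: float | None = None
    beta2: float = 2.0e17

    # thresholds
    z_cutoff: float = -2.0
    cluster_threshold: float = 4.0
    contact_cutoff: float = 8.0
    min_confidence: float = 0.1
    map_min_sep: int = 5
    sasa_threshold: float = 0.15
    partial_cut: float = 3.0
    disruptive_cut: float = 5.0

    seed: int = 0
    out_dir: str = "tmdselect_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if cfg.residue_range is not None:
            cfg.residue_range = tuple(cfg.residue_range)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest(config: RunConfig, inputs: dict[str, str | None]) -> dict:
    return {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256_16": _hash_file(p)}
            for name, p in inputs.items()
            if p is not None
        },
    }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# Model selection arm
# ---------------------------------------------------------------------------

def run_model_selection(config: RunConfig) -> dict:
    """Score → filter → cluster → maps → TM-scores → Trp candidates.

    Returns the summary report (also written to ``out_dir/summary.json``
    alongside TSV tables and the run manifest).  For synthetic runs the
    topology labels are used only to report the purity of the retained set
    and largest cluster — no pipeline stage consumes them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = None

    if config.synthetic:
        spec = EnsembleSpec(seed=config.seed)
        ensemble, labels = make_ensemble(spec)
        reference = make_bundle(template_spec(spec.class_specs["left"]), "template")
        contacts = contacts_from_structure(
            reference,
            cutoff=config.contact_cutoff,
            min_sep=config.map_min_sep,
            seed=config.seed,
        )
        inputs: dict[str, str | None] = {}
    else:
        if not config.decoy_dir or not config.contact_file:
            raise ValueError("model selection needs decoy_dir and contact_file")
        paths = sorted(Path(config.decoy_dir).glob("*.pdb"))
        if not paths:
            raise ValueError(f"no PDB files under {config.decoy_dir}")
        models = [read_structure(p, model_policy="first") for p in paths]
        if config.residue_range is not None:
            first, last = config.residue_range
        else:
            first = models[0].residues[0].index
            last = models[0].residues[-1].index
        ensemble = slice_ensemble(models, first, last)
        contacts = read_contacts(
            config.contact_file,
            min_confidence=config.min_confidence,
            min_separation=config.map_min_sep,
        )
        inputs = {"contact_file": config.contact_file}
        inputs.update({p.name: str(p) for p in paths[:3]})

    table = score_ensemble(ensemble, contacts)
    table.to_tsv(out / "scores.tsv")
    retained = zscore_filter(table, config.z_cutoff)
    (out / "retained_ids.txt").write_text("\n".join(retained) + "\n")

    report: dict = {
        "n_models": len(ensemble.models),
        "n_contacts": len(contacts),
        "z_cutoff": config.z_cutoff,
        "n_retained": len(retained),
    }
    if labels is not None:
        by_id = dict(zip(table.model_ids, labels))
        n_opp = sum(1 for v in labels if v == "right")
        opp_ret = sum(1 for m in retained if by_id[m] == "right")
        report["opposite_removed_fraction"] = (
            1.0 - opp_ret / n_opp if n_opp else None
        )

    if len(retained) < 2:
        report["note"] = "fewer than 2 models retained; clustering skipped"
        _write_json(report, out / "summary.json")
        _write_json(_manifest(config, inputs), out / "manifest.json")
        return report

    kept = [ensemble.models[table.model_ids.index(m)] for m in retained]
    sub = slice_ensemble(kept, *ensemble.residue_range)
    matrix = pairwise_rmsd(sub)
    matrix.to_tsv(out / "pairwise_rmsd.tsv")
    clusters = cluster_neighbors(
        matrix,
        threshold=config.cluster_threshold,
        scores={m: table.score_of(m) for m in retained},
    )
    clusters.to_tsv(out / "clusters.tsv")
    stats = cluster_stats(matrix, clusters)

    for rank, cl in enumerate(clusters.clusters, start=1):
        members = [sub.models[sub.model_ids.index(m)] for m in cl.members]
        amap = average_contact_map(
            members, cutoff=config.contact_cutoff, min_sep=config.map_min_sep
        )
        amap.to_tsv(out / f"cluster{rank}_avg_contact_map.tsv")

    centroid = sub.models[sub.model_ids.index(clusters.largest.centroid)]
    tm = {
        m.model_id: tm_score(m, centroid) for m in sub.models
    }
    _write_json(tm, out / "tm_scores.json")

    largest_members = [sub.models[sub.model_ids.index(m)] for m in
                       clusters.largest.members]
    largest_ens = slice_ensemble(largest_members, *ensemble.residue_range)
    candidates = trp_candidates(largest_ens, threshold=config.sasa_threshold)
    with open(out / "trp_candidates.tsv", "w") as fh:
        fh.write("index\taa\tmean_rel_sasa\tselected\n")
        for c in candidates:
            fh.write(f"{c.index}\t{c.aa}\t{c.mean_relative_sasa:.4f}\t{c.selected}\n")

    report.update(
        {
            "cluster_sizes": [len(c.members) for c in clusters.clusters],
            "cluster_threshold": clusters.threshold,
            "centroid": clusters.largest.centroid,
            "qm_rmsd": stats.qm_rmsd,
            "centroid_rmsds": {f"{a}-{b}": v for (a, b), v in
                               stats.centroid_rmsds.items()},
            "tm_score_min": min(tm.values()),
            "tm_score_ge_05_fraction": float(
                np.mean([v >= 0.5 for v in tm.values()])
            ),
            "n_trp_candidates": sum(c.selected for c in candidates),
        }
    )
    if labels is not None:
        purity = sum(
            1 for m in clusters.largest.members if by_id[m] == "left"
        ) / len(clusters.largest.members)
        report["largest_cluster_purity"] = purity

    _write_json(report, out / "summary.json")
    _write_json(_manifest(config, inputs), out / "manifest.json")
    return report


# ---------------------------------------------------------------------------
# Copper arm
# ---------------------------------------------------------------------------

def run_copper_analysis(config: RunConfig) -> dict:
    """Calibration → stoichiometry; titration → Hill fit; K_R → K_D."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str | None] = {
        "standards_file": config.standards_file,
        "titration_file": config.titration_file,
        "control_file": config.control_file,
    }
    report: dict = {}

    if config.standards_file:
        standards = read_standards(config.standards_file)
    elif config.synthetic:
        standards = make_calibration_standards(seed=config.seed)
    else:
        standards = None
    if standards is not None:
        curve = fit_calibration(standards)
        report["calibration"] = {
            "slope_per_uM": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
        }
        if config.sample_a562 is not None:
            conc, in_range = concentration_from_absorbance(curve, config.sample_a562)
            report["released_copper_uM"] = conc
            report["released_copper_in_range"] = in_range
            if config.protein_uM:
                full, two_dec = stoichiometry_ratio(conc, config.protein_uM)
                report["copper_protein_ratio"] = two_dec
                report["copper_protein_ratio_full"] = full

    if config.titration_file:
        series = read_titration(config.titration_file)
    elif config.synthetic:
        series, _ = make_titration(TitrationSpec(seed=config.seed))
    else:
        series = None
    if series is not None:
        hill = fit_hill(series)
        report["hill"] = {
            "h": hill.h,
            "h_stderr": hill.h_stderr,
            "k_half_uM": hill.k_half,
            "a0": hill.a0,
            "delta_a": hill.delta_a,
        }

    if config.control_file:
        control = read_titration(config.control_file)
        verdict = flatness_test(control)
        report["negative_control"] = {
            "binding": verdict["binding"],
            "verdict": "binding" if verdict["binding"] else "no binding",
            "slope": verdict["slope"],
            "slope_stderr": verdict["slope_stderr"],
        }

    if config.K_R is not None:
        constants = kd_from_KR(config.K_R, config.beta2)
        report["competition"] = {
            "K_R_M2": constants.K_R,
            "beta2_per_M2": constants.beta2,
            "K_D_dimer_M2": constants.K_D_dimer,
            "K_D_per_copper_M": constants.K_D_per_copper,
        }

    if not report:
        raise ValueError("copper analysis config provided no inputs")
    _write_json(report, out / "copper_summary.json")
    _write_json(_manifest(config, inputs), out / "manifest.json")
    return report
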