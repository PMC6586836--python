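"""Pick buried positions for tryptophan scanning and classify CD readouts.

Computes per-residue relative solvent accessibility over a small ensemble of
helical-bundle models, proposes the most buried positions as tryptophan-
mutation candidates, and classifies mutant helicity values against a
tryptophan-free reference construct.
"""

from tmdselect import (
    BundleSpec,
    classify_helicity,
    make_bundle,
    slice_ensemble,
    trp_candidates,
)

models = [make_bundle(BundleSpec(seed=s), f"model_{s}") for s in range(5)]
ensemble = slice_ensemble(models, 1, 98)
reports = trp_candidates(ensemble, threshold=0.15, n_points=480)
selected = [r for r in reports if r.selected]
print(f"{len(selected)} buried candidates (mean relative SASA <= 0.15):")
print("  " + ", ".join(f"{r.aa}{r.index}" for r in selected[:12])
      + (" ..." if len(selected) > 12 else ""))
# Buried positions are where a bulky tryptophan should distort the bundle.

mutants = [("F27W", 34.0), ("F33W", 35.0), ("I29W", 22.0), ("L39W", 25.0),
           ("V54W", 27.0), ("L64W", 32.0), ("L70W", 33.0), ("L75W", 26.0)]
records = classify_helicity(mutants, reference=33.0)
print("helicity calls vs 33% reference:")
for r in records:
    print(f"  {r.label}: {r.helical_fraction:.0f}% ({r.delta:+.0f} pp) -> "
          f"{r.classification}")
# Drops of >= 5 pp are called disruptive — the signature of a tryptophan
# inserted at a buried/interface position.
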