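"""Copper(I) stoichiometry and affinity from chelator-competition data.

Walks the full analytic chain: calibration line of BCA₂-Cu(I) standards →
released-copper concentration → metal:protein ratio; Hill fit of a
protein-into-chelate titration; and conversion of the competition constant
K_R into dimer and per-copper dissociation constants.
"""

from tmdselect import (
    TitrationSpec,
    concentration_from_absorbance,
    fit_calibration,
    fit_hill,
    kd_from_KR,
    make_calibration_standards,
    make_titration,
    stoichiometry_ratio,
)

# 1. Calibration: a noiseless standard line at 0.01 A562/µM
standards = make_calibration_standards((10, 20, 30), slope=0.01)
curve = fit_calibration(standards)
print(f"calibration: slope {curve.slope:.4f} A/µM, r² {curve.r_squared:.4f}")

# 2. Released copper and stoichiometry (worked-example concentrations)
released, _ = concentration_from_absorbance(curve, 0.283)
_, ratio = stoichiometry_ratio(released, 26.22)
print(f"released copper {released:.1f} µM over 26.22 µM protein "
      f"-> {ratio:.2f} Cu(I) per protein")
# A ratio of ~1 supports one copper ion per monomer.

# 3. Hill fit of a synthetic titration generated at h = 1 (non-cooperative)
series, truth = make_titration(TitrationSpec(seed=1))
fit = fit_hill(series)
print(f"Hill fit: h = {fit.h:.2f} ± {fit.h_stderr:.2f} "
      f"(generated at h = {truth['h']}), k_half = {fit.k_half:.1f} µM")
# h ≈ 1 indicates simple, non-cooperative copper binding.

# 4. Femtomolar affinity from the competition constant
cc = kd_from_KR(K_R=1.5e-5, beta2=2e17)
print(f"K_D(dimer, 2 Cu) = {cc.K_D_dimer:.1e} M², "
      f"per copper = {cc.K_D_per_copper:.1e} M")
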