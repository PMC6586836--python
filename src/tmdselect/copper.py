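"""Cu(I)-binding analytics: calibration, stoichiometry, Hill isotherm and
chelator-competition equilibrium.

The experimental system is the chromophoric chelate BCA₂-Cu(I) (bicinchoninic
acid, 2:1 with monovalent copper), which absorbs at 562 nm and serves both as
a Cu(I) buffer and as the spectroscopic reporter.  Two measurements feed the
analysis:

* a calibration curve of BCA₂-Cu(I) standards (A562 vs concentration) used to
  quantify copper released from a denatured, copper-saturated protein sample,
  giving the metal:protein stoichiometry; and
* a titration of protein into BCA₂-Cu(I): copper transfer to the protein
  bleaches the chelate, and the absorbance-vs-protein curve is fitted with a
  Hill isotherm (cooperativity h) and interpreted through the competition
  equilibrium

      P₂ + 2 BCA₂-Cu(I)  ⇌  P₂Cu₂ + 4 BCA

  with partial reactions BCA₂-Cu(I) ⇌ Cu(I) + 2 BCA (formation constant β₂)
  and P₂ + 2 Cu(I) ⇌ P₂Cu₂ (dissociation constant K_D, M²).  The overall
  constant K_R = [P₂Cu₂][BCA]⁴ / ([P₂][BCA₂Cu]²) relates to the protein's
  copper affinity as K_D = 1/(K_R·β₂²); the per-copper dissociation constant
  is √K_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "read_standards",
    "read_titration",
    "write_standards",
    "write_titration",
    "CalibrationCurve",
    "TitrationSeries",
    "HillFit",
    "CompetitionConstants",
    "EquilibriumState",
    "fit_calibration",
    "concentration_from_absorbance",
    "stoichiometry_ratio",
    "fit_hill",
    "solve_competition_equilibrium",
    "compute_KR",
    "kd_from_KR",
    "flatness_test",
    "BETA2_BCA",
]

BETA2_BCA = 2.0e17  # M^-2, literature formation constant of BCA2-Cu(I)


# ---------------------------------------------------------------------------
# Delimited-text I/O (header: conc_uM, A562)
# ---------------------------------------------------------------------------

def _read_two_column(path) -> "pd.DataFrame":
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if not {"conc_uM", "A562"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns conc_uM, A562")
    return df


def read_standards(path) -> np.ndarray:
    """Read calibration standards as an (n, 2) array of (conc_uM, A562)."""
    df = _read_two_column(path)
    return df[["conc_uM", "A562"]].to_numpy(dtype=float)


def write_standards(standards, path) -> None:
    import pandas as pd

    arr = np.asarray(standards, dtype=float)
    pd.DataFrame(arr, columns=["conc_uM", "A562"]).to_csv(path, index=False)


def read_titration(path) -> "TitrationSeries":
    """Read a titration series (protein concentration vs A562)."""
    df = _read_two_column(path)
    return TitrationSeries(
        protein_uM=df["conc_uM"].to_numpy(dtype=float),
        a562=df["A562"].to_numpy(dtype=float),
    )


def write_titration(series: "TitrationSeries", path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"conc_uM": series.protein_uM, "A562": series.a562}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calibration and stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Least-squares line A562 = slope · concentration + intercept."""

    concentrations: np.ndarray  # µM
    absorbances: np.ndarray
    slope: float  # absorbance / µM
    intercept: float
    r_squared: float
    slope_stderr: float

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())


def fit_calibration(
    standards: Sequence[tuple[float, float]] | np.ndarray,
) -> CalibrationCurve:
    """Fit the A562-vs-concentration standard line by ordinary least squares."""
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, A562) standards")
    conc, a = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("standards have zero concentration spread")
    res = stats.linregress(conc, a)
    return CalibrationCurve(
        concentrations=conc,
        absorbances=a,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
    )


def concentration_from_absorbance(
    curve: CalibrationCurve, a562: float
) -> tuple[float, bool]:
    """Invert the calibration line: (A − intercept)/slope, in µM.

    Returns ``(concentration, in_range)``; ``in_range`` is False when the
    implied concentration extrapolates more than 10% beyond the calibrated
    span (negative values are likewise flagged).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (a562 - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    margin = 0.1 * (hi - lo)
    in_range = (lo - margin) <= conc <= (hi + margin)
    return float(conc), bool(in_range)


def stoichiometry_ratio(copper_uM: float, protein_uM: float) -> tuple[float, float]:
    """Metal:protein molar ratio; returns (full precision, 2-decimal)."""
    if protein_uM <= 0:
        raise ValueError("protein concentration must be > 0")
    if copper_uM < 0:
        raise ValueError("copper concentration must be >= 0")
    ratio = copper_uM / protein_uM
    return ratio, round(ratio, 2)


# ---------------------------------------------------------------------------
# Hill isotherm
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Protein-dilution titration read out as A562 of the BCA₂-Cu(I) pool."""

    protein_uM: np.ndarray
    a562: np.ndarray
    bca_total_uM: float | None = None
    cu_total_uM: float | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_uM = np.asarray(self.protein_uM, dtype=float)
        self.a562 = np.asarray(self.a562, dtype=float)
        if self.protein_uM.shape != self.a562.shape:
            raise ValueError("protein and absorbance arrays differ in length")
        if (self.protein_uM < 0).any():
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.protein_uM)


@dataclass
class HillFit:
    h: float  # Hill coefficient
    k_half: float  # half-saturation protein concentration (same units as input)
    a0: float  # baseline absorbance (no protein)
    delta_a: float  # amplitude of the absorbance drop
    h_stderr: float
    k_half_stderr: float

    def predict(self, protein: np.ndarray) -> np.ndarray:
        return _hill_model(np.asarray(protein, float), self.a0, self.delta_a,
                           self.h, self.k_half)


def _hill_model(p, a0, da, h, k):
    p = np.asarray(p, dtype=float)
    frac = np.zeros_like(p)
    pos = p > 0
    frac[pos] = p[pos] ** h / (k**h + p[pos] ** h)
    return a0 - da * frac


def fit_hill(series: TitrationSeries) -> HillFit:
    """Nonlinear least-squares Hill fit A(P) = A₀ − ΔA·Pʰ/(k_halfʰ + Pʰ).

    Initial guesses: A₀ = max A, ΔA = observed range, h = 1, k_half = the
    protein concentration nearest the half-range absorbance.  All parameters
    are constrained positive; a flat series (no amplitude) is
    non-identifiable and raises.
    """
    if len(series) < 6:
        raise ValueError("Hill fit needs >= 6 titration points")
    p, a = series.protein_uM, series.a562
    rng = float(a.max() - a.min())
    if rng <= 0 or rng < 1e-12 * max(abs(a.max()), 1.0):
        raise ValueError("flat titration series: Hill parameters non-identifiable")
    half_level = a.max() - rng / 2.0
    k0 = float(p[np.argmin(np.abs(a - half_level))])
    if k0 <= 0:
        k0 = float(np.median(p[p > 0]))
    p0 = [float(a.max()), rng, 1.0, k0]
    try:
        popt, pcov = optimize.curve_fit(
            _hill_model,
            p,
            a,
            p0=p0,
            bounds=([-np.inf, 1e-12, 1e-3, 1e-12], [np.inf, np.inf, 20.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge (start {p0})") from exc
    a0, da, h, k = (float(v) for v in popt)
    if da <= 0 or h <= 0 or k <= 0:
        raise RuntimeError(f"Hill fit landed on non-physical optimum: {popt}")
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return HillFit(h=h, k_half=k, a0=a0, delta_a=da,
                   h_stderr=float(err[2]), k_half_stderr=float(err[3]))


def flatness_test(series: TitrationSeries, n_sigma: float = 2.0) -> dict:
    """Negative-control check: is A562 vs protein distinguishable from flat?

    Fits a line and reports ``binding=False`` when |slope| < n_sigma · SE —
    the expected verdict for a non-copper-binding control protein.
    """
    res = stats.linregress(series.protein_uM, series.a562)
    binding = abs(res.slope) >= n_sigma * res.stderr
    return {
        "slope": float(res.slope),
        "slope_stderr": float(res.stderr),
        "binding": bool(binding),
    }


# ---------------------------------------------------------------------------
# Competition equilibrium
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumState:
    """Species concentrations (M) of the competition equilibrium."""

    p2_free: float  # free protein dimer
    p2cu2: float  # copper-loaded dimer
    cu_free: float
    bca_free: float
    bca2cu: float

    def balances(self, p_total: float, cu_total: float, bca_total: float):
        """Relative closure of the three mass balances (dimer, Cu, BCA)."""
        bp = self.p2_free + self.p2cu2 - p_total
        bc = self.cu_free + self.bca2cu + 2 * self.p2cu2 - cu_total
        bb = self.bca_free + 2 * self.bca2cu - bca_total
        return (
            bp / max(p_total, 1e-300),
            bc / max(cu_total, 1e-300),
            bb / max(bca_total, 1e-300),
        )


def solve_competition_equilibrium(
    p_total: float,
    cu_total: float,
    bca_total: float,
    kd_dimer: float,
    beta2: float = BETA2_BCA,
    tol: float = 1e-12,
) -> EquilibriumState:
    """Simultaneous mass-action solution of the two partial equilibria.

    Unknowns are the free species (Cu, BCA, P₂), solved in log-space to
    enforce positivity; complexes follow from β₂ = [BCA₂Cu]/([Cu][BCA]²) and
    K_D = [P₂][Cu]²/[P₂Cu₂].  Inputs are molar; totals are the protein-dimer,
    copper and BCA totals.
    """
    if kd_dimer <= 0 or beta2 <= 0:
        raise ValueError("equilibrium constants must be positive")
    if min(p_total, cu_total, bca_total) < 0:
        raise ValueError("totals must be non-negative")
    if cu_total == 0:
        return EquilibriumState(p_total, 0.0, 0.0, bca_total, 0.0)

    # The system reduces to one unknown, the free Cu(I) concentration u:
    #   BCA balance  : bca + 2·β₂·u·bca² = BCA_total   (quadratic in bca)
    #   dimer balance: p2·(1 + u²/K_D) = P_total       (closed form)
    #   Cu balance   : g(u) = u + β₂·u·bca(u)² + 2·p2cu2(u) − Cu_total = 0
    # g is strictly increasing in u, so a bracketed Brent search on log u is
    # globally convergent.

    def species(u: float):
        if bca_total > 0 and u > 0:
            disc = math.sqrt(1.0 + 8.0 * beta2 * u * bca_total)
            bca = 2.0 * bca_total / (1.0 + disc)  # stable quadratic root
        else:
            bca = bca_total
        bca2cu = beta2 * u * bca**2
        load = u * u / kd_dimer
        p2 = p_total / (1.0 + load)
        p2cu2 = p2 * load
        return bca, bca2cu, p2, p2cu2

    def g(log_u: float) -> float:
        u = math.exp(log_u)
        bca, bca2cu, _, p2cu2 = species(u)
        return u + bca2cu + 2.0 * p2cu2 - cu_total

    lo, hi = math.log(cu_total) - 200.0, math.log(cu_total) + 2.0
    if g(lo) > 0 or g(hi) < 0:
        raise RuntimeError(
            f"equilibrium solver could not bracket the root: "
            f"g({lo:.1f})={g(lo):.3e}, g({hi:.1f})={g(hi):.3e}"
        )
    log_u = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=500)
    u = math.exp(log_u)
    bca, bca2cu, p2, p2cu2 = species(u)
    state = EquilibriumState(
        p2_free=float(p2),
        p2cu2=float(p2cu2),
        cu_free=float(u),
        bca_free=float(bca),
        bca2cu=float(bca2cu),
    )
    bal = state.balances(p_total, cu_total, bca_total)
    if max(abs(b) for b in bal) > max(tol, 1e-10):
        raise RuntimeError(
            f"equilibrium solver did not close mass balances: {bal}"
        )
    return state


def compute_KR(state: EquilibriumState) -> float:
    """Overall competition constant K_R = [P₂Cu₂][BCA]⁴/([P₂][BCA₂Cu]²), M²."""
    if min(state.p2_free, state.bca2cu) <= 0 or min(state.p2cu2, state.bca_free) <= 0:
        raise ValueError("all species must be positive to form K_R")
    return (
        state.p2cu2 * state.bca_free**4 / (state.p2_free * state.bca2cu**2)
    )


@dataclass
class CompetitionConstants:
    K_R: float  # M²
    beta2: float  # M⁻²
    K_D_dimer: float  # M²
    K_D_per_copper: float  # M


def kd_from_KR(K_R: float, beta2: float = BETA2_BCA) -> CompetitionConstants:
    """Dissociation constants from the competition constant.

    K_D(dimer) = 1/(K_R·β₂²) in M²; the per-copper constant is its square
    root.  (The symbolic and numeric renderings of this relation in the
    source literature disagree by a factor of β₂ and a cancelling chelate
    concentration term; the numeric path, which this function implements, is
    the dimensionally consistent one and reproduces the published femtomolar
    affinity.)
    """
    if K_R <= 0 or beta2 <= 0:
        raise ValueError("constants must be positive")
    kd_dimer = 1.0 / (K_R * beta2**2)
    return CompetitionConstants(
        K_R=K_R,
        beta2=beta2,
        K_D_dimer=kd_dimer,
        K_D_per_copper=math.sqrt(kd_dimer),
    )
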