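# Methods

## Contact scoring

A predicted contact (i, j, c) contributes
f(c, r) = c·(1/(1+e^{−3(r−8)}) − 1) to a model's Contact score, with r the
distance between representative atoms: Cβ, or Cα for glycine (and, with a
warning, for any residue whose Cβ is missing). The sigmoid is centered at
8 Å — the contact-prediction distance convention — with slope 3 Å⁻¹, so a
pair at exactly 8 Å contributes −c/2, a well-satisfied pair approaches −c,
and a violated pair contributes ~0. The score is a sum, hence permutation-
invariant in contact order and invariant under rigid-body motion.

Contacts are read from a whitespace-delimited `i j [d_lo d_hi] confidence`
dialect; pairs are normalized to i < j, duplicates keep the maximum
confidence, and a minimum sequence separation |i−j| ≥ 5 is applied by
default (the standard coevolution convention; configurable). An overall
score multiplier is exposed for parity with in-folding use of such
restraints but defaults to 1 for rescoring.

Ensemble z-scores use the population standard deviation — at the ensemble
sizes of interest the sample/population distinction is negligible, but the
choice is fixed for reproducibility — and the filter retains z ≤ cutoff
inclusively, with cutoff −2 by default. An ensemble whose scores are all
identical has no z-scale and is rejected rather than silently zeroed.

## Ensemble geometry

Superposition is least-squares (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`), guaranteed proper
(det = +1). Pairwise Cα RMSD over an inclusive residue range feeds a greedy
largest-neighborhood clustering: the model with the most neighbors within a
threshold becomes a cluster centroid, the cluster is removed, and the rule
repeats. Ties in neighbor count break toward the better (lower) Contact
score when scores are supplied, else the lexicographically smallest model
id, making output independent of input order. The library helper
`default_cluster_threshold` uses a quarter of the matrix's RMSD range; the
pipeline default is a fixed 4.0 Å, the upper end of the between-centroid
RMSD scale at which post-filter decoy clusters are typically resolved.
Cluster precision is reported as the quadratic mean of intra-cluster
pairwise RMSD (singletons report 0 with a flag) plus centroid–centroid
distances.

TM-score uses d0 = 1.24·(L−15)^{1/3} − 1.8 with L the reference length
(decoys here are equal-length, so the choice is inert but fixed). The
formula makes d0 non-positive for L ≤ 18, so chains that short are rejected.
The maximization over superpositions seeds from contiguous fragments (full
length, halves, quarters, length-4 windows at half-fragment stride) and
iteratively re-superposes on the residue subset with d_i < max(d0, 0.5),
falling back deterministically to the four closest residues when the subset
collapses; tests compare against an exhaustive-seed variant that tries
every contiguous fragment of length ≥ 4. A `superposition=False` mode
evaluates the score at the coordinates as given.

Contact maps are binary at a representative-atom cutoff (8 Å default) and a
minimum separation (5 when compared against coevolutionary predictions, 1
for intra-model geometry); cluster maps are element-wise means of member
binary maps, so entries are contact frequencies in [0, 1].

## Solvent accessibility and tryptophan scanning

SASA is Shrake–Rupley sphere sampling with a deterministic Fibonacci
lattice: 960 test points per atom by default (reproducibility over raw
speed), probe radius 1.4 Å, van der Waals radii by element (C 1.70, N 1.55,
O 1.52, S 1.80 Å). Per-atom accessible area is the expanded-sphere area
times the unoccluded point fraction; residue SASA is the sum over its
atoms, so per-residue values partition the model total exactly. Because the
point lattice is fixed in the laboratory frame, SASA is exactly invariant
under translation and invariant under rotation only to sampling tolerance
(≈1–2% at 960 points) — an accepted trade for determinism. Relative SASA
divides by the theoretical Gly-X-Gly maxima of Tien et al. 2013 (PLOS ONE
8:e80635); these reference values presume all-atom side chains, so on
backbone+Cβ models the relative scale is conservative (systematically low)
and should be read comparatively, not absolutely.

Tryptophan-scanning candidates are residues whose mean relative SASA across
the ensemble falls at or below a threshold (default 0.15), reported sorted
by burial. Helicity classification consumes already-deconvolved α-helical
percentages: delta = mutant − reference in percentage points; delta ≤ −5 is
disruptive, −5 < delta ≤ −3 partially disruptive, anything else (including
increases) neutral. The cuts are chosen so that mutants within ±2 pp of a
33% reference read neutral while drops to the low-to-mid twenties read
disruptive; CD deconvolution itself (Selcon3/CONTINLL) is out of scope.

## Copper(I) binding

Calibration is ordinary least squares of A562 on BCA₂-Cu(I) concentration
(Beer–Lambert linearity assumed; path length folded into the slope), with
r² and slope standard error reported. Inversion flags implied
concentrations extrapolating more than 10% beyond the calibrated span.
Stoichiometry is the released-copper to protein molar ratio, reported at
full precision and at two decimals.

The Hill fit is unweighted nonlinear least squares of
A(P) = A₀ − ΔA·Pʰ/(k½ʰ + Pʰ) — the absorbance-decrease parameterization,
because the signal is loss of chelate absorbance as protein strips Cu(I).
Initial guesses: A₀ = max A, ΔA = observed range, h = 1, k½ = concentration
nearest the half-range absorbance; parameters are bound positive and a flat
series is rejected as non-identifiable. Standard errors come from the fit
covariance. A negative-control helper calls "no binding" when the slope of
A vs protein is indistinguishable from zero at 2 standard errors.

The competition equilibrium couples BCA₂-Cu(I) ⇌ Cu(I) + 2 BCA
(β₂ = [BCA₂Cu]/([Cu][BCA]²), default 2×10¹⁷ M⁻²) with
P₂ + 2 Cu(I) ⇌ P₂Cu₂ (K_D = [P₂][Cu]²/[P₂Cu₂], units M²). Given totals,
the three balances reduce to a single strictly monotone equation in free
Cu(I) (free BCA is the stable root of a quadratic; the protein balance is
closed-form), solved by Brent bracketing on log[Cu] and verified to close
all balances to < 10⁻¹⁰ relative; failure raises rather than returning an
approximate state. K_R = [P₂Cu₂][BCA]⁴/([P₂][BCA₂Cu]²) (M²) and
K_D(dimer) = 1/(K_R·β₂²), per-copper K_D = √(K_D dimer). The symbolic and
numeric renderings of the K_R→K_D relation in the source literature
disagree (a factor of β₂ and a cancelling chelate-concentration term); the
implementation follows the dimensionally consistent numeric path, which
reproduces the published 1.7×10⁻³⁰ M² and 1.3×10⁻¹⁵ M values. Because
kd_from_KR ∘ compute_KR inverts the solver's constants exactly, the
pipeline's central round-trip (solve → K_R → K_D) is an identity to solver
tolerance, which the tests assert.

## Synthetic data

The decoy generator emulates an ab initio pool for a three-helix
transmembrane bundle. Helices are ideal α-helices (rise 1.5 Å/residue,
twist 100°, Cα radius 2.3 Å, Cβ at a 1.5 Å radial offset) placed on a
triangular cross-section (inter-axis distance 10.2 Å), running antiparallel
and joined by straight loop stubs; each axis is tilted by an 18° crossing
angle whose tangential sense encodes the bundle handedness — the two
classes are therefore genuinely different in their inter-helix contact
registers, not mirror images (a mirror would leave all distances, and hence
all contact scores, unchanged). Per-decoy heterogeneity comes from helix
phase jitter (±120°; the rotational setting of a helix is largely
unresolved in such pools), tilt jitter (σ 8°), axial register (σ 2.5 Å),
axis offset (σ 1.5 Å), azimuth jitter (σ 4°) and per-atom Gaussian noise
(σ 0.8 Å). These defaults were calibrated once against the dispersion such
pools exhibit — within-class pairwise Cα RMSD of a few Å up to ~13 Å across
the pool, and a filtered fraction of a few percent at z ≤ −2 — and are not
tuned per run. The default benchmark mixes 120 matched-topology and 80
opposite-topology decoys (200 total).

Contact predictions derive from the jitter-free class template: every
representative-atom pair within 8 Å at separation ≥ 5 becomes a contact
with confidence decreasing linearly in distance (1 → 0.1 at the cutoff)
plus seeded jitter, contaminated with 10% random false positives at low
confidence — enough to keep the filtering task nontrivial while leaving
exact oracles available at a 0% rate. Titrations are generated from either
the Hill closed form (defaults h = 1, k½ = 10 µM, A₀ = 0.40, ΔA = 0.35) or
the full equilibrium model (125 µM BCA, 50 µM Cu after mixing, protein
0.06–122 µM — the experimental dilution span), with Gaussian noise of 2% of
the amplitude by default. Every generator is a pure function of spec + seed.

What the synthetic data does not emulate: real decoys have packed side
chains, nonideal helix geometry, membrane-slab constraints, and correlated
(not i.i.d. Gaussian) coordinate errors; real contact predictors err with
sequence-dependent structure rather than uniform false positives; real
titrations carry pipetting-correlated rather than independent noise.
Passing benchmarks therefore demonstrates the pipeline's discriminative and
statistical behavior under controlled conditions, not folding accuracy on
real ensembles.

## Problem sizes

The bundled benchmark uses 200 decoys of 98 residues, ~140 contacts, and
200-replicate fit simulations — sizes chosen so the full analysis chain
(including all-vs-all superposition of the retained set and SASA over the
largest cluster) completes in seconds while leaving all thresholds
expressed as ratios or z-scores that transfer to larger pools.

## Known limitations

- The PDB reader is deliberately strict (single chain, no insertion codes,
  ATOM records only) — it targets clean decoy files, not the full wild PDB.
- TM-score seeding is heuristic; agreement with the exhaustive-seed oracle
  is asserted at small L, but pathological equal-length pairs could in
  principle find different local optima.
- SASA rotation invariance is approximate at fixed lattice resolution (see
  above); increase `n_points` where tighter invariance matters.
- The Hill and equilibrium routes describe the same data only approximately
  (the Hill form is a phenomenological summary of the mass-action curve);
  both are exposed and reported side by side rather than reconciled.
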