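# Methods

## Response-surface model

The design module targets the standard second-order response-surface
workflow for a three-factor degradation experiment. Factors are coded so
that the low/center/high physical levels map to −1/0/+1; the default
factors are temperature (20/30/40 °C), pH (5/7/9) and inoculum biomass
(0.1/0.2/0.3 g L⁻¹). Coding is affine from the endpoints; if a factor's
center is not the midpoint the map is piecewise affine on either side of
the center and a warning is raised, since an asymmetric coding changes the
interpretation of the quadratic terms.

The Box-Behnken generator supports exactly three factors: 12 edge runs
(every ±1 pair over the three factor pairs, remaining factor at 0) plus
`n_center` replicated center runs. Runs are emitted in canonical
pair-block order — (x1,x2) block, (x1,x3) block, (x2,x3) block, centers —
which is documented but statistically irrelevant: OLS estimates do not
depend on run order, and randomization of execution order is a lab-bench
concern outside this package.

Fitting is ordinary least squares on the full 10-term model (intercept,
three linear, three quadratic, three interaction terms), delegated to
statsmodels; R² = 1 − SSE/SST and per-coefficient t tests use the residual
degrees of freedom of the fit. No lack-of-fit partitioning is attempted —
with three center replicates the pure-error estimate has only two degrees
of freedom and adds little. A rank-deficient model matrix raises an error
naming the collinear columns (detected by incremental rank growth).

Interaction pruning is backward elimination restricted to interaction
terms: the least-significant interaction with p ≥ α is dropped and the
model refitted, until none remain. Main effects and quadratic terms are
never dropped, following the common practice of retaining designed
factors even when individually non-significant. Because the pruned model
is nested in the full one, R² can only decrease; on the bundled
experiment the drop is < 0.001 because the pruned interactions are
essentially zero.

The stationary point solves 2Bx = −b over the free factors, where b holds
the linear coefficients and B has βᵢᵢ on the diagonal and βᵢⱼ/2 off it.
Factors may be held fixed (e.g. the non-significant biomass at its center
level); fixing substitutes the fixed coordinates into the surface, which
shifts the restricted linear term by the corresponding cross-term
contributions. Classification uses the eigenvalues of the restricted B
with tolerance `max(1e−8·max|λ|, 1e−10)`: all eigenvalues below −tol is a
maximum, above +tol a minimum, mixed a saddle, and any |λ| ≤ tol is
degenerate, in which case coordinates are withheld and ridge analysis is
recommended rather than reporting an unstable solve.

On the bundled 15-run table the fitted surface's stationary point (biomass
fixed at 0) is a maximum at coded (0.648, 0.632) with predicted response
5.98 mg L⁻¹ — above the 5 mg L⁻¹ dose. This is expected behavior, not a
defect: the observed response is ceiling-limited (all three center runs
degrade the full dose), so the quadratic fit is nearly flat on top and
the peak location is weakly identified. The package reports the computed
point as-is; predictions can optionally be clamped to [0, dose], off by
default so that the reported surface is the actual fit.

## Isotope accounting

Delta notation is converted by R = (δ/1000 + 1)·R_std and
F = R/(R + 1); the default reference ratio is 0.0112 (the rounded VPDB
value used in this workflow); the conventional 0.0111802 is available as
`VPDB_CONVENTIONAL`. δ values ≤ −1000 ‰ are rejected (atom fraction would
leave [0, 1)). The conversions are mutually inverse to better than
1e−10 ‰ across δ ∈ [−900, 10000] ‰, covering both natural-abundance and
heavily labeled material.

Per-PLFA excess ¹³C is (F_labeled − F_unlabeled)·[PLFAᵢ] in mg C kg⁻¹;
percent of added label divides by the ¹³C dose, and the distribution
normalizes positive excesses to 100%. A negative excess (labeled culture
isotopically lighter than the control) is physically impossible for a
labeled treatment and is treated as a measurement anomaly: it is kept in
the per-PLFA output with a flag and warning but excluded from the
distribution denominator. If no PLFA shows positive excess, a distribution
is undefined and an error is raised.

The ¹³C dose delivered by uniformly labeled ¹³C₁₂-triclosan is computed
from the molecular formula C₁₂H₇Cl₃O₂ with atomic masses ¹³C = 13.00335,
¹²C = 12.000, H = 1.008, Cl = 35.453, O = 15.999 g mol⁻¹: a 5 mg L⁻¹ dose
carries 2.588 mg ¹³C L⁻¹. Concentrations per kg of solution are treated as
equal to per liter at density 1.0 kg L⁻¹ unless converted by the caller.

The headspace CO₂ label percentage defaults to the ratio convention
100·¹³CO₂/¹²CO₂ (under which equal amounts read 100%); an atom-percent
variant 100·¹³C/(¹³C+¹²C) is available behind a flag, since published
"¹³C/¹²C percentage" figures are ambiguous between the two.

## Degradation bookkeeping

Percent removal is 100·(c₀ − c_t)/c₀, clipped at 0 with a warning when the
residual exceeds the dose. Time-to-threshold linearly interpolates the
concentration series to the first crossing of `remaining_fraction × c₀`
and returns infinity ("not reached") otherwise; no kinetic model is
fitted — the workflow's claims are interpolation-scale, and imposing
first-order kinetics would add assumptions the data cannot check here.
"Complete" degradation defaults to a remaining fraction of 0.01.

Cell-surface hydrophobicity is the MATH-assay index (I − F)/I from
aqueous-phase OD₆₀₀ before and after hydrocarbon partitioning; negative
values are returned but flagged. Complete dechlorination of triclosan
releases 3 Cl⁻ per molecule, i.e. 3·35.453/289.536 ≈ 0.3675 mg Cl⁻ per mg
TCS; `chloride_balance_check` compares measured chloride to this bound
within a relative tolerance (default 10%) and reports consistent /
over-release / under-release.

## Synthetic data

Each generator is the algebraic inverse of its analysis, so noise-free
round trips are exact and tests can assert recovery to numerical
precision rather than against tuned fixtures.

* **Surface**: response = polynomial(coded run) + N(0, σ), σ = 0.1 mg L⁻¹
  by default (a realistic replicate scatter for HPLC-quantified residues
  at a 5 mg L⁻¹ dose). The default true coefficients are those fitted to
  the bundled experiment, so simulated tables resemble the real one.
  Truncation to [0, dose] is available but off by default because
  censoring biases coefficient recovery.
* **Labeling experiment**: for each PLFA, implied excess = fraction ×
  added ¹³C; the labeled atom fraction is the natural-abundance baseline
  (δ = −25 ‰, typical heterotroph biomass) plus excess/pool, converted
  back to δ. Gaussian δ noise (default 0.3 ‰, a typical IRMS replicate
  precision) is applied independently to both treatments. Defaults mirror
  the five diagnostic PLFAs of the degrader strain (14:0 2OH, 16:0, two
  summed features, 16:1 w5c) with incorporation fractions 0.0699, 0.0837,
  0.1384, 0.159 and 0.1648 — totaling 61.58% of the added label — and
  plausible lipid-carbon pools of 0.8–2.5 mg C kg⁻¹. A spec whose label
  load would push an atom fraction to 1 is rejected as infeasible.
* **Trajectories**: substrate follows a scaled logistic decay that equals
  the dose exactly at t = 0 and `residual_fraction` (default 0.005) of the
  dose exactly at the completion time (default 72 h); OD grows
  logistically to its plateau; CSH is a beta-shaped pulse, zero at t = 0,
  peaking at (48 h, 0.76) by default. The pulse family is a documented
  convenience — any smooth unimodal curve would serve; nothing downstream
  depends on its exact shape.

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible given the seed.

What passing tests show — and do not. The generators emulate the
*statistical structure* the analyses assume: homoscedastic Gaussian noise,
exact design geometry, a single well-mixed label pool per lipid. Real data
additionally carry run-order effects, heteroscedastic instrument error,
isotope fractionation during lipid synthesis, and PLFA quantification
error, none of which are modeled; recovery results here validate the
arithmetic and the estimators, not robustness to those effects.

## Numerical choices

* Eigenvalue classification tolerance: relative 1e−8 with absolute floor
  1e−10 (guards against calling a ridge a maximum).
* Coding round-trip accuracy: exact to 1e−12; extrapolation beyond ±1 is
  permitted but warned about.
* The brute-force grid oracle used in tests evaluates the fitted surface
  on a 1e−3 grid over the coded square; canonical-analysis coordinates are
  required to agree within 2e−3 (one grid step each way).
* Monte-Carlo sizes in the test suite: 200 replicates for surface
  coefficient recovery, 500 for label-incorporation recovery — enough to
  bound the standard error of the mean well below the assertion bands
  while keeping the suite fast.
* Reports serialize numbers at full precision in JSON; the text rendering
  rounds to 4 significant figures for display only. Report files are
  written atomically (temp file + rename) so a failure never leaves a
  partial report.

## Known limitations

* Box-Behnken generation is limited to three factors; central-composite
  and larger designs are out of scope.
* No lack-of-fit ANOVA and no kinetic (first-order/Monod) model fitting.
* The distribution-of-label percentages depend on which PLFAs are deemed
  labeled; the negative-excess exclusion rule is a convention, and
  borderline PLFAs near zero excess can flip between runs at high noise.
* Chloride balance assumes complete dechlorination; partial dechlorination
  pathways release less chloride and will read as "under-release".
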