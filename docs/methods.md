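# Methods

## The progression model

Functional decline is modelled as a symmetric logistic state transition from
full health (ALSFRS-R 48) to complete functional loss:

    cFS(t) = 48 / (1 + exp((t − D50) / dx)),   t in months since symptom onset.

Only the model's anchors are canonical — the upper asymptote of 48 points,
half functionality (24 points) exactly at `t = D50`, and `dx` acting as the
time constant of the decline. The closed form above is the unique symmetric
logistic satisfying them and is adopted as this package's definition; the
same holds for `rD50(t) = t / (2·D50)`, reconstructed from its two stated
anchors (0 at onset, 0.5 at D50). Derived quantities:

* `cFL(t) = −d cFS/dt = (48/dx)·σ(1−σ)` with `σ = expit(−(t−D50)/dx)`,
  reported as a positive loss rate (points/month); peak `48/(4·dx)` at D50.
* Phases from rD50 with half-open intervals, boundary to the later phase:
  I `[0, 0.25)`, II `[0.25, 0.5)`, III/IV `[0.5, ∞)`. Phases III and IV are
  never separated and are kept as a single merged label.
* Aggressiveness: high iff `D50 < 30` months (strict).

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective), bounds `D50 ∈ [0.5, 200]`, `dx ∈ [0.25, 100]` months,
parameter tolerance 1e-10. Initialisation: D50 from linear interpolation of
the score-24 crossing of the observed series (fallback 1.5× the last
observation time), `dx₀ = D50₀/2.5` (a typical cohort D50/dx ratio); three
deterministically jittered starts (×1, ×0.5, ×1.8) guard against local
minima. A record that never leaves 48 carries no decline signal: the fit is
returned at the heuristic start with `converged=False` rather than letting
the optimiser run off along the D50 axis. Fewer than two distinct
assessment times is an error.

Cohort reliability filtering drops, with separate reason codes, patients
with fewer than 2 ALSFRS-R scores, failed/non-converged fits, and fitted
D50 above 100 months. The two published exclusion conditions are read as
independent OR-ed criteria. An ALSFRS-R assessment is "paired" to the MRI
when it lies within 10 days (10/30.4375 months; the month constant is the
mean Gregorian month); an equidistant earlier/later tie resolves to the
earlier assessment, the pre-MRI state being causally prior.

Estimator shape: the fitter is exposed as a scikit-learn style estimator
(`D50CurveModel.fit(t, scores)` with fitted attributes `d50_`, `dx_`,
`rss_`, `converged_`), with `fit_d50` as its functional wrapper; the
permutation engine likewise has a `PermutationTFCE` estimator over
`permutation_maxtfce`.

## Voxel-wise inference

Per skeleton voxel an OLS GLM is fitted; the contrast t statistic is
`t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)` on `n − rank(X)` degrees of freedom.
Group factors are cell-means coded (one indicator per level, contrast
`[1, −1, 0…]`); continuous covariates are mean-centred by default (the
original convention is unstated; centring is configurable). Zero-residual-
variance voxels get `t = 0` with a logged warning rather than propagating
non-finite values.

**TFCE.** `TFCE(v) = Σ_h e_v(h)^E · h^H · dh` over thresholds
`h = dh, 2dh, … ≤ max(stat)`, with `e_v(h)` the voxel count of the
connected component (`stat ≥ h`) containing `v`. Defaults `E = 0.5`,
`H = 2`, 26-connectivity, `dh = max(observed stat)/100`; a skeleton-
optimised preset (`tbss_tfce_params()`: `E = 1`) matches standard TBSS
tooling. The integration step derived from the observed map is reused for
every permutation so all maxima share one enhancement scale. Negative
statistic values contribute nothing; each direction of a contrast is its
own one-sided run on the negated contrast, mirroring how increases and
decreases are reported separately in TBSS practice, with no cross-direction
correction beyond that.

**Permutation FWE.** Freedman–Lane: data are residualised against the
nuisance columns (zero contrast weight), residual rows are permuted, the
nuisance fit is added back and the full model refit;
`p_FWE(v) = (1 + #{null max ≥ TFCE(v)}) / (n_perm + 1)` — the +1 guarantees
validity and a p floor of `1/(n_perm+1)` (hence α = .001 tiers need
≥ 1000 permutations). When the requested count reaches the number of
distinct relabelings (two-group designs without nuisance: `C(n, n₁)`;
otherwise `n!`), exhaustive enumeration replaces sampling and the p-values
are exact. All randomness flows through one `numpy` `default_rng(seed)`;
recipe runs derive per-metric/direction seeds by fixed offsets so results
are reproducible run to run.

## The analysis battery

Built-in recipes follow the study design conventions: age and sex are
nuisance covariates in every design; the phase contrast adds D50, the
aggressiveness contrast adds cFS and onset type; significance tiers are
α = .001 (case–control and whole-cohort regressions), .05 (subgroup
contrasts and within-phase regressions) and .01 (regressions in the
MRI-paired subcohort, including ALSFRS-R and the linear progression rate
PR = (48 − ALSFRS-R)/duration). The phase contrast excludes Phase III/IV
patients by default; the `include_phase3` flag reproduces the sensitivity
variant, folding them into the later-phase arm. Between-group demographic
tables dispatch Student's t / Mann–Whitney U by a Lilliefors normality
screen and chi-square for categorical variables; cohort summaries likewise
switch mean±SD vs median±IQR on the same screen.

## The synthetic generator

Defaults encode the clinical structure of a mid-size single-centre ALS
cohort: 145 patients + 69 controls; D50 lognormal with log-median ln(28.8)
and log-SD 0.52 (matching a 28.8-month median with a ≈20.6-month IQR);
`dx = D50/2.54 · exp(N(0, 0.25))`; 4–10 visits starting 2–8 months after
onset at 1–4-month intervals; integer scores = round(curve + N(0, 1.5))
clamped to [0, 48]; MRI time drawn so rD50 at MRI ≈ truncated N(0.28, 0.13)
on [0.05, 0.7], which lands roughly 40%/55%/5% of patients in Phases
I/II/III+.

The DTI phantom carves four disjoint tubular "tract" regions (`cst_like`,
`callosal_like`, `frontal_assoc`, `cerebellar_like`) into a grid, assigns
tract mean FA 0.55 over a 0.12 background and takes the skeleton mask as
mean FA > 0.2. Per subject, tract eigenvalues are
`(L1, L2, L3) = (1.7, 0.4, 0.3)×10⁻³ mm²/s` — arbitrary but
literature-typical white-matter values — plus i.i.d. Gaussian noise
(SD 0.08×10⁻³ per eigenvalue). Planted effects shift the eigenvalue
combination that drives the target metric (AD via L1, RD/FA via L2+L3, MD
via all three) by `magnitude × noise SD × driver`, the driver being a
patient indicator or a covariate standardised within patients; ordering
violations are clipped back to `L1 ≥ L2 ≥ L3 ≥ 0`. Scalar maps follow the
standard definitions (AD = L1, RD = (L2+L3)/2, MD = trace/3, FA the
normalised eigenvalue dispersion, 0 for null tensors).

What the generator does **not** model: MR physics and acquisition noise
correlations, partial-volume and registration error, spatially correlated
noise, skeleton projection itself, and any real-cohort effect sizes —
planted magnitudes are free benchmark parameters. Passing tests therefore
demonstrate the statistical machinery (calibration, localisation,
recovery) under idealised independence assumptions, not anatomical
fidelity on real data.

## Benchmark and validation sizes

The seeded benchmark uses 40 patients + 40 controls on a 32×32×12 grid
(≈ 236 skeleton voxels) with a group-driven FA decrease (magnitude 1.5,
`cst_like`, 80 voxels) and an AD elevation growing as D50 falls (magnitude
1.2, `frontal_assoc`, 96 voxels), analysed with 1000 permutations —
enough for the α = .001 tier while keeping a full validation run in
minutes on one core. Validation properties: noiseless fits recover (D50,
dx) to 1e-6; noisy recovery (200 patients, 1.5-point noise) reaches < 10%
median relative D50 error; TFCE agrees with a brute-force per-threshold
flood-fill oracle to 1e-9; exhaustive permutation p-values equal
all-relabelings enumeration exactly; the family-wise error rate over 500
global-null simulations (20 subjects × 200 voxels × 200 permutations) sits
inside the binomial 95% CI of 0.05 (observed 0.050); planted effects are
recovered with Dice 1.0 and the unplanted symptom-duration regressor
yields no findings.

## Known limitations

* The exact optimiser and constraints of the original D50 implementation
  are unpublished; only the closed-form anchors are certain, so fitted
  parameters may differ in edge cases (very sparse or non-monotone
  records).
* rD50 is evaluated at arbitrary t ≥ 0 without recalibration beyond the
  last observation; whether the original scale permits that is unstated.
* Permutation exchangeability assumes independent subjects — no repeated-
  measures blocks, variance smoothing, or spatial autocorrelation
  modelling.
* Atlas reporting uses the synthetic region names; no real white-matter
  atlas lookup is included.
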