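# Methods

## Problem and model

A DNA-methylation aging clock trained on blood predicts chronological age
(CA) from a vector of beta values. Applied to saliva or buccal swabs —
mixtures of epithelial cells (Epi), immune cells (IC) and a small
fibroblast component (Fib) — the clock's error explodes, because the
epigenetic state of epithelium differs from blood both in baseline
methylation and in its apparent pace of aging. `clockshift` adapts such a
clock to saliva without retraining it, in two stages:

1. **Reference-based deconvolution.** Each bulk profile is decomposed
   against a reference matrix `H` of pure-cell-type beta signatures over
   marker probes, yielding per-sample fractions `(Epi, Fib, IC)` on the
   unit simplex. Two standard estimators are implemented:
   * *RPC (robust partial correlation)*: a Huber-loss robust regression
     (IRLS, tuning constant 1.345 for 95% Gaussian efficiency, intercept
     included, max 100 iterations, coefficient tolerance 1e-8) of the
     bulk vector on the columns of `H`; negative loadings are truncated
     to zero and the vector renormalized to sum 1. Samples whose loadings
     are all non-positive get uniform fractions and are flagged.
   * *CP (constrained projection)*: `min_w ||y − Hw||²` subject to
     `w ≥ 0`, `Σw ≤ 1`, then renormalization to sum exactly 1 (flagging
     samples whose constrained total was below 0.5). The QP is solved
     exactly by enumerating KKT active sets — with `K` cell types there
     are at most `2^K · 2` candidate systems, so for the 2–6 cell types
     this tool targets the enumeration is both exact and faster than an
     iterative solver, with no convergence tolerance to pick.
   RPC is the default estimator; CP is kept as a cross-check because the
   two respond differently to reference misspecification. Missing betas
   (detection-p holes) are dropped per sample rather than imputed:
   deconvolution is an independent per-sample regression, so deletion is
   unbiased under missing-at-random.

2. **Prediction adjustment.** Four correction schemes, each a small
   linear model fitted with elastic net (scikit-learn parameterization):
   * `none` — identity;
   * `simple` — CA ~ prediction;
   * `delta` — (prediction − CA) ~ Epi + IC, and the fitted residual is
     subtracted from the raw prediction;
   * `total` — CA ~ prediction + Epi + IC.
   `simple` and `total` can be fitted in transformed-age space: ages and
   predictions pass through the piecewise map `f(x) = ln((x+1)/21)` for
   `x ≤ 20` and `(x+1)/21 − 1` above, and outputs return through `f⁻¹`.
   The transform makes childhood errors count on a relative scale, which
   matters for cohorts spanning infancy to old age. The knot (20) and
   scale (21) are fixed.

Hyperparameters are selected by grid search over
`l1_ratio ∈ {0.00, 0.01, …, 0.99}` and
`alpha ∈ {1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0, 1, 10, 100}`, scored by the
**pooled** mean absolute error over leave-one-study-out (LOSO) folds —
every fold holds out one entire study, testing cross-cohort transfer,
which is the failure mode that matters for public-repository data.
`alpha = 0` is fitted as ordinary least squares (penalized fitters reject
it), and the l1_ratio axis collapses to a single candidate there. Ties
resolve to the earliest candidate in grid order, making selection
deterministic. After selection the model is refitted on all training
samples. Features are **not** standardized by default: the published
coefficient sets are on natural scales and reproducing their magnitudes
requires raw-scale fits (a flag enables standardization for exploration).

Sign convention for `delta`: since the residual is defined as
prediction − CA, subtracting the fitted residual pulls an over-estimating
clock down. This is the only convention that reduces error; the opposite
sign is available (`--delta-sign add`) for sensitivity analysis.

The published total-age coefficient sets are exposed directly
(`published_total_age_model`): in transformed space
`(0.93, −1.14, 1.05, −1.18)` for (prediction, Epi, IC, intercept), in
years `(0.85, −11.54, 10.56, −15.76)`. The untransformed set implies a
fully epithelial sample is over-aged by `11.54 + 15.76 = 27.3` years
independent of the raw prediction — the quantity `scripts/acceptance.py`
recomputes.

## Evaluation

`evaluate_schemes` scores the six scheme variants plus a median-age
baseline. For each variant, hyperparameters are chosen once by LOSO grid
search on the training studies; the reported CV MAE is the pooled LOSO
error at the selected point (per-fold refits at fixed hyperparameters),
and the holdout MAE comes from the full-train refit applied to held-out
studies. Pooling residuals before averaging (rather than averaging
per-fold MAEs) weights every sample equally; per-fold averaging is
available behind a flag. The report is a pure function of its inputs.

The gain analysis mirrors the accuracy-versus-composition question: per
sample, gain = |raw − CA| − |adjusted − CA| (positive = improvement),
regressed by OLS on the IC fraction, reporting slope, intercept, R²,
Pearson r, and the share of samples the adjustment worsened. The signed
gain is the default response; the absolute adjustment magnitude
|adjusted − raw| is available as a variant.

## Synthetic cohort generator

The generator emulates the structure of public saliva/buccal methylation
collections so the whole pipeline is testable offline:

* **Reference**: bimodal (array-like) pure-cell-type betas over marker
  probes; 60% of probes are discriminative with inter-cell-type
  separation ≥ 0.3, so deconvolution is well-posed.
* **Cohort**: 3 studies × 60 samples by default; ages uniform on
  (1, 90) years; per-study Dirichlet fractions with concentrations
  (17, 1, 2), (10, 1, 9), (3.2, 0.8, 16) for (Epi, Fib, IC), giving
  study-mean IC ≈ 0.10, 0.45, 0.80 — the wide inter-study spread seen
  across public studies — with a small fibroblast component throughout.
  Bulk = fraction-weighted mixture of cell-type profiles + truncated
  Gaussian noise (sd 0.02 on the beta scale), clipped to [0, 1].
* **Age signal**: clock probes drift linearly in transformed age
  (baselines in (0.36, 0.64), |slopes| in (0.01, 0.04) per transformed
  unit, random sign), deliberately linear in `f(age)` rather than raw age
  so the transformed adjusters have a correct-specification regime and
  the transformed-versus-raw comparison is meaningful. Ranges keep the
  signal unclipped across the default age span.
* **Domain gap**: relative to the clock's (blood-like) training domain,
  epithelial profiles drift faster by `epithelial_aging_factor` (default
  1.4) and the saliva compartments read pre-aged by constant shifts in
  transformed-age units — 1.0 for the whole saliva domain plus 1.6 extra
  for epithelium, both scaled by (factor − 1) so that factor = 1 is a
  clean no-effect control. The balance of a mild multiplicative rate
  effect plus strong additive offsets is what the published adjustment
  coefficients themselves imply when inverted (prediction − CA ≈
  0.18·CA + 13.6·Epi − 12.4·IC + 18.5): at these defaults a pure
  epithelial adult reads ≈ 30–35 years too old and a pure immune-cell
  saliva sample ≈ 8 years too old. A purely multiplicative rate effect
  large enough to produce such offsets would instead make the bias an
  age×composition interaction, which no composition-only correction
  could remove — unlike what is observed on real data.
* **Stand-in clock**: elastic net (alpha 1e-3, l1_ratio 0.5) of
  transformed age on clock-probe betas, trained on 300 synthetic pure-IC
  blood-domain profiles; predictions return through `f⁻¹`. It is
  accurate in its own domain (held-out pure-IC MAE ≈ 1 year) and
  over-ages epithelial-rich bulk, reproducing the phenomenon the
  adjustment exists to fix.

Everything is deterministic under a fixed seed; clock-probe parameters
derive from the config seed alone so clocks and cohorts generated from
the same config are mutually consistent.

**What the generator does not emulate**: Illumina probe chemistry and
type-1/type-2 probe effects, batch and normalization artifacts, sex
chromosomes, realistic probe-probe correlation, non-uniform age
distributions per study, and reference misspecification (the cohort is
generated from the same signatures used for deconvolution, apart from
noise). Passing tests therefore demonstrate the pipeline's correctness
and the qualitative mechanism, not real-data error magnitudes: the
printed real-data MAEs are properties of the GEO cohorts and are not
reproduced here.

## Numerical choices and degenerate inputs

* Beta values outside [0, 1] by ≤ 1e-9 are clamped; farther out is a
  validation error naming the offending probe/sample.
* Fraction rows must sum to 1 within 1e-4 on read; estimators always
  return rows summing to 1 within 1e-6.
* Probe intersection requires at least `max(10, 2·K)` shared probes.
* Collinear references are rejected (rank check) rather than silently
  regularized.
* Constant inputs where a variance is required (R², Pearson r, the gain
  regression) raise rather than returning NaN.
* The boundary age 20 is assigned to the logarithmic branch; both
  branches agree there so the choice is observationally irrelevant.

## Problem sizes

Defaults were sized so a full simulate → deconvolve → fit → evaluate
round on one CPU takes well under a minute: 400 probes (120 marker, 200
clock, 80 filler), 180 samples, 801-point hyperparameter grid per scheme
variant. These sizes are comfortably past the regime where the estimators'
behavior stabilizes; larger cohorts sharpen the same conclusions.

## Known limitations

* The delta scheme's features (Epi, IC) exclude Fib by default because
  Epi + Fib + IC ≈ 1 makes the full triple collinear; `include_fib`
  opts in.
* The transformed delta variant is intentionally not offered (the
  residual is defined in years; mixing spaces has no clean
  interpretation).
* Grid-search scoring uses MAE; MSE or R² selection could pick different
  hyperparameters, though for these 1–3 feature models the differences
  are small.
* The CP active-set enumeration is exponential in the number of cell
  types; beyond ~10 cell types an iterative QP solver would be needed.
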