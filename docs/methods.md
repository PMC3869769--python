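# Methods

This note documents the statistical models, numerical choices and known
limitations of the melres pipeline, in the order the pipeline runs.

## Synthetic study generator

The generators in `melres.simulate` produce data with the structure the
pipeline assumes, not a biological model of myeloma.

**Cell-line panel.**  Log-scale expression entries are i.i.d. standard
normal, probes × lines.  A planted support of `support_size` probes
carries weights of magnitude `effect_scale` with alternating signs, and
`gi50 = wᵀx + N(0, noise_sd)` per line, with the intercept fixed at zero
(log-concentration units are arbitrary).  The recorded `true_weights`
exist only so recovery tests can compare against ground truth.

**Trial cohorts.**  Expression is again i.i.d. standard normal.  The PFS
event hazard is `λ·exp(η)` with `η = wᵀx` (proportional hazards,
exponential baseline); overall survival uses rate `0.5·λ` and linear
predictor `0.5·η`, so both endpoints share the effect direction with OS
events rarer and effects attenuated — purely a fixture convention.
Censoring is an independent exponential at `censoring_rate` (0 means no
censoring); the observed time is the minimum, and the event indicator
marks whether the event came first.  In `null_mode` the hazard ignores
expression entirely, giving a negative-control cohort in which any
apparent prognostic separation of the index is spurious.  Clinical
covariates are drawn independently of expression — age uniform on
[35, 69] years, sex Bernoulli(0.55 male), ISS stage multinomial
(0.39, 0.36, 0.25) — so "RI independent of ISS" holds by construction in
default scenarios; `correlated_iss=True` skews the upper
linear-predictor tertile toward stage III for robustness studies.

**Defaults and units.**  Time is in months throughout.  Defaults mirror
the targeted study design: an 18-line panel, a 19-probe support, a
94-patient training and 263-patient validation cohort (the CLI also
generates a 156-patient negative-control cohort), baseline hazard
ln 2/27 per month (≈27-month median PFS at η = 0) and censoring 0.02 per
month (≈38% censored at the event rate above).  `n_probes` defaults to
1000 — representative structure at desk scale rather than a full 54k-probe
array.  Heavier simulation studies in the tests and the acceptance script
use 20–300 probes and 94–1000 patients per cohort, chosen so each check
exercises the asymptotic regime it relies on while the whole suite stays
cheap.

**What the generator does not emulate:** probe-level microarray noise,
batch effects, gene–gene correlation (expression is isotropic), informative
censoring, or any real myeloma biology.  Passing tests therefore
demonstrate correctness of the *pipeline machinery* under its stated
assumptions, not clinical validity of a signature.

**Determinism.**  Identical config + seed gives bit-identical output.  The
panel and cohort generators consume disjoint seeded streams
(`default_rng([seed, 0])` and `default_rng([seed, 1])`), so a panel and a
cohort built from the same seed are independent.

## Sparse PLS discovery

The threshold-and-refit SPLS variant: columns are centred and scaled to
unit variance (probes have heterogeneous variances); at each of `K` steps
the covariance direction `Z = Xᵀr` of the current residual is
soft-thresholded componentwise at `η·max|Z|`, the surviving probes join
the active set, and an ordinary PLS (NIPALS, via scikit-learn's
`PLSRegression`) fit restricted to the active set replaces the model
before deflation.  Coefficients are mapped back to the original scale.
`η = 0` reproduces standard PLS, and with `K = rank(X)` on full-rank data
the fit equals least squares; both reductions are tested.

Tuning minimises cross-validated mean squared prediction error over an
(η, K) grid with seeded shuffled folds; ties break toward larger η then
smaller K (sparser, simpler).  Defaults η = 0.5, K = 2 are configuration
choices, not estimates: the tuning that produced the published 19-gene
list belongs to the upstream screen.  Signature truncation ranks probes
by |coefficient| with exact ties broken by probe-id lexical order, and
signature files list probes in probe-id order — both purely for
reproducibility.

Support size is provably non-increasing in η only for K = 1 (later
components see η-dependent residuals), so the monotone-sparsity property
test fixes K = 1.

## Cox proportional hazards

Newton–Raphson on the partial log-likelihood with Efron's correction for
tied event times (Breslow via `ties="breslow"`; the two coincide without
ties).  Step-halving guards each iteration; convergence is declared when
the relative log-likelihood change falls below 1e-9 (within 25
iterations), followed by one polishing Newton step so coefficient error is
driven to the quadratic-convergence floor — the fit agrees with an
independently converged reference to better than 1e-6.  Failure modes are
explicit errors: constant covariate columns (named), singular information,
iteration-cap overrun, and a diverging linear predictor (|η| > 25), which
signals monotone likelihood / perfect separation.

The covariance is the inverse observed information; hazard ratios carry
Wald 95% CIs (`exp(β ± z·se)`) and Wald p-values, matching the hazard-ratio
table layout of trial reports.  The likelihood-ratio test is used only for
the spline association test below.  A covariate-free fit (p = 0) is
permitted and returns the baseline machinery only.  The baseline
cumulative hazard uses Efron-consistent increments, so martingale
residuals (`event − H₀(t)·exp(η)`) sum to zero at the MLE on tie-free
data; the formal supremum-type proportionality test is out of scope —
plain martingale residuals are provided for diagnostics.

## Kaplan–Meier, log-rank

Product-limit estimator with Greenwood variance; confidence bands on the
log(−log) scale.  The median is where the curve first drops to 0.5 and is
undefined (NaN) when it never does; its CI comes from where the
transformed band crosses 0.5.  The K-sample log-rank test sums observed
minus expected events with the hypergeometric variance; with two groups
and no ties it equals the Cox score test at β = 0 (tested to 1e-6).

## Restricted cubic splines

Harrell's truncated-power basis: a linear term plus k−2 nonlinear terms
constructed to be linear beyond the boundary knots, normalised by the
squared boundary span.  Default four knots at the 0.05/0.35/0.65/0.95
marginal quantiles of the index.  The log relative-hazard curve is the Cox
fit on this basis, centred to zero at the cohort median RI, with
delta-method pointwise bands and a likelihood-ratio association test on
the basis dimension.  The LR test is asymptotic; its null calibration is
evaluated at 250-patient cohorts, where the chi-square approximation is
accurate at the 0.05 level.

## Time-dependent ROC

Cumulative-case / dynamic-control at horizon t: cases are events by t,
controls are event-free beyond t.  Sensitivity and specificity come from
the Kaplan–Meier/Bayes construction — subgroup survival above and below
each marker threshold, inverted through the overall curve — so censored
subjects contribute through the subgroup KM estimates; no nearest-neighbour
smoothing is applied.  AUC is the trapezoid along the threshold-ordered
curve.  Without censoring the estimator reduces exactly to the empirical
ROC and the AUC to the Mann–Whitney statistic (tested).  The estimator can
be non-monotone in finite samples; thresholds are the unique marker values
(capped at 1000 quantiles for very large cohorts).

## Resistance index, strata, evaluation

Reweighting fits one multivariate Cox model of the training endpoint on
the signature probes, unstandardised by default so the weights apply
directly to another cohort measured on the same log scale (a
standardisation flag exists; the published table's weights are used as-is).
Zero-variance probes are dropped with a warning and recorded.  The RI is
the raw linear combination — no centring or rescaling — so scoring the
training cohort reproduces the Cox linear predictor exactly.

Percentiles are cohort-internal averaged ranks × 100/n; cuts at 25 and 75
assign boundary samples downward.  Each trial is stratified within itself;
a flag allows training-derived cutpoints instead.  The merged dichotomy
pools sensitive and intermediate strata (their relative-hazard profiles
are indistinguishable in the motivating data) against the resistant
quartile.  Evaluation reports, per endpoint: per-stratum KM curves and
medians with the 3-group log-rank test; univariate Cox of the dichotomy;
a multivariate Cox adding age, sex (female reference) and ISS dummies
(stage I reference); the spline curve; and time-dependent ROC at
configurable horizons (default 12/24/36 months).  α = 0.05 throughout.

## Random-list chance control

Lists of the signature's size are drawn without replacement from the
shared probe universe (lists may overlap across draws); each is reweighted
on the training cohort, scored and stratified on validation, and its
univariate and adjusted Cox p-values recorded.  "Performed better" means a
strictly smaller p-value than the true signature's.  Lists whose fits fail
(non-convergence, degenerate stratification) are excluded from the
denominator with a logged count rather than imputed.  The drug-specificity
check scores each winning list on the cell-line panel and counts
two-sided Pearson GI50 correlations with p < α.  Note that correlations of
many lists against a single panel's GI50 vector are dependent, so the
count's variance exceeds binomial on one panel; the calibration test
spreads lists across independent panels.  Defaults: 200 lists at test
scale, 1000 at study scale.

## Design choices that were genuinely open

- Event-time law: exponential baseline — the simplest law satisfying
  proportional hazards, with closed forms for the generator tests.
- Tie handling: Efron default (the reference environment's default),
  Breslow available.
- Table p-values: Wald (the trial-table convention); LR reserved for the
  spline association test.
- tdROC variant: any consistent cumulative/dynamic estimator is
  acceptable for the property-based checks; the KM/Bayes form was chosen
  for its exact no-censoring reduction.
- Median CI: log(−log) band crossing (the common default).
- CLI: plain TSV/CSV only; raw array processing (background correction,
  RMA) is upstream and out of scope, as are GEO retrieval, molecular
  subtype classification, cross-platform probe mapping and
  remission-status analyses.

## Known limitations

- The survival machinery omits time-varying covariates, stratified
  baselines and interval censoring.
- The spline LR test and Wald intervals are asymptotic; very small cohorts
  (tens of events) show mild anticonservatism.
- The tdROC estimator is unsmoothed and can be non-monotone at small n.
- Synthetic cohorts cannot validate a clinical signature; they validate
  the machinery that would evaluate one.
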