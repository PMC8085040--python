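# Methods

`stabcox` implements a variable-discovery workflow for cohort survival data
with competing risks, of the kind used to screen ~100 candidate predictors of
mortality in a few hundred dialysis patients.  This note records the models,
the numerical choices, and what the synthetic test-bed does and does not
establish.

## The workflow

1. **Quintile dummy coding.**  Each quantitative predictor is replaced by two
   indicator columns: membership in the top or bottom fifth of the *total*
   study population.  The quota per group is `round(n_observed / 5)`; group
   membership is by rank, with subjects tied at the boundary value chosen
   uniformly at random to fill the quota (once per encoding call, seeded).
   Values in the middle three fifths, and missing values, contribute 0 to
   both dummies; missing nominal values fall to the reference category.  Age
   enters linearly, in decades.  Thresholding trades statistical efficiency
   for robustness to single high-leverage measurements and for capturing
   threshold-shaped risk; the spline stage (below) revisits non-linearity on
   the continuous scale.  Computing thresholds on the total cohort — before
   the derivation/confirmation firewall — is a deliberate reproduction of the
   workflow being modelled; the boundary-subject leakage this creates is
   negligible but real, and a negative-control test documents that the two
   threshold sources genuinely differ.

2. **Matched split.**  1000 uniformly random 2/3:1/3 splits are scored by
   balance tests on the matching variables (chi-squared for nominal,
   Mann-Whitney for quantitative; the five mortality indicators — all-cause,
   three causes, one-year — always tested as 2x2 tables).  The split with
   the largest minimum p-value wins (maximin; ties to the first).  The
   derivation size is `round(2n/3)` (317 of 475).

3. **Elastic-net Cox with two-level CV.**  The penalized objective is

       -(1/n) * Breslow log partial likelihood
           + lambda * sum_j m_j * ( alpha*|b_j| + (1-alpha)/2 * b_j^2 )

   solved by iteratively reweighted least squares with cyclic coordinate
   descent, warm starts along a log-spaced lambda path from `lambda_max` (the
   smallest all-zero penalty, computed from the null-model score) down to
   `lambda_min_ratio * lambda_max`.  Columns are standardized internally
   (unit 1/n-variance) with coefficients reported on the original scale;
   0/1 dummies are standardized too, matching the usual solver default — the
   flag is exposed because it materially affects selection.  Alpha is chosen
   on an equally spaced 15-point grid on [0, 1] by 20-fold cross-validated
   partial-likelihood deviance (Verweij–van Houwelingen: full-data minus
   leave-fold-out log likelihood at the fold-out fit), taking per-alpha the
   deviance-minimizing lambda and then the best alpha restricted to
   alpha > 0 (ridge never selects).  Fold assignments are uniform, redrawn
   if any fold has no events; with fewer events than folds, the fold count
   is capped at the event count (warned).

4. **Stability selection.**  B = 100 half-subsamples (without replacement);
   each run perturbs per-feature penalties by `m_j = 1/W_j`,
   `W_j ~ Uniform[weakness, 1]` with weakness 0.8 (a two-point variant is
   available behind a flag; the continuous draw is the default).  Selection
   frequencies are pointwise per lambda on the grid computed from the full
   derivation data.  The stable set is read at the smallest lambda whose
   average per-subsample active-set size q stays within
   `q_max = p * sqrt(pcer * (2*pi_thr - 1))` — the Meinshausen–Bühlmann
   bound E(V) <= q^2 / ((2*pi_thr - 1) p) at a per-comparison error rate of
   10% — keeping features with frequency >= 60% there.  If q exceeds the
   bound everywhere the largest penalty is used, flagged as unattainable.
   For efficiency the subsample paths may stop early once the active set
   exceeds a cap (glmnet's `dfmax`); grid points not solved by every
   subsample are excluded from the bound scan, which is conservative.

5. **Confirmation.**  Each stable feature is tested only against the
   outcome(s) it was selected for, by univariate cause-specific Cox
   regression (Efron ties, via lifelines) on the withheld confirmation
   subjects: hazard ratio, Wald 95% CI and p, the count of non-zero
   observations, and flags (`*` p < 0.05; `#` p < 0.1 with the derivation
   effect direction).  Monotone-likelihood fits (e.g. a dummy group without
   events) are reported as degenerate rows (HR 0 or inf, CI (0, inf),
   p ~ 1), never dropped.

6. **Penalized splines.**  One covariate (transformed, e.g. ln AST) enters a
   Cox model through a cubic B-spline basis (12 functions, uniform unclamped
   knots over the observed range, so the penalty null space reproduces exact
   straight lines) with a second-order difference penalty.  The smoothing
   parameter is found by bisection so the effective df — the trace of
   `(H + lambda*P)^-1 H` over the spline block — equals 4 within 0.05; the
   search asserts monotonicity of df in the penalty.  Curves are reported as
   log-HR against the median covariate with pointwise Wald bands from
   `(H + lambda*P)^-1`.  The linearity test refers twice the unpenalized
   log-partial-likelihood difference against the nested linear fit to a
   chi-squared with `tr(2F - F^2) - 1` df (`F` the penalized projection);
   the usual `tr(F) - 1` reference measured anti-conservative (7.8% type-I
   at nominal 5% over 1000 linear-truth replicates) while the `tr(2F - F^2)`
   scale sits inside the Monte-Carlo band.  Penalized LRTs are approximate
   either way and the output says so.  A documented outlier rule
   (conjunction of per-variable cutoffs, e.g. AST > 600 AND ALT > 900)
   can drop subjects before spline fits, with a removal log.

7. **Time-dependent AUC.**  Discrimination is incident/dynamic: at each
   event time, cases are subjects dying exactly then, controls those still
   at risk after, ties counting 1/2.  Out-of-sample curves come from 1000
   bootstrap resamples: fit the Cox model on the resample, score the
   out-of-bag subjects, evaluate the AUC at their event times, assign each
   value to month `ceil(t)` and average within months over all (rep, time)
   contributions.  Multivariable models with missing predictors use M = 25
   marginal random imputations (each missing cell drawn uniformly from the
   variable's observed values), bootstrapping within each imputation and
   averaging the per-imputation curves with equal weight (the per-imputation
   curves are retained).  Resamples with a monotone likelihood fall back to
   a weak ridge so the rep still scores; true fit failures are skipped and
   counted, with more than 20% failures an error.  The raw rank-based AUC
   estimator is used, with no smoothing before monthly averaging.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions the workflow assumes:

- n = 475 subjects; ~104 predictors in correlated blocks (equicorrelated
  Gaussian copula within a block, independent across blocks): 30 nominal
  comorbidity-style indicators (prevalences 0.15 / 0.35, correlation 0.2),
  60 log-normal laboratory values (correlations 0.3-0.4), 12
  detection-limited cytokines (log-mean -0.5, log-sd 1.2, LOD 1.0 pg/mL, so
  ~66% of subjects fall below the limit — stored as 0 with a below-LOD
  flag, which is an assay floor, not missingness), one age-like and one
  IL-6-like matching variable.
- Three competing death causes from cause-specific exponential hazards
  `lambda_k * exp(x' beta_k)` (latent clocks, minimum wins), plus an
  independent dropout clock and administrative censoring at 48 months.
  Baseline hazards (0.003644, 0.001752, 0.003626 per month) and the dropout
  rate (0.003694) were calibrated once, against the closed-form
  competing-exponential integral averaged over a large covariate draw, so
  expected observed mortality is ~35.5% split 13.5/9/13% over
  cardiovascular/infection/other and ~80% of censoring is administrative.
- Planted effects: an age-like linear effect (log-HR 0.5/0.5/0.4 per latent
  SD), an infection-specific top-quintile cytokine effect (log-HR 1.1,
  matching the confirmed IL-12p70 hazard ratio of ~3.1 — deliberately
  borderline for selection at this sample size, as in the study), and a
  protective bottom-quintile (-0.7 CV/other) plus U-shape (0.3 per
  ln-unit^2) effect on one laboratory value to exercise the spline stage.
  U-shapes are quadratics in the ln-value centred at its median.
- Missingness is completely at random per variable (2-10%), never on the
  outcome — matching the assumption under which marginal random imputation
  is valid.

What the generator does **not** emulate: informative censoring or dropout,
time-varying covariates, measurement error in instrument-derived predictors,
realistic inter-block correlation (the real cohort's correlation structure
is unpublished; equicorrelated blocks are a modelling choice), or non-MCAR
missingness.  Passing tests therefore demonstrate that the pipeline's
statistical guarantees (error control, calibration, recovery) hold under its
stated assumptions, not that they hold on the real cohort.

## Numerical choices and degenerate inputs

- Breslow ties in the penalized solver (standard for pathwise coordinate
  descent); Efron ties in the unpenalized confirmation fits (the reported
  quantities' convention).  Solver tolerance 1e-7 on standardized
  coefficients by default; KKT residuals are machine-checkable and tested.
  `lambda_max` is nudged up by 1e-6 relative so the all-zero solution is
  strictly optimal at the first grid point.
- The coordinate-descent kernels are numba-compiled with an active-set
  cycle (full sweep, active-set iteration, full verification sweep) and
  Fortran-ordered column access.
- Simulation-scale runs (tests, the acceptance script) use a loosened
  solver tolerance (1e-5), a 50-point path and an active-set cap of 50 —
  selection patterns were verified identical to the tight settings on
  benchmark instances; the stated problem sizes (200 null cohorts at n=300,
  p=120, B=50; 50 recovery seeds; 1000 spline-calibration replicates) are
  the package's chosen simulation scales.
- Constant design columns keep coefficient 0; all-missing nominal variables
  encode as all-zero reference columns with a warning; quintile coding
  requires >= 5 observed values; cohorts must have strictly positive
  follow-up times and exactly one cause code per subject.
- Ties at quintile boundaries are randomized once per encoding call with a
  logged seed (not once per outcome run).
- The log-rank trend test uses cause-specific risk sets with equally spaced
  scores; its output metadata records that choice.
- Every pipeline stage derives its RNG from the master seed through a
  counter-based seed sequence, so stages re-run in isolation reproduce the
  full run's artifacts byte for byte.

## Known limitations

- The PCER bound is used with the pointwise average active-set size q as its
  q_Lambda, the common implementation practice; a cumulative-over-the-path
  variant sits behind a flag.
- Penalized-spline LRT p-values are approximate (see above); treat values
  near the threshold with caution.
- The bootstrap AUC refits spline smoothing per resample, which is honest
  but slow at B = 1000; reduced-B smoke settings exist for exploration.
- The CV fold assignment is unstratified by event status (redraw on
  event-free folds), matching the default of the solver family emulated;
  stratification is not implemented.
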