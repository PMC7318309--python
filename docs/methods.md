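# Methods

## The model and the two reliabilities

Patient outcomes within providers follow the one-way random-effects model

    Y*_ij = mu + alpha_i + X_ij' beta + eps_ij,
    alpha_i ~ N(0, sigma_b^2),   eps_ij ~ N(0, sigma_w^2),

for provider i = 1..m with n_i patients; large Y* means a poor outcome.
After risk adjustment (Y_ij = Y*_ij − mu − X_ij' beta) the provider mean
Ybar_i estimates alpha_i with variance sigma_b^2 + sigma_w^2/n_i.

The **inter-unit reliability** (IUR) is the intraclass-type ratio
sigma_b^2 / (sigma_b^2 + sigma_w^2/n); the overall IUR uses the effective
average size n' = (Σn_i − Σn_i²/Σn_i)/(m−1), which enters the expectation
of the between sums of squares in the unbalanced ANOVA.  Variance
components are estimated by ANOVA moments (within mean square;
between-variance solved from E(SSB) and clamped at 0), not REML: the IUR's
definition is a moment statement and the closed form keeps it transparent.

The IUR measures average discriminability, not what profiling is used
for — finding extreme providers.  The **profile IUR** (PIUR) targets that
directly.  Randomly split each provider's patients into halves A and B,
flag each half at one-sided level p with a chosen method, repeat, and pool
the empirical reflagging rate theta-hat = Pr(flagged in B | flagged in A).
Under the null model the two half-sample Z-scores are bivariate normal
with correlation rho = R/(2−R) at reliability R, giving a closed
reflagging curve G(R) per method (a ratio of a bivariate-normal rectangle
probability to a univariate tail; see `calibration`).  The PIUR is the
R~ solving G(R~) = theta-hat: the reliability a pure null model would need
to reflag that consistently.  PIUR >> IUR signals outlying providers.

## Profiling methods

* FE: Z = Ybar_i √n_i / sigma_w, flag Z > z_p.
* RE (BLUP shrinkage): Z = √(IUR_i) Z_FE, compared to z_p as constructed
  (its null variance is rho/(1−rho), deliberately not re-standardised).
* FERE: Z = Ybar_i / √(sigma_b² + sigma_w²/n_i), marginally N(0,1).
* EN (empirical null): fit N(mu_M, sigma_M²) robustly to the central FE
  Z-scores; flag Z_FE > mu_M + z_p sigma_M.  Because Var(Z_FE) = 1/(1−IUR)
  under the null, the fit also yields the outlier-robust reliability
  estimate EN-IUR = 1 − 1/sigma_M².  The EN reflagging rate is calibrated
  against the FERE curve (the two rules agree asymptotically when the
  null model is exact).

## The contamination model and the theoretical PIUR

Provider effects follow the mixture pi0 N(0, sigma_b²) + pi1 f1, where f1
places outliers at the fixed effect gamma·sigma_T
(sigma_T² = sigma_b² + sigma_w²/n'), or optionally at draws from a
half-normal shifted above a support bound C = 2 sigma_b.  For the point
mass the FERE reflagging rate has the closed form

    theta(R) = [pi0 Φ2_rho(−z_p, −z_p) + pi1 Φ(s)²]
               / [pi0 Φ(−z_p) + pi1 Φ(s)],
    s = −z_p/√(1−rho) + gamma/√(2−2R),

the Φ(s)² term because, given a fixed outlier effect, the two half-sample
scores are independent (verified here by direct Monte-Carlo).  The
theoretical PIUR feeds theta(R) back through the G_FERE inversion.

## Numerical choices

* **Bivariate normal CDF** via Owen's T function (~1e−14 absolute error);
  `scipy.stats.multivariate_normal` is the independent cross-check in the
  tests.  Exact zeros of the arguments are nudged by 1e−13 to step off
  the removable singularity of the Owen decomposition.
* **Inversion** G(R~) = theta by Brent root-finding on [0, 1−1e−9];
  tolerance 1e−8 on G (G is nearly flat near 0 at small p, so an
  R-tolerance would be meaningless there).  Rates at or below G(0) clamp
  to 0, at or above the R→1 limit to 1−1e−9, with a `clamped` marker.
* **Empirical-null fit**: truncated-normal ML with truncation limits
  fixed at median ± 2·(1.4826·MAD) of the Z-scores.  A value-based
  central window keeps enough curvature for the MLE to exist and be
  stable at moderate m while excluding one-sided outlier mass outright;
  Monte-Carlo at n ∈ {300, 1000}: mean fitted sigma 0.987–0.997, and a
  shift below 0.01 under 10% contamination at +6.  Sample-quantile
  windows (e.g. the conventional central 80%) remain available but are
  noticeably biased and occasionally divergent at n = 300, where the
  windowed likelihood's supremum can sit at sigma → ∞; such fits raise,
  and the split loops then fall back to Huber M-estimation (c = 1.345,
  iterated-MAD scale), which is logged.
* **RE curve validity**: below R ≈ 0.15 the RE flag probability
  underflows and the conditional ratio is numerically void; G_re refuses
  R = 0 (the method flags nothing at the null).

## Splitting conventions

Half-splits are uniformly random partitions into ceil(n_i/2)/floor(n_i/2)
(fair coin for the odd patient); providers under `min_split_size` (2) are
excluded and logged.  Z-scores inside halves use the realised half sizes.
Variance components for FE/RE/FERE are taken once from the full panel
(ANOVA, or supplied); the EN is refitted inside every half because half
Z-scores have a different null variance.  theta-hat pools flag events over
providers and splits and counts both conditional directions (B|A and A|B),
which are exchangeable by construction.

A single panel's theta-hat is a ratio dominated by the few providers its
flags land on (about m·p per half); repeated splits of one panel are
strongly correlated, so the per-panel estimate has a sampling SD of a few
hundredths however many splits are run.  Table-style summaries in
`reports` therefore pool reflagging counts across replicate panels before
the single inversion, and use many panels with few splits where flags are
rare.  For reduced-size reproductions the split flagging uses the known
(generator) components: the study design treats them as known, and at
m = 1000 the ANOVA estimates coincide with truth to a few percent anyway,
while at m = 300 their noise would attenuate the rate.

## Count measures

Standardized ratios O_i/E_i (mortality or readmission style) use the
Poisson null O_i ~ Poisson(E_i): exact or mid-p tail P-values, and FE-type
Z-scores (O−E)/√E or the mid-p quantile transform.  The PIUR route splits
patients with their expecteds (conserving O and E exactly), refits an
empirical null per half, and calibrates against G_FERE.  Inside the
splitter the exact-tail Z is the default: half-sample expecteds are small
and the (O−E)/√E score is right-skewed there, which would inflate the null
reflagging rate.  Facilities with E below `min_expected` (3.0, the usual
exclusion rule) cannot enter.

The synthetic O/E generator draws patient expecteds Gamma(2, 0.10)
(mean 0.2 events per patient — with ~100 patients this gives facility
expecteds near 20, the scale of annual dialysis mortality) and events
Poisson(e·exp(alpha_i)) with alpha from the contamination mixture on the
log-rate scale.

## What the generator emulates, and what it does not

The simulator reproduces the statistical structure the method is built
for: normal within-provider noise, normal-or-contaminated provider
effects, fixed or rounded-normal provider sizes (mean 100, SD 50, floored
at 10), optional covariates whose provider-level means correlate with the
provider effect (the confounding that motivates within-provider
fixed-effects estimation of beta).  It does not emulate non-normal or
heteroscedastic patient noise, time trends, informative provider size
(size correlated with quality), or covariate-driven case-mix differences
beyond the linear term — so passing tests certify the estimators under
the model's assumptions, not robustness to their violation.

## Problem sizes used in the checks

Analytic results are exact and scale-free.  Simulated table rows are
reproduced at m = 300 with replicate panels (400×6 panel×split pairs for
the noisiest zero-outlier rows, 12×25 for contaminated rows), a design
with estimator standard errors of about 0.02–0.03 — comfortably inside
the ±0.08 agreement band used at this scale.  The acceptance script reruns
the key cells at the full m = 1000 with 10–20 replicate panels.

## Known limitations

* Closed-form curves treat halves as exactly n/2; odd sizes differ by one
  patient (the empirical route handles them exactly).
* A single global empirical null is misspecified under strong size
  heterogeneity (Var(Z_FE,i) grows with n_i); quantile-stratified nulls
  (`fit_empirical_null_stratified`) are available but default to one
  stratum, which is what reproduces the published variable-size behaviour
  (including its inflated EN-PIUR at high reliability).
* Per-panel PIURs carry the irreducible ratio noise described above; for
  inference across datasets, pool reflagging counts, not PIURs.
* The RE calibration curve is numerically unusable below R ≈ 0.15.
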