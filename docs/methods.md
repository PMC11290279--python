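# Methods

## The design being simulated

A two-stage platform trial starts with a control arm (0) and two
intervention arms (A, B) and opens a third intervention arm (C) at the
start of stage two.  Each arm recruits n_j = 120 subjects in total; arm
C recruits all 120 in stage two.  Three timing settings move the stage
boundary: arm C is added after 25%, 50% (the default, "setting one") or
75% of the initial arms' recruitment.  Stage totals are fixed by design;
only the cohort/arm split of each subject is random.

Subjects are allocated by two-step simple randomization: first to a
cohort (one intervention plus control) with probabilities proportional
to integer step-one weights, then within the cohort to intervention or
control with step-two weights.  The ratios are stored exactly as
integers (e.g. stage two of setting one: cohorts 80:80:140 for A:B:C;
within cohort C, 120:20 for C:control) and normalized at use time.
Simple randomization means realized arm-stage counts are random with
the planned counts as expectations.  A replication whose dataset lacks
a cell required by some analysis is recorded as a failure for that
analysis and excluded from its summary with an exclusion count — it is
never silently regenerated.  At these sample sizes the probability of
an empty cell is negligible.

## Outcome model

Stage-one outcomes are jointly normal with per-arm means
(mu_01, mu_A1, mu_B1) and covariance sigma^2 I + sigma_c^2 11';
stage-two outcomes have means (mu_02, mu_A2, mu_B2, mu_C2) + tau and
covariance (sigma^2 + sigma_e^2) I + sigma_c^2 11', with sigma^2 = 1
throughout.  The three heterogeneity knobs:

* tau — a fixed cohort effect (step time trend) added to *every*
  stage-two arm, so it cancels in concurrent within-stage contrasts;
  values 0 and -0.5.
* sigma_c — a random cohort effect: one shared normal deviate per stage
  (variance sigma_c^2), inducing within-stage correlation; 0 or 0.38.
* sigma_e — extra stage-two residual SD (heteroscedasticity, variances
  add); 0 or 0.38.

The default sampler draws the shared deviate and i.i.d. residuals
additively, which is distributionally identical to the literal joint
normal; a direct multivariate-normal sampler is kept as `method="mvn"`
for equivalence testing.  The rank-one covariance term spans the whole
stage, not the randomization cohorts; because the same shift could
plausibly be read as per-randomization-cohort, that variant is exposed
as `cohort_effect="cohort"` but is not the default — the per-stage form
is what the printed covariances say.  Effect scenarios: S0 (all means
zero), SC.m/SC.b (stage-two control mean 0.2/0.7) and SA.m/SA.b
(stage-two arm-A mean 0.2/0.7).  The effect size 0.38 used in the power
calculation is the detectable difference at 90% power with 120 per arm
(one-sided 5%), computed by the exact noncentral-t formulation rather
than the normal approximation — exactness costs nothing.

## Testing strategies

All tests are one-sided (benefit = positive intervention-minus-control
difference) with pooled-variance t statistics under a homoscedastic
working model.  The working model is deliberately wrong under the
heterogeneity scenarios; quantifying the damage is the point.

* **T-test A/B/C** test each comparison at alpha = 5%; comparison C uses
  concurrent (stage-two) control data, **T-test C-nc** pools the
  non-concurrent stage-one controls as well.
* **Bonferroni / Bonferroni-nc**: each elementary test at alpha/3.
* **Dunnett.closed / Dunnett.closed-nc**: closed testing over all
  non-empty subsets of {A, B, C}, each subset tested by the Dunnett
  max-t statistic; ignores the two-stage structure.
* **Combination.closed**: for each subset, a stage-one Dunnett p over
  the subset with C removed (p1 = 1 when the subset reduces to nothing:
  there is no stage-one information about C) and a stage-two Dunnett p
  over the full subset are combined by Fisher's product rule — reject
  when p1 p2 <= exp(-chi2_4(1-alpha)/2), about 0.00870 at alpha = 5% —
  followed by the closed principle.

Dunnett p-values are computed from the joint multivariate-t
distribution of the contrast statistics.  Numerical route: the
correlation matrix of the contrasts is always of product form
lambda lambda' + diag(1 - lambda^2) here (the control pools are nested,
so the covariance of two pool means is sigma^2 over the larger pool
size), which allows writing P(max_j T_j <= t) as a double integral over
the shared normal factor and the chi-distributed pooled-SD estimate.
We evaluate it with 48-point Gauss-Hermite x 32-point Gauss-Legendre
quadrature (the Legendre nodes spanning the essentially full support of
the chi density, weights renormalized); this is deterministic,
reproducible to ~1e-10, and about three orders of magnitude faster than
QMC integration of the multivariate t, which matters at 5000
replications x 13 subset tests.  A seeded QMC fallback via scipy's
multivariate t handles a non-product correlation matrix, which can only
arise in the model-based variant.  Degrees of freedom pool all arms
contributing to the involved statistics, with the union of the control
pools as one group (N minus the number of groups); for stage-wise
p-values the variance is estimated within the stage alone.  The df
convention for mixed control pools is a package decision — no standard
fixes it.

Model-based testing (`model_based_tests`) re-runs the t-test /
Bonferroni / closed-Dunnett battery on theta_hat_j / SE_j from a fitted
estimation model, with the joint distribution for the Dunnett variant
taken from the model's estimated covariance of the three estimators and
its residual degrees of freedom.  How to form that joint distribution
from a fitted model is underdetermined; this construction is our
interpretation and is kept out of the headline strategy battery.

## Estimation models

Five strategies, all reporting theta_hat = (theta_A, theta_B, theta_C):

* **M0** — arm indicators only; theta_j is exactly the all-stage sample
  mean difference.
* **M.stage** — adds a stage indicator (coefficient tau_hat).
* **M.stageXA** — adds the stage-by-A interaction (eta_A).
* **M.stageXAXB** — adds both interactions; saturated over the seven
  arm-stage cells, so theta_A and theta_B are the stage-one contrasts
  and theta_C is the concurrent stage-two contrast, exactly.
* **M.new** — the pairwise trials analysis: duplicate stage-one control
  records twice (blocks A0, B0) and stage-two control records three
  times (A0, B0, C0), tag intervention records with their own block,
  fit one OLS with arm indicators plus block offsets gamma_B0,
  gamma_C0, and take standard errors from a cluster-robust sandwich
  clustered on the original subject id.  Its theta_A/theta_B equal the
  stage-weighted mean difference
  sum_k w_jk Xbar_jk − sum_k w_0k Xbar_0k with realized weights
  w_jk = n_jk/n_j, and theta_C = Xbar_C2 − Xbar_02, exactly.  (With
  full duplication gamma_B0 is identically zero — blocks A0 and B0 hold
  the same control copies — so its sandwich variance is a true zero.)

Sandwich flavour: CR0 (no small-sample correction) by default with CR1
behind a flag; point estimates are unaffected and the cluster count is
large.  Model-based p-values use the residual degrees of freedom of the
fit; a cluster-count df for M.new sits behind the same flag.  Weights
use realized counts because the least-squares identities hold only for
realized counts.

## Performance measures and truth

Rejection summaries report per-hypothesis rates for the t-test
strategies and the reject-at-least-one rate (FWER) for the
Bonferroni/closed families, each with binomial MC standard error
sqrt(p(1-p)/n) and the band nominal ± z sqrt(nominal(1-nominal)/n)
(at 5000 replications, [0.044, 0.056] around 5%).

Estimate summaries report mean, median, quartiles and
rMSE = sqrt(mean((theta_hat − truth)^2)).  The default truth is the
**stage-weighted effect with within-stage contrasts**,
truth_j = sum_k w_jk (mu_jk − mu_0k) with planned weights.  Rationale:
it reproduces every printed weighted value (−0.1, −0.35, 0.1, 0.35 at
setting one; 0.525 and 0.175 at settings two/three), makes tau cancel
within stages, and reduces to the stage-two contrast mu_C2 − mu_02 for
arm C, matching the unbiasedness statements for the pairwise analysis.
Weighting arm and control by their own weights instead would make the
truth tau-dependent for arm C; the truth mapping is configurable for
that reason.  Under heterogeneous-effect scenarios the null hypothesis
itself differs between stages, so rejection rates there are emitted but
not interpreted as error rates.

One caveat the simulations surface: the M.stageXA least-squares normal
equations tie theta_A to the stage-one contrast, so under SA scenarios
its mean estimate sits near the stage-one effect (≈ 0), not the
stage-two effect; under SC scenarios it is biased away from both the
weighted and stage-one values (e.g. ≈ −0.175 under SC.b).  The package
reports this model's behaviour empirically and does not assert a
stage-two interpretation for it.

## Problem sizes, seeding, limitations

Replication r of a run with master seed s uses
`SeedSequence(s, spawn_key=(r,))`; results are bit-identical across
runs and independent of execution order.  Headline quantities
(calibration band, inflation/deflation rates, weighted-effect recovery,
the closed-Dunnett FWER under combined heterogeneity) use the study's
5000 replications; the qualitative error-control and estimator-bias
grids use 1200–1500 replications with correspondingly widened (±4 SE)
bands, which is ample for the order-of-magnitude contrasts they check.
Under a random cohort effect the concurrent strategies become mildly
conservative (pooled variances over-estimate the relevant contrast
variance), so "controls the error rate" is checked one-sidedly against
the upper band edge.

The generator emulates the study conditions only: two discrete stages
(no continuous recruitment-time trends), no covariates, no missing
data, no interim stopping or sample-size re-estimation, normal outcomes
only.  Passing tests therefore say nothing about nonlinear time trends,
informative dropout, or binary/survival endpoints.  The conditional
error principle and inverse-normal combination are out of scope, as are
Cochran's-Q-style heterogeneity tests and Bayesian/ML approaches to
heterogeneity.
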