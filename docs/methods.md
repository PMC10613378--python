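# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `peernet`.

## Network construction

Billing rows `(physician_id, patient_id, hospital_id, date)` are tallied into
the physician x patient encounter matrix `Z = [z_ik]`. The shared-patient
projection supports two weight schemes:

- **shared-count** (default): `a_ij = sum_k I(z_ik>0) I(z_jk>0)` - each
  shared patient contributes 1 regardless of encounter multiplicity;
- **geometric-mean**: `a_ij = sum_k sqrt(z_ik z_jk)` - shared patients
  contribute more when both physicians saw them often.

Binarization uses the strict rule `b_ij = I(a_ij > a_low)`; an `inclusive`
mode (`>=`, the "minimum threshold" reading) is provided because the two
conventions genuinely differ at exact threshold ties, and we did not want to
guess a user's intent. Node order is lexicographic by physician id
everywhere, so matrices are reproducible across runs. Physician volumes by
hospital give the primary hospital `S_i` (argmax volume; ties broken by
lexicographically smallest hospital id - deterministic and reproducible), the
distinct-hospital count, and the Shannon diversity
`H_i = -sum_l p_il ln p_il` in nats (natural log; `ln R` for an equal R-way
split). The physician network window defaults to calendar 2019 and the
hospital network window to 2020-03-01..2021-05-31, both configurable.

Betweenness centrality is unnormalized geodesic betweenness on the full
(possibly disconnected) undirected graph; reported values are pair counts,
not proportions. The threshold sweep compares each cutoff's per-hospital
subnetwork-density distribution to the baseline cutoff with a two-sided
Mann-Whitney rank test; a nonparametric test was chosen because the density
distributions are heavily skewed toward 1 and no parametric family is
defensible.

## Exposures

`B` splits into `B_wi` (peers sharing the physician's primary hospital) and
`B_ac` (everything else), with `B_wi + B_ac = B` enforced as an invariant.
Exposures are row-stochastic weighted averages of peers' binary outcomes:

- **within**, `WY_wi`: reported on a 0-100 percent scale, so its odds ratio
  is per percentage point of participating peers;
- **across**, `WY_ac`: a proportion in [0, 1], step-masked before
  row-normalization - only peers at hospitals randomized at the same trial
  step or earlier are eligible. Masking *before* normalizing keeps the
  weights a proper average over eligible peers. Same-step peers are included
  (the design's "same step or earlier"), accepting residual same-step
  simultaneity.

Physicians with no eligible peers keep exposure 0 plus an explicit
`*_undefined` flag rather than being dropped - this keeps the sample stable
and lets models optionally adjust for the flag. For modeling, the across
proportion is transformed to `ln(1 + 100 p)` by default: monotone, zero at
zero (so no offset is needed at zero exposure), and approximately
logarithmic for large exposures. `identity` and `ln(100p + eps)` transforms
are available because the appropriate treatment of zero across-exposure is a
judgment call we left configurable.

## Participation models

- **Univariate screens**: two-sided Student t-tests (equal variances) for
  continuous variables, chi-squared without continuity correction for
  categorical ones; missing ages form a reported Missing category and are
  excluded from the t-test.
- **Fixed-effects logistic regression**: ML via statsmodels; Wald odds
  ratios, 95% CIs and p-values. Complete separation is detected and reported
  as a fit warning with the (unstable) estimates, never silently. Singular
  designs raise an error listing the collinear terms.
- **Random-intercept logistic regression**: own Gauss-Hermite marginal
  maximum-likelihood fitter (25 nodes; `theta = tau * x` substitution, so
  nodes track the prior scale). `tau` is optimized on its natural scale with
  a hard bound at 0, making boundary estimates (`tau_hat = 0`, where the fit
  coincides with plain logistic regression) representable; at the boundary no
  Wald SE for `tau` is reported. The fitter agrees with `lme4::glmer`
  (nAGQ=25) to four decimals on frozen test fixtures. No frequentist GLMM
  was available in the installed Python stack, which is why this component
  is implemented here.
- **Missing age**: age enters only as `(age - mean observed age) x
  AgeObserved` together with the `AgeObserved` main effect; missing ages are
  zeroed, so the age slope is informed solely by physicians whose age is
  known while no observation is dropped.
- **Model reduction**: backward elimination removing the single least
  significant removable term per iteration until all p < alpha (default
  0.05), with marginality respected: an interaction leaves before its main
  effects, and the age pair travels as one unit whose p-value is the smaller
  of its two members. Ties in p are broken by term order, making reduction
  deterministic given the data. An intercept-only terminus is legal.
- **Interaction choice**: the across-exposure modifier can be either the
  non-primary-hospital count `N_i` or the Shannon diversity `H_i`. The
  generator uses `N_i` (the theoretical model's form); the pipeline's
  result-style models default to `H_i`, the form under which across-hospital
  influence is reported in practice. Both are available everywhere.
- Wald inference is used throughout because results are reported as
  OR/CI/p triplets; profile-likelihood CIs are out of scope.

## Synthetic data-generating process

The generator emulates a stepped-wedge physician-recruitment study:

| parameter | default | rationale |
|---|---|---|
| hospitals / steps | 40 / 5 | study scale; steps balanced, randomized |
| physicians per hospital | 7-11 | yields ~360 invitees |
| multi-site fraction | 0.50 | realized mean ~1.5 billing hospitals |
| extra sites | truncated geometric (p=0.55), max 9 | mostly 2-4 sites, tail to 9 |
| billing shares | symmetric Dirichlet(0.2) | one dominant site; realized mean H ~0.18 |
| patients per hospital | 100-150 | within-hospital subnetworks complete |
| encounters per patient | 2-6 | short inpatient contact patterns |
| age | N(42.3, 8.3), 14.6% missing | typical hospitalist demographics |
| tenure | N(3.6, 0.9) years | typical organizational tenure |
| tau | 0.126 | modest unexplained hospital variation |

The primary hospital is the largest billing share (attribution by observed
billing); each patient belongs to one hospital and their encounters are
assigned to physicians billing there with probability proportional to billing
shares, so a physician's encounter counts across hospitals are proportional
to their shares in expectation. Every physician is guaranteed at least one
billing row (an employed hospitalist with zero encounters would be
unattributable). Dates are uniform over 2019-01 to 2021-05 and exist only to
populate the schema and the hospital-network window filter.

Generating coefficients default to the effect sizes such a study reports
(odds ratios ~0.96 per year of age, ~6 for age observed, ~1.6 per tenure
year, ~7 per Shannon unit, 1.05 per within-exposure percent, 1.00 across
main effect, ~1.12 interaction); the intercept (-5.35) was calibrated once by
simulation so the default configuration's overall participation rate sits
near 47%, and frozen.

**Sequential decisions.** Real within-hospital decisions are simultaneous,
which makes naive peer-effect regression inconsistent (endogenous feedback).
The generator instead uses a well-defined sequential process: hospitals are
processed in trial-step order, physicians within a hospital decide one at a
time in uniformly random order, and each decision sees only already-decided
eligible peers (within: same primary hospital; across: same step or earlier).
The exposures actually used are recorded in `SimTruth`, and the
exposure-bookkeeping test verifies they equal the exposure module's values on
the recorded decided sets. Parameter recovery targets this sequential DGP:
fitting against the recorded decision-time exposures identifies every
coefficient, including the within-hospital peer effect. Fitting against
observationally recomputed exposures reintroduces the simultaneity problem by
construction - that is a property of the estimand, not a bug - and the
recovery API exposes both routes (`use_true_exposures`), excluding the
within term by default on the observational route. The real study's joint
decision process is unknown; the sequential scheme is one admissible
resolution, not a claim about how physicians actually decided.

**What the generator does not emulate**: patient case-mix, diagnosis or
revenue structure, calendar seasonality, non-trial hospitals entering
exposure computation, and the magnitude of real per-pair patient sharing
(synthetic physician pairs share ~5-20 patients, not hundreds, so threshold
sweeps lose edges at lower cutoffs than real billing data would). Passing
tests therefore demonstrate correctness of the algebra and estimation
machinery under a controlled process, not fidelity to any particular health
system.

## Problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerances asserted: parameter recovery runs 200 replicates
of ~2000 physicians across 40 hospitals (50 per hospital, 250-350 patients
per hospital so pairwise sharing stays dense); mixed-model tau recovery uses
100 replicates of 40 groups x 10; the null Wald calibration uses 400
replicates at n=2000. The acceptance script runs a 50-replicate version of
the recovery experiment.

## Known limitations

- The ML estimate of `tau` at truth 0 has substantial mass above 0 at
  moderate group counts (about 40% of replicates at 40 groups of 10, with
  estimates occasionally above 0.3); this matches lme4 exactly and is a
  property of maximum likelihood at the boundary, not of this
  implementation. Interpret small positive `tau_hat` at this scale with
  care.
- Dense adjacency matrices bound practical network sizes to a few thousand
  physicians (a 2000-node study uses ~32 MB per matrix).
- No instrumental-variable or network-autocorrelation estimator is provided;
  the package treats within-hospital simultaneity by exclusion (default) or
  by the sequential-DGP assumption, never by solving it.
- Higher-order (two-step) exposures, time-varying exposure updating within a
  step, directed referral inference and community detection are out of
  scope.
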