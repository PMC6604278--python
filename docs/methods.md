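# Methods

## Problem setting

Two population-based data sources each yield a binary case indicator per
person (a "case ascertainment algorithm" applied to administrative health
records or to electronic medical records).  Both indicators are error-prone:
a source with sensitivity `Sn` and specificity `Sp` observes a marginal
prevalence

    p_obs = Sn·π + (1 − Sp)·(1 − π)

when the true prevalence is π.  The package estimates π from the pair of
indicators, and provides a simulation engine to study how the competing
estimators behave as functions of π, the per-source observed prevalences,
the between-source correlation, and the structure of the disease markers.

## Estimators

**OR / AND.**  Union and intersection proportions with normal-approximation
(Wald) intervals, z = 1.959964 at the 95% level.  These obey exact
identities used as test oracles: `AND ≤ min(p̂1, p̂2) ≤ max(p̂1, p̂2) ≤ OR`
and `OR + AND = p̂1 + p̂2`.

**RSSA.**  The Rogan–Gladen corrector `(p̂ + Sp − 1)/(Sn + Sp − 1)` is
applied per source with externally assumed accuracy values (defaults: the
published averages 0.72/0.95 and 0.87/0.90), truncated to [0, 1], and the
two corrected estimates are averaged.  The truncation and the combination
rule matter: when a source's observed prevalence falls at or below its
assumed false-positive floor `1 − Sp`, that source's corrected estimate is
0 and the average is pulled down hard.  An inverse-variance-weighted
combination (delta-method weights `n·J²/(p(1−p))`, J the Youden index) is
available via `RssaEstimator(combination="inverse_variance")`.  Intervals
are percentile bootstrap over individuals (B = 999 by default), preserving
the (y1, y2) pairing.

**PSSA.**  A Bayesian latent-class model:

    D_i | x_i      ~ Bernoulli(Φ(x_i'α))          (probit outcome model)
    Y_ij | D_i=1   ~ Bernoulli(Sn_j)              (reporting model)
    Y_ij | D_i=0   ~ Bernoulli(1 − Sp_j)

with Y1 ⟂ Y2 | D.  Priors: α ~ N(0, 10²) per coefficient; Sn_j, Sp_j ~
Beta(2, 1), a weak push toward informative tests.  The reporting model is
intercept-only (constant Sn/Sp per source): with only two sources this is
what keeps the model identified and avoids label-switching, together with a
guard that redraws any (Sn_j, Sp_j) pair implying Sn + Sp < 1 (equivalent
to truncating the Beta priors to the informative orientation).  The Gibbs
cycle is: (1) each D_i from its Bernoulli full conditional — prior odds
Φ(x'α)/(1−Φ(x'α)) times the two reporting likelihood ratios; (2) α by
Albert–Chib truncated-normal data augmentation (the posterior covariance
factor is constant and pre-factorized); (3) conjugate Beta updates for each
Sn_j, Sp_j from the current classification counts.  The reported quantity
is the posterior of the *realized* cohort prevalence `mean_i(D_i)`; its
point estimate is the posterior mean and the default interval is the
2.5/97.5 posterior percentile.  Defaults follow the reference analysis:
10,000 iterations, 500 burn-in, 2 chains.  A percentile bootstrap over full
refits is possible in principle but deliberately not wired in (999 refits
of a Gibbs sampler is not a desk-scale computation); posterior percentiles
are the default interval.

Convergence: `gelman_rubin_psrf` implements the standard between/within
variance ratio for ≥ 2 chains (cross-checked against arviz in the tests);
inside replication loops a single chain is run and its split-half PSRF is
used as the non-convergence flag (threshold 1.2, flagged not discarded).

DIC uses the observed-data likelihood with D marginalized analytically,
`DIC = 2·D̄ − D(θ̄)`, with the posterior-mean deviance averaged over at
most 500 thinned draws.  `p_D = D̄ − D(θ̄) ≥ 0` on well-behaved fits is a
test property.

## Simulation engine

**Markers.**  Binary markers are produced by dichotomizing a multivariate
normal vector: column k is cut at the standard-normal `(1 − p_k)` quantile,
success = latent value above threshold, so marginal prevalences are exact
in expectation and the latent correlation is the specified matrix.
Exchangeable structures use the constant off-diagonal; unstructured ones
draw off-diagonals uniformly from `corr_mean ± 0.15` (clipped to [0, 0.95]),
recenter, and project to the nearest positive-definite correlation matrix
(eigenvalue clipping with unit-diagonal restoration), accepting when the
mean off-diagonal lands within 0.01 of the target.  Marker prevalences
default to a single U[0.05, 0.35] draw per condition on a condition-derived
seed; the logistic coefficients default to log odds ratios equally spaced
on [log 1.5, log 2.5] — magnitudes typical of chronic-disease risk-marker
associations.  The intercept is calibrated per replication by monotone
root-finding so the population mean risk equals the target prevalence.

**Observation model.**  Given D, each source fires with probability Sn (if
D = 1) or 1 − Sp (if D = 0).  The two sources' uniform draws are coupled by
a bivariate Gaussian copula with stratum-specific correlation, so marginal
accuracies are preserved exactly while the within-stratum error dependence
is a free parameter spanning conditional independence (0) through strong
agreement.

**Accuracy calibration.**  A simulation condition pins four observable
targets: π, both observed prevalences, and the between-source correlation,
interpreted on the tetrachoric scale (the scale on which linked AHR/EMR
agreement is reported, and the only scale on which values like 0.85 are
attainable for rare outcomes).  The four generating accuracy parameters are
closed as follows: both sources share one positive-predictive-value
parameter ψ, with `Sn_j = ψ·p_obs,j/π` (capped at 0.95) and the remaining
observed positives assigned to false positives.  ψ is solved by monotone
root-finding so that *conditionally independent* sources already exhibit
the target tetrachoric correlation — the exact 2×2 joint cell is computed
analytically from bivariate-normal rectangle probabilities (Owen's T
identity) at every step.  Only when the target correlation falls outside
the attainable conditional-independence range is ψ clamped at the boundary
and the residual closed by the within-stratum copula correlation.  This
closure reflects the documented error structure of administrative case
definitions (under-ascertainment dominates; positive predictive value is
high) and means the latent-class estimator faces its assumed model at the
generating values, while the rule-based estimators face exactly the margins
and joint cell the condition specifies.  A `specificity_override` bypasses
the closure (both specificities fixed, sensitivities solved from the
marginal constraint) to study misspecified-accuracy scenarios.

**Evaluation.**  `RB = 100·|π − mean(π̂)|/π`; `MSE = var(π̂) + bias²`
reported ×100, with the population (divide-by-R) variance so the
decomposition `MSE/100 − bias² = var` is exact.  Conditions are seeded by a
CRC32 hash of their field values combined with the base seed, so any cell
is reproducible in isolation; replications derive child seeds from the
condition seed.  Defaults: 500 replications of populations of 10,000 (the
population size is not dictated by the reference design; 10,000 makes
estimator error, not population noise, the dominant term while keeping a
full grid tractable), with a documented reduced-replication mode used by
the acceptance checks (200 replications for rule-based cells, 100 with
2,000 Gibbs iterations for latent-class cells).

**Tetrachoric correlation.**  Two-step maximum likelihood: thresholds fixed
at the normal quantiles of the margins, then the latent correlation
maximizes the 2×2 multinomial likelihood; the interval inverts the observed
Fisher information of the profile likelihood.  An empty off-diagonal cell
returns ±1 with a boundary flag.

## Fixture cohort

`generate_fixture_dataset` emulates a linked two-source primary-care cohort
entirely synthetically: default n = 68,877, true prevalence 0.25, source
margins 0.309 (over-capturing) and 0.249 (under-capturing), tetrachoric
agreement target 0.90, plus sex, three age groups, and binary comorbidity
flags with realistic prevalences and a mild exchangeable correlation (0.1),
generated through the same copula machinery.  The flags and a strong age
gradient drive the true-status model so the latent-class estimator has
informative markers.  What the fixture does **not** emulate: record-linkage
error, covariate missingness, informative cohort entry, or any resampling
of real records — results on it demonstrate mechanics, not real-world
performance.

## What passing tests do and do not show

The generator satisfies the latent-class model's conditional-independence
assumption at the calibrated accuracies (by construction, whenever the
correlation target is attainable under conditional independence).  Tests
that show PSSA nearly unbiased therefore certify correct inference *under
the model*, not robustness to dependent errors — the residual-dependence
mode and the specificity override exist to study exactly those violations.
Conversely, RSSA's large bias in low-prevalence cells is a property of the
published-accuracy correction at those margins (observed prevalences at or
below the assumed false-positive floor truncate to zero), not a simulation
artifact.

## Numerical choices

- Bivariate-normal CDF via Owen's T (`scipy.special.owens_t`), cross-checked
  against quadrature; degenerate margins (p ∈ {0, 1}) short-circuit.
- Truncated-normal draws by inverse CDF arranged to evaluate `ndtri` on the
  small tail probability (accurate to |η| ≈ 35); probabilities clipped at
  1e-300 before `ndtri`, latent-status log odds clipped at ±690 before
  exponentiation.
- Root-finds (`brentq`) at xtol 1e-10 for all calibrations; the intercept
  calibration brackets adaptively since the mean risk is strictly monotone
  in the intercept.
- Rogan–Gladen estimates outside [0, 1] are truncated (documented behavior,
  relied on by the low-prevalence analyses).

## Known limitations

- Two sources only; no capture–recapture estimators.
- Intercept-only reporting model: misclassification cannot depend on
  covariates, and consequently marker correlation barely affects PSSA here,
  unlike analyses whose reporting models condition on markers.
- No missing-data handling in the covariates.
- The polychoric case beyond 2×2 is out of scope; only the tetrachoric
  special case is implemented.
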