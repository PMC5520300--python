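# Methods

## Estimand and identification

The target is the complier-average causal effect (CACE) of offering a
financial incentive for smoking cessation on infant birth weight: the mean
causal difference among *potential quitters* — mothers who quit if and
only if offered. Identification rests on randomization plus three
assumptions that the data cannot test and that every report therefore
lists explicitly:

* **No defiers** (monotonicity): nobody quits only when *not* offered
  (π_d = 0).
* **Exclusion restriction**: randomization moves birth weight only through
  quitting, so the hardened-smoker (never-taker) and independent-quitter
  (always-taker) mean outcomes are the same in both arms.
* **MCAR missingness**: the ~4% of missing birth weights are missing
  completely at random; all estimation is complete-case, with no
  imputation.

Under these, the incentives-arm smoker cell is pure HS and the control-arm
quitter cell pure IQ; prevalences P_HS, P_IQ come from those cell
fractions (note the two use different arm denominators) and
P_PQ = 1 − P_HS − P_IQ, which equals the between-arm quit-rate difference
exactly. The two mixed cells are inverted as weighted means:

    W_PQQ = (W_1 (P_IQ + P_PQ) − P_IQ W_IQ) / P_PQ
    W_PQS = (W_0 (P_HS + P_PQ) − P_HS W_HS) / P_PQ

CACE = W_PQQ − W_PQS. Provided every input is computed from the same
complete-case record set, this equals the Wald / instrumental-variable
ratio (μ_1 − μ_0)/P_PQ *exactly* (simple algebra on the weighted-mean
decompositions); `equivalence_report` computes both routes and raises if
they ever differ by ≥ 1e-6 g, which would indicate an implementation
defect, not sampling noise. When prevalences and means are instead taken
from independently rounded printed summaries the two routes can differ at
the ±2 g level; reports show full-precision and rounded values side by
side so such rounding effects stay visible.

**Degenerate inputs.** A non-positive compliance gap leaves the inversion
undefined. Point-estimate entry points flag the result invalid and
propagate NaN sentinels rather than raising, because resampling must be
able to traverse this state; `P_PQ ≤ 1e-6` is treated as unidentified to
keep floating-point dust (a gap of ~1e-16 from rates that are equal in
exact arithmetic) from producing absurd ±1e18 g estimates.

## Bootstrap and BCa intervals

Uncertainty for the four subgroup means and the CACE comes from a
nonparametric bootstrap (default 10,000 replicates) over the analyzable
records, with the full chain recomputed per replicate. Two schemes:

* `within_arm` (default): resample with replacement separately per arm,
  preserving the randomized arm sizes. This avoids empty-arm replicates
  and matches the design's fixed allocation.
* `whole_cohort`: resample the pooled records; arm sizes vary.

A replicate is stored only if both arms and all four arm × quit cells are
nonempty and the compliance gap exceeds 1e-6; excluded replicates are
counted and reported (on trial-sized cohorts they are rare, ~0.03% of
replicates in the coverage study below). Draws are reproducible
bit-for-bit given (cohort, seed, scheme, replicates): each arm consumes an
independent child stream of the seed, so batch size does not perturb
results.

Intervals are bias-corrected and accelerated: z₀ = Φ⁻¹(fraction of draws
strictly below the point estimate), acceleration a from the jackknife
skewness formula a = Σdᵢ³ / (6 (Σdᵢ²)^{3/2}) over leave-one-record-out
estimates of the same statistic (computed in one vectorized pass by
subtracting record contributions from the cell totals; O(n) estimator
evaluations), adjusted tail probabilities clipped to [1/(B+1), B/(B+1)],
endpoints read off the draw distribution by linear-interpolation
quantiles. Edge conventions: identical draws give a zero-width interval;
a fraction-below of 0 or 1 clamps z₀ to the clipping bound with a logged
warning; a non-positive BCa denominator (pathological acceleration) pins
the endpoint at the clipping bound. The implementation is verified against
a straight-line textbook recomputation to 1e-9 and against an independent
library BCa implementation to within the spacing of adjacent order
statistics (the two differ only in quantile convention).

## Power under dilution

A complier-level effect δ_c appears between arms as the diluted ITT
difference π_c δ_c. Sample size for a two-sided two-sample t test is
solved on the exact noncentral-t power curve (df = 2n − 2, noncentrality
(δ/σ)√(n/2)), seeded by and cross-checked against the closed-form normal
approximation 2σ²(z_{1−α/2} + z_{power})²/δ², which agrees within ±2
participants over the relevant regime. The headline reproduction —
27,637 per group for δ_c = 100 g, π_c = 0.143, α = 0.05, power 0.80 —
uses σ = 600 g. The outcome SD behind that published figure was not
stated; 600 g is the value that inverts the standard formula to the
printed n and sits close to the observed pooled SD (~590 g). It is an
explicit, logged input, not a fitted constant.

## Synthetic cohort generator

The generator emulates the motivating trial: 303 control / 304 incentives
mothers; stratum prevalences 0.770 / 0.087 / 0.143 (HS / IQ / PQ);
normal outcomes per stratum with means 3053 / 3586 / 3193 g and SDs
588 / 566 / 570 g; a constant 145 g added to PQ outcomes in the
incentives arm only; quit status a deterministic function of (stratum,
arm); 25/607 of weights masked missing completely at random. Choices the
published summaries do not pin down, adopted as conventions: outcomes are
normal within stratum (only means/SDs are reported); the PQ SD of 570 g
is interposed between the observed cell SDs; the PQ base mean is set to
the estimated no-offer potential-quitter mean so the implied cell means
approximate the published table. The latent-draw stream (stratum, base
outcome, missingness) is laid out independently of arm assignment, so the
exclusion restriction holds by construction and is asserted by
regenerating with arms relabelled. Latent stratum labels are carried in
the records for validation only; estimators never read them, and tests
confirm label-stripped cohorts give identical estimates.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: covariate structure and confounded
missingness (real missingness is unlikely to be MCAR), non-normal or
skewed birth-weight tails, gestational-age dependence, any defier
behaviour, and measurement error in cotinine-validated quit status.
Recovery and coverage results certify the estimator under its own
assumptions, not those assumptions themselves.

## Validation summary (all recomputed by the test suite)

* Deterministic anchors from the printed table: quit rates 23.1% / 8.7%
  (gap 14.3%), prevalences 0.769 / 0.087 / 0.143, W_PQS = 3193 g,
  W_PQQ = 3338 g ± 2, CACE = 145 g ± 2 by both routes; Welch p = 0.67 for
  the arm contrast; Fisher p < 1e-4 for the quit table; 27,637 per group.
* Exact-identity property: intuitive and Wald routes agree to 1e-9
  relative on random individual-level cohorts.
* Bootstrap machinery: matches exhaustive enumeration of all 6⁶ resamples
  of a 6-record cohort (Kolmogorov distance < 0.02 at 10⁵ replicates);
  BCa matches the textbook oracle to 1e-9.
* Simulation at the trial's design (500 cohorts, 1,000 replicates each,
  chosen to keep the full suite under a minute of bootstrap time):
  95% CACE interval coverage 0.934; bias 1.1 g (MC SE 17 g); estimate SD
  ≈ 386 g, consistent with the very wide published interval. Large-n
  recovery (5,000/arm, 200 sims) is unbiased within 3 MC SEs.

## Known limitations

* No covariate adjustment (two-stage least squares or Bayesian mixture
  extensions would be the natural next step); no delta-method or
  studentized variance alternatives to the bootstrap.
* The published 95% CI (−617, +803 g) cannot be reproduced exactly
  without the individual-level trial data; validation of the interval
  machinery is by oracle and simulation instead.
* Complete-case estimation is only as good as the MCAR assumption.
* With small cells (few control quitters) the inversion is numerically
  identified but extremely noisy; the reported W_PQS interval width makes
  this visible rather than hiding it.
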