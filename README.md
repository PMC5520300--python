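# cacetrial

Complier-average causal effect (CACE) analysis for two-arm randomized
trials with noncompliance, built around a motivating problem from perinatal
epidemiology: a trial that offered pregnant smokers financial vouchers for
biochemically validated quitting saw a large jump in cessation (23.1% vs
8.7%) but essentially no intention-to-treat (ITT) effect on infant birth
weight (+21 g, p = 0.67). The ITT comparison dilutes any real benefit over
the whole arm, most of whom never changed behaviour. `cacetrial` recovers
the effect *among the mothers whose quitting was caused by the offer*.

It is written for trial statisticians and epidemiologists who want the
whole chain — descriptives, estimation, uncertainty, power — reproducible
from a plain CSV of `(arm, quit, birth_weight)` records, plus a synthetic
cohort generator so every stage can be exercised and validated without any
real data.

## The model

Randomization splits mothers into three latent principal strata (no
defiers, by assumption):

| stratum | quits if offered | quits if not | CACE notation |
|---|---|---|---|
| hardened smokers (HS) | no | no | never-takers, π_n |
| independent quitters (IQ) | yes | yes | always-takers, π_a |
| potential quitters (PQ) | yes | no | compliers, π_c |

Two cells identify a stratum directly: incentives-arm continuing smokers
are pure HS (giving P_HS and W_HS), control-arm quitters are pure IQ
(P_IQ, W_IQ). P_PQ = 1 − P_HS − P_IQ. The two mixed cells are then
inverted as weighted means to obtain the unobservable potential-quitter
means with and without the offer:

    W_PQQ = (W_1 · (P_IQ + P_PQ) − P_IQ · W_IQ) / P_PQ
    W_PQS = (W_0 · (P_HS + P_PQ) − P_HS · W_HS) / P_PQ

where W_1 is the incentives-arm quitter mean and W_0 the control-arm
smoker mean. The CACE is W_PQQ − W_PQS, and is algebraically identical to
the instrumental-variable Wald ratio (μ_1 − μ_0) / P_PQ — the ITT outcome
difference divided by the compliance gap — whenever all inputs come from
one complete-case record set. The package computes both routes and asserts
their agreement. Uncertainty comes from a nonparametric bootstrap with
bias-corrected and accelerated (BCa) intervals; power calculations account
for the dilution of a complier-level effect δ to an ITT effect π_c · δ.

On the published summary table (cells 262/3075, 25/3586, 227/3053, 68/3432),
the chain gives P_PQ = 0.1434, W_PQQ = 3338 g, W_PQS = 3193 g and a CACE of
145 g — a clinically meaningful benefit hidden inside the 21 g ITT contrast.

## Worked example

Simulate a trial-sized cohort (607 mothers, ~4% missing weights) and
analyze it:

```sh
cacetrial simulate --out cohort.csv --seed 22
cacetrial analyze --input cohort.csv --bootstrap 10000 --seed 1 --out run
```

The report (excerpt, this exact seed) walks the chain step by step:

```
  P_HS = 0.804795 | 0.805
  P_IQ = 0.106897 | 0.107
  P_PQ = 1 - P_HS - P_IQ = 0.088309 | 0.088
  W_PQQ = (W_1*(P_IQ+P_PQ) - P_IQ*W_IQ)/P_PQ = 3182.7335 | 3183 g
  W_PQS = (W_0*(P_HS+P_PQ) - P_HS*W_HS)/P_PQ = 2807.5705 | 2808 g
  CACE (intuitive) = W_PQQ - W_PQS = 375.1629 | 375 g
  CACE (Wald)      = (mu1 - mu0)/P_PQ = 375.1629 | 375 g

  complier-average causal effect   375.16 g  [-1197.02, 1601.34]  (level=0.95)
```

This cohort was generated with a true complier effect of 145 g; the 375 g
point estimate with a ±1400 g interval is exactly the behaviour the method
predicts at n ≈ 600 — the estimator is unbiased but very noisy, because it
scales a small arm difference by 1/P_PQ ≈ 11. Across 500 replications of
this design the 95% interval covers the truth 93.4% of the time.

The power subcommand quantifies why the original trial could not see the
effect:

```sh
cacetrial power --delta-complier 100 --pi-c 0.143 --sd 600
# delta_itt = 14.3 g  ->  n_per_group = 27637  (n_total = 55274)
```

Detecting a 100 g complier-level benefit at 80% power needs ~27,637
mothers per arm once dilution is taken into account.

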