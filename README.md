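# twotrials

How much evidence is there behind a medication endorsed because **two
trials reached p < .05**? This package answers that question by simulation:
it generates sets of two-arm trials conditioned on the endorsement rule
being met — exactly two trials significant (two-tailed p < .05) with the
experimental arm ahead, and no trial significant in the other direction —
pools each accepted set, and measures the strength of evidence in the
combined data with a default Bayes factor.

It is aimed at biostatisticians and meta-researchers studying significance
thresholds in regulatory decision-making, and is equally usable as a plain
library for one-sided JZS Bayes factors of the independent two-sample
design.

## The evidence measure

For pooled data with t statistic `t` and group sizes `n1, n2`, the JZS
(Jeffreys–Zellner–Siow) Bayes factor places a Cauchy(0, r) prior with
r = √2/2 on the standardized effect δ and integrates the noncentral-t
likelihood over it:

```
BF10 = ∫ f(t | δ, n1, n2) Cauchy(δ; 0, r) dδ  /  f(t | δ=0, n1, n2)
```

The one-sided (directional) factor truncates the prior to δ > 0
(experimental better) and equals `BF10 × Pr(δ > 0 | data) / ½`. Bayes
factors are read on the usual scale: < 1 favors the null, 1–3 "not worth
more than a bare mention", 3–20 positive, ≥ 20 strong.

The simulation study crosses true effect sizes {0.2, 0.5, 0} SD, trial
counts {2, 3, 4, 5, 20} and per-arm sample sizes {20, 50, 100, 500, 1000},
with 500 replications per cell. See `docs/methods.md` for the model,
numerics and seeding scheme.

## Worked example

A single Bayes factor from the command line:

```sh
$ twotrials bf 2.5 50 50
BF(two_sided) = 3.23342
$ twotrials bf 2.5 50 50 --direction greater
BF(greater) = 6.40237
```

A trial with t = 2.5 at 50 per arm is "significant" (p ≈ .014), yet the
two-sided evidence is barely past the bare-mention boundary; the one-sided
factor roughly doubles because essentially all posterior mass is on the
positive side.

One simulation cell from the library — true effect 0.2 SD, five trials
conducted of which exactly two came out significant-favorable, 20
participants per arm, 100 replications:

```python
import numpy as np
import twotrials as tt

cell = tt.CellConfig(effect_size=0.2, k_trials=5, n_per_arm=20,
                     replications=100, master_seed=42, cell_index=0)
summary = tt.run_cell(cell)
print(np.round(summary.bin_percentages, 1))   # [ 7. 10. 38. 45.]
print(round(float(np.median(summary.bf_values)), 2))  # 17.65
```

Even though every one of these scenarios satisfies the endorsement rule,
17% of replications carry combined evidence below BF = 3 (7% actually favor
the null), and the median Bayes factor is only ≈ 18 — the rule is
compatible with wildly varying strength of evidence.

The full factorial study and its figures:

```sh
twotrials run-grid --out results/full --seed 1234 --jobs 4
twotrials report --results results/full --out figures/
```

`run-grid` writes a tidy CSV (one row per replication), a per-cell summary
CSV and a manifest; `report` renders log-scale box-plot panels and stacked
evidential-bin bar charts per effect size, plus `headlines.json` with the
quoted-cell percentages and Wilson 95% intervals. Sensitivity variants:
`--tau 0.1` (between-trial effect heterogeneity) and `--sd-ratio 1.5`
(unequal arm variances).

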