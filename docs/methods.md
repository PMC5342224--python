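# Methods

## The question

Regulatory endorsement of a new medication has often been read as "two
trials, each with two-tailed p < .05, favoring the treatment". `twotrials`
quantifies what that rule actually buys in evidential terms: it simulates
sets of two-arm trials *conditioned* on the rule being satisfied — exactly
two trials significant in the favorable direction, none significant in the
unfavorable direction — and measures the strength of evidence in the
combined data with a default Bayes factor. The point of the conditioning is
deliberate: the simulations are not about how often the rule triggers, but
about how much evidence is present *when* it triggers.

## Data-generating model

Each trial has `n` participants per arm. Control observations are drawn
from N(0, σ²) with σ = 1; experimental observations from N(d·σ, σ²), where
`d` is the standardized effect (Cohen's d). The main study crosses

| factor | values | default |
|---|---|---|
| true effect `d` (SD units) | 0.2, 0.5, 0 | — |
| trials conducted `k` | 2, 3, 4, 5, 20 | — |
| participants per arm `n` | 20, 50, 100, 500, 1000 | — |
| replications per cell | — | 500 |
| significance level α | — | 0.05 two-tailed, strict (`p < α`) |

75 cells in total; each effect-size slab plans 25 cells × 500 = 12,500
accepted data sets.

Two sensitivity variants relax the main generator:

* **between-trial heterogeneity** — the per-trial true effect is drawn once
  per trial from N(d, τ). τ defaults to 0.1 SD when the variant is enabled
  (`DEFAULT_HETEROGENEITY_SD`); the draw is per *trial*, not per
  participant, so each trial retains a well-defined true effect.
* **unequal variances** — the experimental arm's SD is multiplied by
  `sd_ratio` (default 1.5 when enabled, `DEFAULT_UNEQUAL_SD_RATIO`) while
  the analysis keeps the pooled-variance t-test. The violation of the
  analysis model is intentional: the variant probes robustness of the
  conclusions, not a Welch-style correction.

## Rejection sampling of qualifying scenarios

A replication regenerates the *entire* k-trial set until exactly two trials
are significant-favorable and zero are significant-unfavorable.
Regenerating whole sets (rather than patching individual trials) preserves
the conditional distribution of accepted sets; per-trial resampling would
bias it. The attempt count per accepted set is recorded; it is geometric
with success probability equal to the acceptance probability of a single
set, which for small k can be checked against the binomial law over
single-trial outcome categories (a property test does exactly this).

Some cells are essentially impossible — e.g. at d = 0.2 with n = 1000 per
arm, nearly every trial is significant, so "exactly two of twenty" never
happens. A replication that exhausts the attempt cap (default 100,000 set
regenerations) marks its whole cell infeasible; infeasible cells carry no
Bayes factors and render as blank panels, and the cap is recorded in place
of the mean attempt count. The cap is this package's operationalization of
"conditions that do not realistically occur"; at the default cap the three
blank small-effect cells are (d=0.2, k=5, n=1000), (d=0.2, k=20, n=500) and
(d=0.2, k=20, n=1000).

## The evidence measure

For each accepted set, all experimental arms are pooled into one sample and
all control arms into another (total k·n per arm), and the evidence is the
**one-sided JZS Bayes factor** for "experimental better" against the point
null. The JZS construction places a Cauchy(0, r) prior on the standardized
effect δ with r = √2/2, and non-informative priors on the nuisance location
and scale; the data then enter only through the pooled t statistic and the
group sizes:

    BF10 = ∫ f(t | δ, n1, n2) · Cauchy(δ; 0, r) dδ / f(t | 0, n1, n2)

with `f` the noncentral-t density of the t statistic (df = n1+n2−2,
noncentrality δ·√(n1·n2/(n1+n2))). The one-sided factor uses the
half-Cauchy on δ > 0, computed as BF10 × (posterior mass of δ > 0)/(1/2),
so the identity BF⁺ + BF⁻ = 2·BF10 holds by construction.

Bayes factors are reported raw and summarized two ways per cell:

* percentages in the evidential bins [0,1), [1,3), [3,20), [20,∞) —
  favors-null, "not worth more than a bare mention", positive, strong.
  Boundary values go to the upper bin; under continuous data a boundary has
  probability zero, so the convention is cosmetic.
* Tukey box statistics of log BF: interpolated quartiles, whiskers at the
  most extreme points within 1.5·IQR of the quartiles, points beyond
  flagged outliers. Whiskers are clamped never to retreat inside the box, a
  corner reachable with interpolated quartiles on heavily tied values.

## Numerics

The marginal-likelihood integral is evaluated in log space on the bounded
axis θ = arctan(δ/r), where the Cauchy prior is uniform. The integrand is
exponentiated only after subtracting its peak log value (taken at the
sample effect δ̂ = t/√(n_eff)), then integrated by adaptive Gauss–Kronrod
quadrature separately over the two half-axes — which yields the posterior
directional mass in the same pass. The quadrature targets 1e-8 relative
error, tolerates 1e-6, and raises a diagnostic error beyond that rather
than returning a silently wrong value.

The noncentral-t density itself never appears in absolute form — only the
likelihood *ratio* f(t|δ)/f(t|0), computed from the chi-mixture integral
representation: the ratio reduces to exp(a²/2 − μ²/2)·I_ν(a)/I_ν(0) with
a = μt/√(ν+t²), I_ν(a) = ∫₀^∞ xᵛ exp(−(x−a)²/2) dx, and I_ν(0) known in
closed form. I_ν(a) is a smooth unimodal integrand evaluated by 128-node
Gauss–Legendre around its mode (12 Laplace scale-lengths each side). This
stays accurate for df up to at least ~40,000 and |t| up to 50, where
gamma-function formulations overflow; against the closed form at a = 0 the
inner quadrature agrees to ~1e-11 at df = 39,998. Extremely large evidence
(log BF > ~709) overflows the linear scale; `log=True` returns log BF.

Two independent checks guard the engine:

* **Savage–Dickey oracle** — the Bayes factor equals prior/posterior
  density at δ = 0, which rearranges to the normalized importance estimate
  mean[f(t|δᵢ)/f(t|0)] over prior draws δᵢ. The densities come from
  `scipy.stats.nct` (a separate implementation) and the estimate carries a
  Monte-Carlo standard error. Draws in tails that scipy cannot evaluate —
  same-sign |ncp| > |t|+35 (density below double underflow) and, for
  df > 150, opposite-sign |t·ncp| > 8 (density ≲1e-7 of the estimate) —
  contribute zero; the truncation is orders of magnitude below the MC
  error.
* **cross-implementation check** — two-sided values are compared in tests
  against `pingouin.bayesfactor_ttest`, which evaluates the same model
  through the entirely different Rouder g-mixture quadrature; agreement is
  at ~1e-13 relative.

## Seeding and reproducibility

Replication `j` of cell `i` uses `SeedSequence(master_seed,
spawn_key=(i, j))`: counter-based, so cells and replications may run in any
order or in parallel with identical output, and a longer run's first
replications reproduce a shorter run's. The rejection sampler draws
attempts in internal batches whose size depends only on the cell
dimensions, keeping the stream deterministic.

## Problem sizes in the test suite

Stochastic tests run at the study's own scale where that is what is being
checked (the two quoted cells at 500 replications; tolerances of 3 binomial
standard errors), and at reduced scale where only a direction or flag is
under test: infeasibility is probed with a 10,000-attempt cap and 20
replications, trend checks use 150 replications, and the zero-effect median
check uses 200 replications per sample size.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: normal outcomes,
equal allocation, fixed n, independent trials, selection on exactly two
favorable significant results. It does not model interim analyses or
optional stopping, publication-bias mechanisms beyond the selection rule
itself, non-normal or binary endpoints, dropout, or unequal allocation —
so passing tests certify the machinery under the stated conditions, not the
behavior of real trial portfolios. Non-inferiority designs and reanalyses
of empirical trial data are out of scope.

## Known limitations

* The directional Bayes factor underflows to the smallest positive float
  when the posterior mass in the disfavored direction itself underflows
  (|t| very large against the direction); use the two-sided value and the
  mirror identity BF⁺(t) = BF⁻(−t) if that region matters.
* The Savage–Dickey oracle is intended for |t| ≲ 6 and n ≤ ~1000 per arm
  (the envelope probed for scipy's noncentral-t implementation).
* Infeasibility is cap-relative: a cell flagged infeasible at the default
  cap is a statement about ~1e-5 acceptance probability, not a proof of
  impossibility.
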