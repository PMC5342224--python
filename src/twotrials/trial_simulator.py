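"""Synthetic two-arm clinical-trial generator.

Trials mimic two-condition between-subjects experiments: a control (placebo)
arm drawn from N(0, sd_control) and an experimental arm drawn from
N(effect, sd_control * sd_ratio), with the effect expressed in control-SD
units (Cohen's d when sd_ratio == 1).  Two sensitivity variants extend the
main generator:

* between-trial effect heterogeneity — the per-trial true effect is drawn
  once per trial from N(effect_size, effect_sd);
* unequal variances — the experimental arm's SD is scaled by ``sd_ratio``
  while the analysis deliberately keeps the pooled-variance t-test, so the
  generator violates the analysis model.

All randomness flows through an explicit numpy Generator so that every
simulated trial is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np
from scipy import stats

from .bayes_core import TrialTestResult

__all__ = [
    "ScenarioConfig",
    "TrialData",
    "TrialOutcome",
    "simulate_trial",
    "significant_favorable",
    "DEFAULT_ALPHA",
    "DEFAULT_HETEROGENEITY_SD",
    "DEFAULT_UNEQUAL_SD_RATIO",
]

#: Two-tailed significance threshold used throughout the study.
DEFAULT_ALPHA: float = 0.05

#: Documented defaults for the sensitivity variants (the main study uses
#: effect_sd = 0 and sd_ratio = 1).
DEFAULT_HETEROGENEITY_SD: float = 0.1
DEFAULT_UNEQUAL_SD_RATIO: float = 1.5


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters for one simulation cell.

    Parameters
    ----------
    effect_size
        True mean advantage of the experimental arm, in control-SD units
        (0, 0.2 or 0.5 in the main study).
    n_per_arm
        Participants per group (>= 2).
    k_trials
        Trials conducted per scenario set (>= 2).
    sd_control
        Control-arm standard deviation (1 in the main study).
    sd_ratio
        Experimental-arm SD divided by control-arm SD (1 in the main study;
        the unequal-variance sensitivity analysis uses values != 1).
    effect_sd
        Between-trial SD of the true effect (0 in the main study; the
        heterogeneous-effect sensitivity analysis uses values > 0).
    """

    effect_size: float
    n_per_arm: int
    k_trials: int
    sd_control: float = 1.0
    sd_ratio: float = 1.0
    effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError(f"n_per_arm must be >= 2, got {self.n_per_arm}")
        if self.k_trials < 2:
            raise ValueError(f"k_trials must be >= 2, got {self.k_trials}")
        if not self.sd_control > 0:
            raise ValueError(f"sd_control must be positive, got {self.sd_control}")
        if not self.sd_ratio > 0:
            raise ValueError(f"sd_ratio must be positive, got {self.sd_ratio}")
        if self.effect_sd < 0:
            raise ValueError(f"effect_sd must be non-negative, got {self.effect_sd}")
        if not np.isfinite(self.effect_size):
            raise ValueError(f"effect_size must be finite, got {self.effect_size}")


@dataclass(frozen=True)
class TrialData:
    """Raw observations for one simulated two-arm trial."""

    experimental: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        exp = np.asarray(self.experimental, dtype=float)
        ctl = np.asarray(self.control, dtype=float)
        object.__setattr__(self, "experimental", exp)
        object.__setattr__(self, "control", ctl)
        if exp.ndim != 1 or ctl.ndim != 1 or exp.size != ctl.size or exp.size < 2:
            raise ValueError("arms must be equal-length 1-d arrays with >= 2 values")
        if not (np.isfinite(exp).all() and np.isfinite(ctl).all()):
            raise ValueError("arms contain non-finite values")

    @property
    def n_per_arm(self) -> int:
        return int(self.experimental.size)


class TrialOutcome(Enum):
    """Classification of one trial's two-tailed test at level alpha."""

    SIGNIFICANT_FAVORABLE = "significant_favorable"
    SIGNIFICANT_UNFAVORABLE = "significant_unfavorable"
    NONSIGNIFICANT = "nonsignificant"


def simulate_trial(config: ScenarioConfig, rng: np.random.Generator) -> TrialData:
    """Draw one two-arm trial.

    Draw order (fixed for reproducibility): the per-trial true effect if
    ``effect_sd > 0``, then the experimental arm, then the control arm.
    """
    delta = config.effect_size
    if config.effect_sd > 0:
        delta = rng.normal(config.effect_size, config.effect_sd)
    sd_exp = config.sd_control * config.sd_ratio
    experimental = rng.normal(delta * config.sd_control, sd_exp, config.n_per_arm)
    control = rng.normal(0.0, config.sd_control, config.n_per_arm)
    return TrialData(experimental=experimental, control=control)


def significant_favorable(
    result: TrialTestResult, alpha: float = DEFAULT_ALPHA
) -> TrialOutcome:
    """Classify a trial result at the two-tailed level ``alpha``.

    Significance is strict (``p < alpha``; a p value exactly at the
    threshold is non-significant) and "favorable" means the experimental
    arm had the higher mean.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if result.p_two_tailed >= alpha:
        return TrialOutcome.NONSIGNIFICANT
    if result.mean_diff > 0:
        return TrialOutcome.SIGNIFICANT_FAVORABLE
    return TrialOutcome.SIGNIFICANT_UNFAVORABLE


# ---------------------------------------------------------------------------
# vectorized internals used by the rejection sampler
# ---------------------------------------------------------------------------

def _simulate_sets(
    config: ScenarioConfig, rng: np.random.Generator, n_sets: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n_sets`` full k-trial scenario sets at once.

    Returns arrays of shape ``(n_sets, k_trials, n_per_arm)`` for the
    experimental and control arms.  Per-set draw order matches
    :func:`simulate_trial` (effects, then experimental, then control arms).
    """
    k, n = config.k_trials, config.n_per_arm
    if config.effect_sd > 0:
        delta = rng.normal(config.effect_size, config.effect_sd, size=(n_sets, k, 1))
    else:
        delta = config.effect_size
    sd_exp = config.sd_control * config.sd_ratio
    experimental = delta * config.sd_control + sd_exp * rng.standard_normal(
        (n_sets, k, n)
    )
    control = config.sd_control * rng.standard_normal((n_sets, k, n))
    return experimental, control


def _batch_t_tests(
    experimental: np.ndarray, control: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance t-tests along the last axis.

    Returns ``(t, p_two_tailed, mean_diff)`` with the leading shape of the
    inputs.  Matches :func:`twotrials.bayes_core.pooled_t_test`.
    """
    n = experimental.shape[-1]
    df = 2 * n - 2
    mean_diff = experimental.mean(axis=-1) - control.mean(axis=-1)
    sp2 = (experimental.var(axis=-1, ddof=1) + control.var(axis=-1, ddof=1)) / 2.0
    se = np.sqrt(sp2 * (2.0 / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, mean_diff
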