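"""Rejection sampling of "exactly two significant trials" scenarios.

The endorsement rule under study accepts a drug once exactly two trials in a
set of k are statistically significant (two-tailed p < .05) with the
experimental arm ahead, and no trial is significant in the wrong direction.
This module regenerates whole k-trial sets until that condition holds, then
pools all arms and computes the one-sided JZS Bayes factor for the combined
data.

Regeneration granularity matters: the *entire* k-trial set is redrawn on
every attempt.  Patching individual trials would bias the conditional
distribution of the accepted sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .bayes_core import BFSpec, TrialTestResult, jzs_bf_directional, pooled_t_test
from .trial_simulator import (
    DEFAULT_ALPHA,
    ScenarioConfig,
    TrialData,
    TrialOutcome,
    _batch_t_tests,
    _simulate_sets,
    significant_favorable,
)

__all__ = [
    "BFResult",
    "InfeasibleScenarioError",
    "DEFAULT_MAX_ATTEMPTS",
    "is_qualifying_set",
    "sample_qualifying_scenario",
    "pooled_bf",
]

#: Attempt cap per replication; cells where a replication exhausts the cap
#: are declared infeasible (the empty cells of the published figures).
DEFAULT_MAX_ATTEMPTS: int = 100_000

#: The endorsement rule requires exactly this many favorable significant trials.
REQUIRED_SIGNIFICANT: int = 2


@dataclass(frozen=True)
class BFResult:
    """Pooled one-sided Bayes factor for one accepted replication."""

    bf: float
    pooled_t: float
    total_n_per_arm: int
    attempts: int


class InfeasibleScenarioError(RuntimeError):
    """No qualifying scenario set found within the attempt cap."""

    def __init__(self, config: ScenarioConfig, max_attempts: int):
        self.config = config
        self.max_attempts = max_attempts
        super().__init__(
            f"no qualifying scenario within {max_attempts} attempts for "
            f"effect={config.effect_size}, k={config.k_trials}, "
            f"n={config.n_per_arm}"
        )


def is_qualifying_set(
    results: Sequence[TrialTestResult], alpha: float = DEFAULT_ALPHA
) -> bool:
    """True iff exactly two trials are significant-favorable and none
    significant-unfavorable."""
    outcomes = [significant_favorable(res, alpha) for res in results]
    n_fav = sum(o is TrialOutcome.SIGNIFICANT_FAVORABLE for o in outcomes)
    n_unf = sum(o is TrialOutcome.SIGNIFICANT_UNFAVORABLE for o in outcomes)
    return n_fav == REQUIRED_SIGNIFICANT and n_unf == 0


def sample_qualifying_scenario(
    config: ScenarioConfig,
    rng: np.random.Generator,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    alpha: float = DEFAULT_ALPHA,
) -> Tuple[List[TrialData], int]:
    """Regenerate whole k-trial sets until one qualifies.

    Returns the first qualifying set together with the number of sets
    generated (the accepted one included).  Attempts are drawn in fixed-size
    internal batches for speed; the batch size depends only on the cell
    dimensions, so results are a deterministic function of ``rng``'s state.

    Raises
    ------
    InfeasibleScenarioError
        If ``max_attempts`` sets are generated without a qualifying one.
    """
    if max_attempts < 1:
        raise ValueError(f"max_attempts must be >= 1, got {max_attempts}")
    values_per_set = 2 * config.k_trials * config.n_per_arm
    batch = int(max(1, min(512, 2_000_000 // values_per_set)))
    done = 0
    while done < max_attempts:
        n_sets = min(batch, max_attempts - done)
        experimental, control = _simulate_sets(config, rng, n_sets)
        t, p, mean_diff = _batch_t_tests(experimental, control)
        fav = (p < alpha) & (mean_diff > 0)
        unf = (p < alpha) & (mean_diff < 0)
        qualifying = (fav.sum(axis=1) == REQUIRED_SIGNIFICANT) & (
            unf.sum(axis=1) == 0
        )
        hits = np.flatnonzero(qualifying)
        if hits.size:
            idx = int(hits[0])
            trials = [
                TrialData(experimental=experimental[idx, j], control=control[idx, j])
                for j in range(config.k_trials)
            ]
            return trials, done + idx + 1
        done += n_sets
    raise InfeasibleScenarioError(config, max_attempts)


def pooled_bf(
    trials: Sequence[TrialData],
    spec: BFSpec | None = None,
    attempts: int = 1,
) -> BFResult:
    """One-sided JZS Bayes factor for all trials combined.

    All experimental arms are concatenated into one sample and all control
    arms into another, exactly as if the k trials were a single big trial;
    the pooled-variance t-test on the combined samples then feeds the
    directional Bayes factor (alternative: experimental better).
    """
    if not trials:
        raise ValueError("need at least one trial to pool")
    spec = spec or BFSpec(direction="greater")
    experimental = np.concatenate([tr.experimental for tr in trials])
    control = np.concatenate([tr.control for tr in trials])
    res = pooled_t_test(experimental, control)
    bf = jzs_bf_directional(res.t, res.n1, res.n2, spec)
    return BFResult(
        bf=bf,
        pooled_t=res.t,
        total_n_per_arm=res.n1,
        attempts=attempts,
    )
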