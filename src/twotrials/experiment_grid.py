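"""Factorial simulation grid and per-cell evidence summaries.

The main study crosses three true effect sizes (0.2, 0.5, 0 SD), five trial
counts (2, 3, 4, 5, 20) and five per-arm sample sizes (20, 50, 100, 500,
1000) — 75 cells, 500 replications each.  Every replication rejection-samples
a qualifying scenario set, pools it and records the one-sided JZS Bayes
factor.  Per cell we summarize the 500 Bayes factors as

* percentages in the evidential bins [0,1), [1,3), [3,20), [20, inf) —
  favors-null / bare-mention / positive / strong; and
* Tukey box-plot statistics of log(BF) (whiskers at the most extreme points
  within 1.5 IQR of the quartiles).

Cells whose selection condition is essentially impossible under the
generator (a replication exhausts the attempt cap) are flagged infeasible
and carry no Bayes factors, mirroring the empty cells of the study's
figures.

Seeding is counter-based: replication ``j`` of cell ``i`` uses
``SeedSequence(master_seed, spawn_key=(i, j))``, so cells and replications
can run in any order — or in parallel — with identical results.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bayes_core import DEFAULT_PRIOR_SCALE, BFSpec
from .scenario_sampler import (
    DEFAULT_MAX_ATTEMPTS,
    InfeasibleScenarioError,
    pooled_bf,
    sample_qualifying_scenario,
)
from .trial_simulator import DEFAULT_ALPHA, ScenarioConfig

__all__ = [
    "GridConfig",
    "CellConfig",
    "CellSummary",
    "BoxplotStats",
    "BIN_EDGES",
    "BIN_LABELS",
    "build_grid",
    "run_cell",
    "run_grid",
    "categorize_bf",
    "bin_percentages",
    "boxplot_stats",
    "summaries_to_tidy",
    "summaries_to_table",
    "write_results",
]

#: Evidential bin boundaries on the Bayes-factor scale (upper-bin on ties).
BIN_EDGES: Tuple[float, float, float] = (1.0, 3.0, 20.0)

BIN_LABELS: Tuple[str, str, str, str] = (
    "favors_null",      # BF in [0, 1)
    "bare_mention",     # BF in [1, 3)
    "positive",         # BF in [3, 20)
    "strong",           # BF >= 20
)


@dataclass(frozen=True)
class GridConfig:
    """Full factorial study definition with the main-study defaults."""

    effect_sizes: Tuple[float, ...] = (0.2, 0.5, 0.0)
    trial_counts: Tuple[int, ...] = (2, 3, 4, 5, 20)
    sample_sizes: Tuple[int, ...] = (20, 50, 100, 500, 1000)
    replications: int = 500
    master_seed: int = 0
    alpha: float = DEFAULT_ALPHA
    prior_scale: float = DEFAULT_PRIOR_SCALE
    max_attempts: int = DEFAULT_MAX_ATTEMPTS
    effect_sd: float = 0.0
    sd_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")
        if not self.effect_sizes or not self.trial_counts or not self.sample_sizes:
            raise ValueError("factor lists must be non-empty")

    @property
    def n_cells(self) -> int:
        return len(self.effect_sizes) * len(self.trial_counts) * len(self.sample_sizes)


@dataclass(frozen=True)
class CellConfig:
    """One factorial combination plus everything needed to run it."""

    effect_size: float
    k_trials: int
    n_per_arm: int
    replications: int
    master_seed: int
    cell_index: int
    alpha: float = DEFAULT_ALPHA
    prior_scale: float = DEFAULT_PRIOR_SCALE
    max_attempts: int = DEFAULT_MAX_ATTEMPTS
    effect_sd: float = 0.0
    sd_ratio: float = 1.0

    def scenario(self) -> ScenarioConfig:
        return ScenarioConfig(
            effect_size=self.effect_size,
            n_per_arm=self.n_per_arm,
            k_trials=self.k_trials,
            sd_ratio=self.sd_ratio,
            effect_sd=self.effect_sd,
        )

    def replication_rng(self, replication: int) -> np.random.Generator:
        """Independent, order-invariant stream for one replication."""
        seq = np.random.SeedSequence(
            self.master_seed, spawn_key=(self.cell_index, replication)
        )
        return np.random.default_rng(seq)


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey box-plot summary (computed on log Bayes factors)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class CellSummary:
    """Distributional summary of one cell's pooled Bayes factors."""

    effect_size: float
    k_trials: int
    n_per_arm: int
    feasible: bool
    bf_values: np.ndarray
    attempts: np.ndarray
    bin_percentages: Optional[np.ndarray]
    box: Optional[BoxplotStats]
    mean_attempts: float


def build_grid(config: GridConfig) -> List[CellConfig]:
    """Expand a :class:`GridConfig` into one :class:`CellConfig` per cell.

    Cell order (and hence each cell's seed sub-stream) is the cartesian
    product effect-size x trial-count x sample-size, in the order given.
    """
    cells = []
    combos = itertools.product(
        config.effect_sizes, config.trial_counts, config.sample_sizes
    )
    for index, (effect, k, n) in enumerate(combos):
        cells.append(
            CellConfig(
                effect_size=effect,
                k_trials=k,
                n_per_arm=n,
                replications=config.replications,
                master_seed=config.master_seed,
                cell_index=index,
                alpha=config.alpha,
                prior_scale=config.prior_scale,
                max_attempts=config.max_attempts,
                effect_sd=config.effect_sd,
                sd_ratio=config.sd_ratio,
            )
        )
    return cells


def categorize_bf(bf: float) -> str:
    """Map a Bayes factor to its evidential bin label.

    Boundaries go to the upper bin (BF == 3 is "positive"); under the
    continuous generators an exact boundary has probability zero, so the
    convention never moves a percentage.
    """
    if not (np.isfinite(bf) and bf > 0):
        raise ValueError(f"Bayes factor must be positive and finite, got {bf!r}")
    return BIN_LABELS[int(np.searchsorted(BIN_EDGES, bf, side="right"))]


def bin_percentages(bf_values: np.ndarray) -> np.ndarray:
    """Percentages of Bayes factors in the four evidential bins (sums to 100)."""
    bf_values = np.asarray(bf_values, dtype=float)
    if bf_values.size == 0:
        raise ValueError("no Bayes factors to bin")
    idx = np.searchsorted(BIN_EDGES, bf_values, side="right")
    counts = np.bincount(idx, minlength=4)
    return 100.0 * counts / bf_values.size


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Tukey box-plot statistics of log-transformed values.

    Quartiles use linear interpolation; whiskers sit at the most extreme
    data points within 1.5 IQR of the quartiles; anything beyond is an
    outlier.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    if not (values > 0).all():
        raise ValueError("boxplot_stats expects positive Bayes factors")
    log_v = np.log(values)
    q1, med, q3 = np.percentile(log_v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    in_lo = log_v[log_v >= q1 - 1.5 * iqr]
    in_hi = log_v[log_v <= q3 + 1.5 * iqr]
    # whiskers sit at the most extreme points inside the fences but never
    # retreat inside the box (possible with interpolated quartiles on
    # heavily tied data)
    whisker_low = min(float(in_lo.min()), float(q1))
    whisker_high = max(float(in_hi.max()), float(q3))
    outliers = np.sort(log_v[(log_v < whisker_low) | (log_v > whisker_high)])
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def run_cell(cell: CellConfig) -> CellSummary:
    """Run every replication of one cell.

    A replication that exhausts the attempt cap marks the whole cell
    infeasible (its selection condition "does not realistically occur");
    the summary then carries no Bayes factors and records the cap as the
    mean attempt count.
    """
    scenario = cell.scenario()
    spec = BFSpec(prior_scale=cell.prior_scale, direction="greater")
    bfs = np.empty(cell.replications)
    attempts = np.empty(cell.replications, dtype=np.int64)
    for j in range(cell.replications):
        rng = cell.replication_rng(j)
        try:
            trials, n_attempts = sample_qualifying_scenario(
                scenario, rng, max_attempts=cell.max_attempts, alpha=cell.alpha
            )
        except InfeasibleScenarioError:
            return CellSummary(
                effect_size=cell.effect_size,
                k_trials=cell.k_trials,
                n_per_arm=cell.n_per_arm,
                feasible=False,
                bf_values=np.empty(0),
                attempts=np.empty(0, dtype=np.int64),
                bin_percentages=None,
                box=None,
                mean_attempts=float(cell.max_attempts),
            )
        result = pooled_bf(trials, spec, attempts=n_attempts)
        bfs[j] = result.bf
        attempts[j] = result.attempts
    return CellSummary(
        effect_size=cell.effect_size,
        k_trials=cell.k_trials,
        n_per_arm=cell.n_per_arm,
        feasible=True,
        bf_values=bfs,
        attempts=attempts,
        bin_percentages=bin_percentages(bfs),
        box=boxplot_stats(bfs),
        mean_attempts=float(attempts.mean()),
    )


def run_grid(
    config: GridConfig,
    out_dir: str | Path | None = None,
    jobs: int = 1,
    progress: bool = False,
) -> List[CellSummary]:
    """Run the full grid, optionally in parallel, optionally writing results.

    With ``out_dir`` set, writes ``results.csv`` (tidy, one row per
    replication), ``summary.csv`` (one row per cell) and ``manifest.json``
    (full configuration) — everything the reporting layer needs.
    """
    cells = build_grid(config)
    if progress:
        from tqdm import tqdm

        cells_iter = tqdm(cells, desc="cells")
    else:
        cells_iter = cells
    if jobs > 1:
        from joblib import Parallel, delayed

        summaries = Parallel(n_jobs=jobs)(delayed(run_cell)(c) for c in cells_iter)
    else:
        summaries = [run_cell(c) for c in cells_iter]
    if out_dir is not None:
        write_results(summaries, config, out_dir)
    return summaries


# ---------------------------------------------------------------------------
# results persistence
# ---------------------------------------------------------------------------

def summaries_to_tidy(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """One row per replication: effect, k, n, replication, bf, attempts."""
    frames = []
    for s in summaries:
        if not s.feasible:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "effect": s.effect_size,
                    "k": s.k_trials,
                    "n": s.n_per_arm,
                    "replication": np.arange(s.bf_values.size),
                    "bf": s.bf_values,
                    "attempts": s.attempts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["effect", "k", "n", "replication", "bf", "attempts"]
        )
    return pd.concat(frames, ignore_index=True)


def summaries_to_table(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """One row per cell: feasibility, bin percentages, box statistics."""
    rows = []
    for s in summaries:
        row = {
            "effect": s.effect_size,
            "k": s.k_trials,
            "n": s.n_per_arm,
            "feasible": s.feasible,
            "mean_attempts": s.mean_attempts,
        }
        if s.feasible:
            row.update(
                {
                    f"pct_{label}": s.bin_percentages[i]
                    for i, label in enumerate(BIN_LABELS)
                }
            )
            row.update(
                {
                    "log_bf_median": s.box.median,
                    "log_bf_q1": s.box.q1,
                    "log_bf_q3": s.box.q3,
                    "log_bf_whisker_low": s.box.whisker_low,
                    "log_bf_whisker_high": s.box.whisker_high,
                    "n_outliers": s.box.outliers.size,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    summaries: Sequence[CellSummary], config: GridConfig, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries_to_tidy(summaries).to_csv(out / "results.csv", index=False)
    summaries_to_table(summaries).to_csv(out / "summary.csv", index=False)
    manifest = dataclasses.asdict(config)
    manifest["n_cells"] = config.n_cells
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
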