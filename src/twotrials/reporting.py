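"""Figures and headline numbers from a completed grid run.

Everything here is a pure function of the tidy results CSV written by
:func:`twotrials.experiment_grid.run_grid` — re-rendering never touches the
results files.  Two figure families mirror the study's presentation:

* per effect size, a panel of box plots of the pooled Bayes factor (log
  scale, dashed reference line at BF = 1) with one panel per trial count
  and one box per sample size, infeasible cells left blank;
* per effect size, stacked bars of the four evidential-bin percentages.

``extract_headlines`` pulls out the specific cells the study quotes (the
share of BF < 1 at effect 0.2, k = 20, n = 20; the share of BF < 3 at
effect 0.2, k = 5, n = 20; zero-effect medians at k = 20) together with
Wilson 95% intervals for the binomial percentages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .experiment_grid import BIN_LABELS, bin_percentages

__all__ = [
    "load_tidy",
    "render_boxplot_figure",
    "render_bin_barchart",
    "extract_headlines",
    "report",
]

_BIN_COLORS = ("black", "red", "green", "blue")  # bottom-to-top bin order


def load_tidy(results_dir: str | Path) -> pd.DataFrame:
    """Read the tidy per-replication results CSV from a run directory."""
    return pd.read_csv(Path(results_dir) / "results.csv")


def _cells(df: pd.DataFrame, effect: float, k: int, ns: Sequence[int]):
    sub = df[(df["effect"] == effect) & (df["k"] == k)]
    return [sub.loc[sub["n"] == n, "bf"].to_numpy() for n in ns]


def _panel_axes(n_panels: int):
    ncols = min(n_panels, 3)
    nrows = -(-n_panels // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.0 * ncols, 3.0 * nrows), squeeze=False
    )
    return fig, axes.ravel()


def render_boxplot_figure(
    df: pd.DataFrame, effect: float, path: str | Path
) -> Path:
    """Box plots of pooled Bayes factors: one panel per trial count, one box
    per sample size, log-scale y axis, dashed line at BF = 1."""
    ks = sorted(df.loc[df["effect"] == effect, "k"].unique())
    ns = sorted(df.loc[df["effect"] == effect, "n"].unique())
    if not ks:
        ks, ns = [], []
    fig, axes = _panel_axes(max(len(ks), 1))
    for ax, k in zip(axes, ks):
        values = _cells(df, effect, int(k), ns)
        positions = [i + 1 for i, v in enumerate(values) if v.size]
        present = [v for v in values if v.size]
        if present:
            ax.boxplot(present, positions=positions, whis=1.5, widths=0.6)
        ax.set_yscale("log")
        ax.axhline(1.0, linestyle="--", color="grey")
        ax.set_xlim(0.5, len(ns) + 0.5)
        ax.set_xticks(range(1, len(ns) + 1))
        ax.set_xticklabels([str(n) for n in ns])
        ax.set_title(f"{int(k)} trials")
        ax.set_xlabel("participants per group")
        ax.set_ylabel("BF (alternative over null)")
    for ax in axes[len(ks):]:
        ax.set_visible(False)
    fig.suptitle(f"Pooled one-sided JZS Bayes factors, true effect {effect} SD")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_bin_barchart(
    df: pd.DataFrame, effect: float, path: str | Path
) -> Path:
    """Stacked evidential-bin percentages (black/red/green/blue, bottom-up:
    BF < 1, 1-3, 3-20, >= 20); one panel per trial count."""
    ks = sorted(df.loc[df["effect"] == effect, "k"].unique())
    ns = sorted(df.loc[df["effect"] == effect, "n"].unique())
    fig, axes = _panel_axes(max(len(ks), 1))
    for ax, k in zip(axes, ks):
        values = _cells(df, effect, int(k), ns)
        bottoms = np.zeros(len(ns))
        for b, (label, color) in enumerate(zip(BIN_LABELS, _BIN_COLORS)):
            heights = np.array(
                [bin_percentages(v)[b] if v.size else 0.0 for v in values]
            )
            ax.bar(
                range(len(ns)), heights, bottom=bottoms, color=color,
                label=label, width=0.6,
            )
            bottoms += heights
        ax.set_xticks(range(len(ns)))
        ax.set_xticklabels([str(n) for n in ns])
        ax.set_ylim(0, 100)
        ax.set_title(f"{int(k)} trials")
        ax.set_xlabel("participants per group")
        ax.set_ylabel("% of replications")
    for ax in axes[len(ks):]:
        ax.set_visible(False)
    if len(ks):
        axes[0].legend(fontsize=7)
    fig.suptitle(f"Evidential bins, true effect {effect} SD")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _share_below(df: pd.DataFrame, effect: float, k: int, n: int, cutoff: float
                 ) -> Optional[Dict[str, float]]:
    bf = df[
        (df["effect"] == effect) & (df["k"] == k) & (df["n"] == n)
    ]["bf"].to_numpy()
    if bf.size == 0:
        return None
    count = int((bf < cutoff).sum())
    lo, hi = proportion_confint(count, bf.size, alpha=0.05, method="wilson")
    return {
        "effect": effect,
        "k": k,
        "n": n,
        "cutoff": cutoff,
        "replications": int(bf.size),
        "percent_below": 100.0 * count / bf.size,
        "wilson_95_low": 100.0 * float(lo),
        "wilson_95_high": 100.0 * float(hi),
    }


def extract_headlines(df: pd.DataFrame) -> Dict[str, object]:
    """Headline statistics for the specific cells the study quotes.

    Missing cells (not simulated, or infeasible) produce warnings in the
    output rather than an exception, so partial runs still report.
    """
    headlines: Dict[str, object] = {}
    warnings: List[str] = []

    quoted = {
        "bf_below_1_effect02_k20_n20": (0.2, 20, 20, 1.0),
        "bf_below_3_effect02_k5_n20": (0.2, 5, 20, 3.0),
    }
    for key, (effect, k, n, cutoff) in quoted.items():
        entry = _share_below(df, effect, k, n, cutoff)
        if entry is None:
            warnings.append(f"cell effect={effect}, k={k}, n={n} missing")
        else:
            headlines[key] = entry

    zero = df[(df["effect"] == 0.0) & (df["k"] == 20)]
    medians = {
        int(n): float(np.median(grp["bf"])) for n, grp in zero.groupby("n")
    }
    if medians:
        headlines["zero_effect_k20_median_bf_by_n"] = medians
    else:
        warnings.append("zero-effect k=20 cells missing")
    headlines["warnings"] = warnings
    return headlines


def report(results_dir: str | Path, out_dir: str | Path) -> Dict[str, object]:
    """Render all figures and write headline numbers for a run directory."""
    df = load_tidy(results_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for effect in sorted(df["effect"].unique()):
        tag = str(effect).replace(".", "p").replace("-", "m")
        render_boxplot_figure(df, effect, out / f"boxplots_effect_{tag}.png")
        render_bin_barchart(df, effect, out / f"bins_effect_{tag}.png")
    headlines = extract_headlines(df)
    with open(out / "headlines.json", "w") as fh:
        json.dump(headlines, fh, indent=2)
    return headlines
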