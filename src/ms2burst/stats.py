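"""Between-condition comparison of burst properties.

Conditions (reporter genotypes) are compared per metric — total output,
burst amplitude, burst duration, burst frequency — by the two-sided
Wilcoxon rank-sum test, with medians reported relative to the control
condition. The rank-sum p-value is exact (full enumeration of the
permutation distribution over midranks) for small samples and a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

EXACT_MIN_N = 8  # exact enumeration whenever min(n) <= this ...
EXACT_MAX_COMBINATIONS = 500_000  # ... and the subset count stays tractable

METRICS = ("total_output", "amplitude", "duration", "n_bursts")


@dataclass
class GroupComparison:
    """One condition-vs-control comparison of one burst metric."""

    metric: str
    condition: str
    control: str
    n_condition: int
    n_control: int
    median: float
    control_median: float
    median_ratio: float
    statistic: float
    p_value: float


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``sample_a``
    (midranks for ties). The p-value is exact — every assignment of the
    combined midranks to group A enumerated — when the smaller sample
    has at most 8 observations and the subset count is tractable;
    otherwise a tie-corrected normal approximation with continuity
    correction is used. Two samples with all values identical give
    p = 1.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs >= 1 observation")
    combined = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = _midranks(combined)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if np.all(combined == combined[0]):
        return w, 1.0

    n_small = min(n1, n2)
    if n_small <= EXACT_MIN_N and comb(n, n1) <= EXACT_MAX_COMBINATIONS:
        dev = abs(w - mu) - 1e-9
        hits = 0
        total = 0
        # enumerate rank sums of the smaller group; symmetric in groups
        k = n1 if n1 <= n2 else n2
        mu_k = k * (n + 1) / 2.0
        for idx in combinations(range(n), k):
            s = ranks[list(idx)].sum()
            if abs(s - mu_k) >= dev:
                hits += 1
            total += 1
        return w, hits / total

    # tie-corrected normal approximation
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _metric_values(summary: pd.DataFrame, metric: str) -> np.ndarray:
    """Extract one metric's per-nucleus values from a summary table.

    Zero-burst nuclei are kept for total output and burst frequency but
    dropped for amplitude and duration, where the metric is undefined.
    """
    if metric == "total_output":
        return summary["total_output"].to_numpy(float)
    if metric == "n_bursts":
        return summary["n_bursts"].to_numpy(float)
    if metric == "amplitude":
        v = summary["mean_amplitude"].to_numpy(float)
    elif metric == "duration":
        v = summary["mean_duration_s"].to_numpy(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return v[np.isfinite(v)]


def compare_conditions(
    summaries: dict[str, pd.DataFrame], control: str
) -> tuple[list[GroupComparison], pd.DataFrame]:
    """Compare every condition against the control for all four metrics.

    Returns the comparison records and a table that additionally
    carries Benjamini-Hochberg adjusted p-values across the emitted
    non-control comparisons (the raw per-comparison p is the primary
    readout; the adjusted column is informational).
    """
    if control not in summaries:
        raise ValueError(f"control condition {control!r} not among conditions")
    if len(summaries) < 2:
        raise ValueError("need >= 2 conditions")
    for name, df in summaries.items():
        if len(df) == 0:
            raise ValueError(f"condition {name!r} is empty")

    comparisons: list[GroupComparison] = []
    for metric in METRICS:
        ctrl_vals = _metric_values(summaries[control], metric)
        for name, df in summaries.items():
            vals = _metric_values(df, metric)
            if vals.size == 0 or ctrl_vals.size == 0:
                continue
            if name == control:
                stat, p = float(_midranks(np.concatenate([vals, vals]))[: vals.size].sum()), 1.0
                med = float(np.median(vals))
                cmed = med
            else:
                stat, p = wilcoxon_rank_sum(vals, ctrl_vals)
                med = float(np.median(vals))
                cmed = float(np.median(ctrl_vals))
            comparisons.append(
                GroupComparison(
                    metric=metric,
                    condition=name,
                    control=control,
                    n_condition=int(vals.size),
                    n_control=int(ctrl_vals.size),
                    median=med,
                    control_median=cmed,
                    median_ratio=med / cmed if cmed != 0 else float("nan"),
                    statistic=stat,
                    p_value=p,
                )
            )

    table = pd.DataFrame([vars(c) for c in comparisons])
    mask = table["condition"] != control
    table["p_bh"] = np.nan
    if mask.any():
        table.loc[mask, "p_bh"] = _benjamini_hochberg(table.loc[mask, "p_value"].to_numpy())
    return comparisons, table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def transcription_onset(
    smoothed: np.ndarray, threshold: float
) -> int | None:
    """First frame index with smoothed value above threshold, else None."""
    above = np.flatnonzero(np.asarray(smoothed) > threshold)
    return int(above[0]) if above.size else None


def render_report(
    comparison_table: pd.DataFrame,
    traces_by_condition: dict[str, dict[int, np.ndarray]],
    start_threshold: float,
    out_dir: str | Path,
    summaries_by_condition: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the comparison figures and their backing tables.

    Produces a per-condition trajectory heatmap with nuclei ordered by
    transcription onset (first frame above threshold; silent nuclei
    last), boxplots of total output / amplitude / duration, a burst
    frequency histogram, and ``comparisons.tsv`` with every number shown
    in the figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["comparisons"] = out / "comparisons.tsv"
    comparison_table.to_csv(paths["comparisons"], sep="\t", index=False)

    # trajectory heatmaps, onset-ordered
    n_cond = len(traces_by_condition)
    fig, axes = plt.subplots(1, max(n_cond, 1), figsize=(4 * max(n_cond, 1), 4), squeeze=False)
    order_rows = []
    for ax, (name, traces) in zip(axes[0], traces_by_condition.items()):
        ids = sorted(traces)
        length = max((traces[t].size for t in ids), default=0)
        onsets = []
        for t in ids:
            o = transcription_onset(np.nan_to_num(traces[t]), start_threshold)
            onsets.append((o if o is not None else np.inf, t))
        onsets.sort(key=lambda x: (x[0], x[1]))
        mat = np.full((len(ids), length), np.nan)
        for row, (_, t) in enumerate(onsets):
            mat[row, : traces[t].size] = traces[t]
            order_rows.append((name, row, t))
        if mat.size:
            ax.imshow(np.nan_to_num(mat), aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_title(name)
        ax.set_xlabel("frame")
        ax.set_ylabel("nucleus (onset order)")
    fig.tight_layout()
    paths["heatmap"] = out / "trajectories.png"
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)
    pd.DataFrame(order_rows, columns=["condition", "row", "track_id"]).to_csv(
        out / "heatmap_order.tsv", sep="\t", index=False
    )
    paths["heatmap_order"] = out / "heatmap_order.tsv"

    # metric distributions: boxplots when per-nucleus values are available,
    # otherwise bars of the medians from the comparison table
    fig, axes = plt.subplots(1, 4, figsize=(16, 4))
    for ax, metric in zip(axes, METRICS):
        sub = comparison_table[comparison_table["metric"] == metric]
        if summaries_by_condition is not None and metric != "n_bursts":
            names = list(summaries_by_condition)
            data = [_metric_values(summaries_by_condition[n], metric) for n in names]
            ax.boxplot(data, tick_labels=names, showmeans=False)
        elif summaries_by_condition is not None:
            for name, df in summaries_by_condition.items():
                ax.hist(
                    _metric_values(df, "n_bursts"),
                    bins=np.arange(-0.5, 10.5),
                    histtype="step",
                    label=name,
                )
            ax.legend(fontsize=7)
        else:
            ax.bar(sub["condition"], sub["median"], color="#7fb3d5")
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    paths["metrics"] = out / "metric_medians.png"
    fig.savefig(paths["metrics"], dpi=120)
    plt.close(fig)
    return paths
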