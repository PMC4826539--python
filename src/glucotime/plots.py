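"""The three standard figures: p-value boxplots, daily CDF panels, and
component interval plots.  Figures are derived views of the CSV/JSON
outputs and are never inputs to computation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mixture import MEAL_TIMES_DEFAULT, ComponentSummary
from .records import StudyPanel, WardDay


def plot_cdf_panel(
    days: list[WardDay],
    out_path: str | Path,
    aggregate: bool = True,
    title: str | None = None,
):
    """Daily empirical CDFs (light) with the pooled two-month CDF (dark)
    and the Uniform(0, 24) diagonal reference.

    Returns the figure, or None (with a warning on the module logger) when
    no day has data.
    """
    days_with_data = [d for d in days if d.n > 0]
    if not days_with_data:
        import logging

        logging.getLogger(__name__).warning("no data to plot; %s not written", out_path)
        return None
    fig, ax = plt.subplots(figsize=(6, 5))
    for wd in days_with_data:
        y = wd.timings
        ax.step(np.concatenate([[0], y, [24]]),
                np.concatenate([[0], np.arange(1, wd.n + 1) / wd.n, [1]]),
                where="post", color="0.75", lw=0.6)
    if aggregate:
        pooled = np.sort(np.concatenate([d.timings for d in days_with_data]))
        ax.step(np.concatenate([[0], pooled, [24]]),
                np.concatenate([[0], np.arange(1, pooled.size + 1) / pooled.size, [1]]),
                where="post", color="0.2", lw=1.8, label="aggregate")
    ax.plot([0, 24], [0, 1], ":", color="k", lw=1, label="Uniform(0, 24)")
    ax.set_xlim(0, 24)
    ax.set_ylim(0, 1)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("cumulative proportion")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return fig


def plot_pvalue_boxes(
    ks_results: pd.DataFrame,
    ranks: pd.DataFrame,
    power: pd.DataFrame,
    out_path: str | Path,
    specialty: dict[str, str] | None = None,
    alpha: float = 0.05,
):
    """−log10(p) boxplots per ward, ordered by rank, shaded by power.

    High-power wards (mean or median simulated power ≥ threshold) are drawn
    in white, the rest in dark gray; the panel annotates each ward's
    min/median/max daily n.  ``specialty`` optionally groups the ordering.
    """
    if ks_results.empty:
        return None
    order = ranks.sort_values("rank")["ward"].tolist()
    if specialty:
        order = sorted(order, key=lambda w: (specialty.get(w, "?"),
                                             order.index(w)))
    hp = power.set_index("ward")["high_power"].to_dict()
    data, colors, labels = [], [], []
    counts = []
    for w in order:
        g = ks_results[ks_results["ward"] == w].dropna(subset=["p_value"])
        vals = -np.log10(np.clip(g["p_value"].to_numpy(), 1e-300, None))
        data.append(vals)
        colors.append("white" if hp.get(w, False) else "0.4")
        labels.append(w)
        n = g["n"].to_numpy()
        counts.append((int(n.min()), int(np.median(n)), int(n.max())) if n.size else (0, 0, 0))
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(order)), 5))
    bp = ax.boxplot(data, patch_artist=True, tick_labels=labels)
    for patch, c in zip(bp["boxes"], colors):
        patch.set_facecolor(c)
    ax.axhline(-np.log10(alpha), color="0.6", ls="--", lw=1)
    for i, (lo, med, hi) in enumerate(counts):
        ax.annotate(f"{lo}/{med}/{hi}", (i + 1, ax.get_ylim()[0]),
                    fontsize=6, ha="center", va="bottom")
    ax.set_ylabel(r"$-\log_{10}(p)$, 1S-KS")
    ax.set_xlabel("ward (ranked; white = high power)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return fig


def plot_components(
    summaries: dict[str, list[ComponentSummary]],
    out_path: str | Path,
    meal_times=MEAL_TIMES_DEFAULT,
):
    """Per-ward mean ± 1.96 SD interval bars for the four narrow components,
    with vertical mealtime/bedtime reference lines."""
    wards = [w for w, s in summaries.items()
             if sum(c.narrow for c in s) == 4]
    if not wards:
        return None
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(wards) + 2))
    for i, w in enumerate(wards):
        for c in summaries[w]:
            if not c.narrow:
                continue
            lo, hi = c.interval
            ax.plot([lo, hi], [i, i], "-", color="0.3", lw=1.5,
                    marker="|", markersize=8)
            ax.plot(c.mean_hours, i, "D", color="0.1", markersize=5)
    for m in meal_times:
        ax.axvline(m, color="0.7", ls=":", lw=1)
    ax.set_yticks(range(len(wards)))
    ax.set_yticklabels(wards)
    ax.set_xlim(0, 24)
    ax.set_xlabel("time of day (h)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return fig
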