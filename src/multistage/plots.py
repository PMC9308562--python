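"""Diagnostic figures, rendered from exported tables.

All plotting functions accept plain DataFrames (the pipeline's CSV outputs
read back in) rather than live objects, so every figure is reproducible from
artifacts alone.  Output is vector graphics (PDF/SVG) via matplotlib.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["loglog_plot", "classification_scatter", "rates_boxplot"]

_TERTILE_COLORS = {"sporadic": "tab:orange", "mid-range": "tab:green", "late-onset": "tab:red"}


def loglog_plot(curves: dict[str, pd.DataFrame], fits: pd.DataFrame | None, path) -> None:
    """log(adjusted cumulative hazard) vs log(age) per stratum.

    ``curves`` maps stratum label -> adjusted-curve table (columns age,
    S_adj, var_adj); dashed lines are pointwise 95% intervals from the
    Greenwood variance mapped to the log-H scale.  ``fits`` (optional,
    columns stratum, m, L) overlays the fitted straight line of slope m.
    """
    if not curves:
        raise ValueError("no strata to plot")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for i, (label, df) in enumerate(curves.items()):
        s = df["S_adj"].to_numpy(dtype=float)
        ok = (s > 0) & (s < 1)
        if ok.sum() < 2:
            continue
        t = df["age"].to_numpy(dtype=float)[ok]
        H = -np.log(s[ok])
        color = f"C{i}"
        ax.plot(np.log(t), np.log(H), drawstyle="steps-post", color=color, label=label)
        if "var_adj" in df:
            var = df["var_adj"].to_numpy(dtype=float)[ok]
            se_logH = np.sqrt(var) / (s[ok] * H)  # delta method twice
            ax.plot(np.log(t), np.log(H) + 1.96 * se_logH, "--", lw=0.8, color=color)
            ax.plot(np.log(t), np.log(H) - 1.96 * se_logH, "--", lw=0.8, color=color)
        if fits is not None:
            row = fits[fits["stratum"].astype(str) == str(label)]
            if len(row):
                m, L = float(row.iloc[0]["m"]), float(row.iloc[0]["L"])
                x = np.log(t[[0, -1]])
                ax.plot(x, m * (x - np.log(L)), color=color, lw=1.5, alpha=0.6)
    ax.set_xlabel("log(age)")
    ax.set_ylabel("log(adjusted cumulative hazard)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def classification_scatter(classification: pd.DataFrame, path) -> None:
    """F(50) vs relative increase by age 100, log axes, tertile colours."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for tert, sub in classification.groupby("tertile"):
        ax.scatter(
            sub["F50"],
            sub["relative_increase"],
            s=14,
            color=_TERTILE_COLORS.get(str(tert), "gray"),
            label=str(tert),
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("probability of first admission by age 50, F(50)")
    ax.set_ylabel("relative increase by 100, (F(100)-F(50))/F(50)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def rates_boxplot(rates: pd.DataFrame, path, measure: str = "relative_aging_rate") -> None:
    """Box plots of RR or RAR per covariate level, split by tertile group.

    Whiskers at 1 x the interquartile range; one panel per group present in
    the ``tertile`` column.
    """
    groups = [g for g in ("sporadic", "late-onset") if g in set(rates.get("tertile", ()))]
    if not groups:
        groups = [None]
    fig, axes = plt.subplots(1, len(groups), figsize=(5.5 * len(groups), 4), squeeze=False)
    for ax, g in zip(axes[0], groups):
        sub = rates if g is None else rates[rates["tertile"] == g]
        levels = sorted(sub["level"].unique())
        data = [sub.loc[sub["level"] == lv, measure].to_numpy(dtype=float) for lv in levels]
        ax.boxplot(data, tick_labels=levels, whis=1.0)
        ax.axhline(1.0, color="gray", lw=0.8)
        ax.set_title(g or "all diseases")
        ax.set_ylabel(measure.replace("_", " "))
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
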