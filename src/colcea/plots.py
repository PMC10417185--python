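"""Minimal figure helpers: tornado diagram and CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_tornado", "plot_ceac"]


def plot_tornado(tornado_df: pd.DataFrame, base_icer: float, path: str | Path,
                 wtp: float | None = None) -> Path:
    df = tornado_df.sort_values("spread")
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(df) + 1.5))
    y = range(len(df))
    lows = df[["icer_low", "icer_high"]].min(axis=1)
    highs = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(y, highs - lows, left=lows, color="#4878a8", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1, label="base-case ICER")
    if wtp is not None:
        ax.axvline(wtp, color="tab:red", ls="--", lw=1, label="WTP")
    ax.set_yticks(list(y), df["parameter"])
    ax.set_xlabel("ICER (I$/DALY averted)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(ceac_df: pd.DataFrame, path: str | Path,
              base_wtp: float | None = None) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for strategy, grp in ceac_df.groupby("strategy"):
        ax.plot(grp["wtp"], grp["probability_optimal"], label=strategy)
    if base_wtp is not None:
        ax.axvline(base_wtp, color="k", ls="--", lw=1)
    ax.set_xlabel("Willingness-to-pay (I$/DALY averted)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
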