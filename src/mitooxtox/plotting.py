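"""Diagnostic figures: SR scatter and BEQ contribution bars."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .iceberg import IcebergResult

__all__ = ["plot_specificity_scatter", "plot_contributions"]


def plot_specificity_scatter(
    table: pd.DataFrame, path: str | Path, threshold: float = 10.0
) -> None:
    """SR_baseline vs SR_cytotoxicity on log axes with TR diagonals.

    Points above/right of the dashed threshold lines act specifically;
    the grey diagonals are constant toxic ratio TR = SR_baseline/SR_cyto.
    """
    df = table.dropna(subset=["sr_cyto", "sr_baseline"])
    fig, ax = plt.subplots(figsize=(5, 5))
    if not df.empty:
        for cls, sub in df.groupby("classification"):
            ax.loglog(sub["sr_cyto"], sub["sr_baseline"], "o", label=cls, alpha=0.8)
        lo = min(df["sr_cyto"].min(), df["sr_baseline"].min()) / 10
        hi = max(df["sr_cyto"].max(), df["sr_baseline"].max()) * 10
    else:
        lo, hi = 0.1, 1e3
    span = np.array([lo, hi])
    for tr in (0.1, 1, 10, 100, 1000):
        ax.loglog(span, tr * span, color="0.8", lw=0.7, zorder=0)
    ax.axvline(threshold, ls="--", color="k", lw=0.8)
    ax.axhline(threshold, ls="--", color="k", lw=0.8)
    ax.set_xlabel("SR_cytotoxicity = IC10 / EC10(MMP)")
    ax.set_ylabel("SR_baseline = IC10,baseline / EC10(MMP)")
    if not df.empty:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contributions(results: Sequence[IcebergResult], path: str | Path) -> None:
    """Stacked per-chemical BEQ_i bars with BEQ_bio markers per sample."""
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(results)), 4))
    chem_ids = sorted({c for r in results for c in r.beq_i})
    bottoms = np.zeros(len(results))
    xs = np.arange(len(results))
    for chem in chem_ids:
        vals = np.array([r.beq_i.get(chem, 0.0) for r in results])
        ax.bar(xs, vals, bottom=bottoms, label=chem)
        bottoms += vals
    bios = [r.beq_bio for r in results]
    ax.plot(
        [x for x, b in zip(xs, bios) if b is not None],
        [b for b in bios if b is not None],
        "k_", markersize=18, label="BEQ_bio",
    )
    ax.set_yscale("log")
    ax.set_xticks(xs, [r.sample_id for r in results], rotation=45, ha="right")
    ax.set_ylabel("BEQ (mol ref-equivalents / L water)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
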