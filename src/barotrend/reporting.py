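"""Figure and table rendering for a completed analysis bundle.

Outputs (PNG + SVG, deterministic file names under ``outdir``):

* ``corrplot`` — heatmap of median Winsorized correlations by comparison x
  scope, with an X drawn over cells whose permutation test is not
  significant at 0.05;
* ``ridgeline`` — per-comparison smoothed densities of the three
  within-group bootstrap distributions, stacked vertically;
* ``boxplots`` — per-comparison box plots of the within-group bootstrap
  distributions;
* ``synoptic`` — the trend-classification table as CSV and as a rendered
  image, with ``---`` marking patterns without empirical support.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .cohort import GROUPS
from .pipeline import ResultBundle

log = logging.getLogger("barotrend")


def _save(fig, outdir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = outdir / f"{stem}.{ext}"
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def render_corrplot(bundle: ResultBundle, outdir: Path) -> list[Path]:
    pivot = bundle.summary.pivot(
        index="comparison", columns="scope", values="median_wincorr"
    )
    pvals = bundle.summary.pivot(index="comparison", columns="scope", values="perm_p")
    order = list(bundle.ensemble.comparisons)
    scopes = list(bundle.ensemble.scopes)
    pivot = pivot.loc[order, scopes]
    pvals = pvals.loc[order, scopes]
    fig, ax = plt.subplots(figsize=(6, 8))
    sns.heatmap(
        pivot, vmin=-1, vmax=1, cmap="RdBu_r", annot=True, fmt=".2f",
        cbar_kws={"label": "median WINcorr"}, ax=ax,
    )
    for yi, comp in enumerate(order):
        for xi, scope in enumerate(scopes):
            if pvals.loc[comp, scope] >= 0.05:
                ax.plot(
                    [xi + 0.15, xi + 0.85], [yi + 0.15, yi + 0.85], color="k", lw=1.5
                )
                ax.plot(
                    [xi + 0.15, xi + 0.85], [yi + 0.85, yi + 0.15], color="k", lw=1.5
                )
    ax.set_title("Median Winsorized correlation with adjusted alpha")
    return _save(fig, outdir, "corrplot")


def render_ridgeline(bundle: ResultBundle, outdir: Path) -> list[Path]:
    vals = bundle.ensemble.values
    comps = bundle.ensemble.comparisons
    ncol = 4
    nrow = int(np.ceil(len(comps) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.6 * nrow), sharex=True)
    palette = {0: "#1f77b4", 1: "#ff7f0e", 2: "#2ca02c"}
    for ci, comp in enumerate(comps):
        ax = axes.flat[ci]
        for gi, g in enumerate(GROUPS):
            x = vals[:, ci, 1 + gi]
            x = x[np.isfinite(x)]
            if x.size < 2 or np.ptp(x) == 0:
                continue
            sns.kdeplot(x=x, ax=ax, fill=True, alpha=0.4, color=palette[gi], label=g)
        ax.set_title(f"alpha vs {comp}", fontsize=9)
        ax.set_ylabel("")
    for ax in axes.flat[len(comps):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=7)
    fig.suptitle("Bootstrap WINcorr distributions by SAP group", y=1.0)
    return _save(fig, outdir, "ridgeline")


def render_boxplots(bundle: ResultBundle, outdir: Path) -> list[Path]:
    vals = bundle.ensemble.values
    comps = bundle.ensemble.comparisons
    ncol = 4
    nrow = int(np.ceil(len(comps) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow))
    for ci, comp in enumerate(comps):
        ax = axes.flat[ci]
        data = [vals[:, ci, 1 + gi][np.isfinite(vals[:, ci, 1 + gi])] for gi in range(3)]
        ax.boxplot(data, tick_labels=list(GROUPS), showfliers=False)
        ax.axhline(0, color="grey", lw=0.6)
        ax.set_title(f"alpha vs {comp}", fontsize=9)
    for ax in axes.flat[len(comps):]:
        ax.axis("off")
    fig.tight_layout()
    return _save(fig, outdir, "boxplots")


def render_synoptic(bundle: ResultBundle, outdir: Path) -> list[Path]:
    df = bundle.trends.copy()
    df["monotonic"] = np.where(df["monotonic_p"] < 0.05, df["monotonic"], "---")
    df["umbrella"] = np.where(df["umbrella_p"] < 0.05, df["umbrella"], "---")
    tab = df[
        ["comparison", "monotonic", "umbrella", "endpoint_profile",
         "strongest_group", "band"]
    ]
    csv_path = outdir / "synoptic.csv"
    tab.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(9, 0.4 * len(tab) + 1))
    ax.axis("off")
    table = ax.table(
        cellText=tab.values, colLabels=tab.columns, loc="center", cellLoc="center"
    )
    table.scale(1, 1.3)
    paths = _save(fig, outdir, "synoptic")
    return [csv_path, *paths]


def render_reports(bundle: ResultBundle, outdir) -> list[Path]:
    """Render all figures/tables; skips ridgelines if the ensemble is empty."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    paths += render_corrplot(bundle, outdir)
    if bundle.ensemble.values.size:
        paths += render_ridgeline(bundle, outdir)
        paths += render_boxplots(bundle, outdir)
    else:  # pragma: no cover - defensive
        log.warning("ensemble empty: ridgeline and box plots skipped")
    paths += render_synoptic(bundle, outdir)
    return paths
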