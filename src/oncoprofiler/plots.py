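"""Figure rendering for the four analyses.

Every function consumes only the tidy tables the analysis modules emit
(plots are a pure function of tables) and writes one file per panel with
deterministic names ``<analysis>_<entity>[_<gene>].<ext>``. Empty tables
produce a placeholder "no data" panel rather than a crash.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "global_grid",
    "mutation_pies",
    "methylation_region_grid",
    "delta_histograms",
    "waterfall_plots",
    "expression_boxplots",
    "cnv_category_bars",
]


def _placeholder(path: Path, title: str) -> Path:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.text(0.5, 0.5, "no data", ha="center", va="center", fontsize=14, color="grey")
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(path)
    plt.close(fig)
    return path


def global_grid(
    matrix: pd.DataFrame, outdir, name: str, label: str, fmt: str = "png"
) -> Path:
    """Gene x entity heat grid (global mutation / expression / CNV profile)."""
    outdir = Path(outdir)
    path = outdir / f"{name}_global.{fmt}"
    if matrix.empty:
        return _placeholder(path, name)
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.9 * matrix.shape[1], 1.0 + min(0.35 * matrix.shape[0], 12))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="Reds", vmin=0)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    if matrix.shape[0] <= 60:
        ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_title(label)
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def mutation_pies(classes: pd.DataFrame, outdir, fmt: str = "png") -> list[Path]:
    """One circle chart per (entity, gene): slice size is the share of a
    variant class among all mutations; labels add the per-sample percentage."""
    outdir = Path(outdir)
    paths = []
    for (entity, gene), sub in classes.groupby(["entity", "gene"], sort=True):
        path = outdir / f"mutation_{entity}_{gene}.{fmt}"
        sub = sub[sub["slice_proportion"] > 0]
        if sub.empty:
            paths.append(_placeholder(path, f"{entity} {gene}"))
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        labels = [
            f"{c} ({100 * sp:.1f}% of samples)"
            for c, sp in zip(sub["variant_class"], sub["sample_percentage"])
        ]
        ax.pie(sub["slice_proportion"], labels=labels, textprops={"fontsize": 7})
        ax.set_title(f"{entity} / {gene}")
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def methylation_region_grid(results: pd.DataFrame, outdir, fmt: str = "png") -> Path:
    """Gene x region grid of delta-beta for one entity, hatched where the
    BH-adjusted p clears no significance."""
    outdir = Path(outdir)
    entity = results["entity"].iloc[0] if len(results) else "none"
    path = outdir / f"methylation_{entity}_regions.{fmt}"
    if results.empty:
        return _placeholder(path, "methylation")
    pivot = results.pivot_table(
        index="gene", columns="region", values="delta_beta", aggfunc="first"
    )
    fig, ax = plt.subplots(figsize=(8, 1.0 + min(0.4 * len(pivot), 12)))
    im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="coolwarm", vmin=-1, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    if pivot.shape[0] <= 60:
        ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_title(f"{entity}: delta-beta by gene region")
    fig.colorbar(im, ax=ax, label="delta-beta")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def delta_histograms(hist_table: pd.DataFrame, outdir, fmt: str = "png") -> list[Path]:
    """Per-(gene, region) histogram of per-pair beta differences."""
    outdir = Path(outdir)
    paths = []
    for (entity, gene, region), sub in hist_table.groupby(
        ["entity", "gene", "region"], sort=True
    ):
        safe_region = region.replace("'", "")
        path = outdir / f"methylation_{entity}_{gene}_{safe_region}_hist.{fmt}"
        if sub["count"].sum() == 0:
            paths.append(_placeholder(path, f"{gene} {region}"))
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(sub["bin_left"], sub["count"], width=sub["bin_right"] - sub["bin_left"],
               align="edge", color="#4477aa")
        ax.set_xlabel("beta difference (tumor - normal)")
        ax.set_ylabel("samples")
        ax.set_title(f"{entity} / {gene} / {region}")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths


def waterfall_plots(calls: pd.DataFrame, outdir, axis: str, fmt: str = "png") -> list[Path]:
    """One waterfall panel per entity (or gene): non-neutral samples ordered
    by descending score."""
    outdir = Path(outdir)
    key = "entity" if axis == "entity_centric" else "gene"
    paths = []
    kept = calls[calls["call"] != "neutral"]
    for panel in sorted(calls[key].unique()):
        path = outdir / f"expression_waterfall_{panel}.{fmt}"
        sub = kept[kept[key] == panel].sort_values(
            ["score", "sample"], ascending=[False, True]
        )
        if sub.empty:
            paths.append(_placeholder(path, str(panel)))
            continue
        fig, ax = plt.subplots(figsize=(6, 3.2))
        colors = np.where(sub["call"] == "over", "#cc3311", "#0077bb")
        ax.bar(range(len(sub)), sub["score"], color=colors)
        ax.set_xlabel("samples exceeding threshold")
        ax.set_ylabel("score")
        ax.set_title(str(panel))
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths


def expression_boxplots(summary: pd.DataFrame, outdir, fmt: str = "png") -> list[Path]:
    """Per-entity box plots (one box per gene) from the five-number summary."""
    outdir = Path(outdir)
    paths = []
    for entity, sub in summary.groupby("entity", sort=True):
        path = outdir / f"expression_box_{entity}.{fmt}"
        if sub.empty:
            paths.append(_placeholder(path, entity))
            continue
        fig, ax = plt.subplots(figsize=(1.5 + 0.8 * len(sub), 3.5))
        stats = [
            {
                "med": r.median, "q1": r.q1, "q3": r.q3,
                "whislo": r.whisker_low, "whishi": r.whisker_high,
                "label": r.gene, "fliers": [],
            }
            for r in sub.itertuples()
        ]
        ax.bxp(stats, showfliers=False)
        ax.set_ylabel("RSEM normalized count")
        ax.set_title(entity)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths


def cnv_category_bars(categories: pd.DataFrame, outdir, fmt: str = "png") -> list[Path]:
    """Per-(entity, gene) bar plot of sample counts in each category -2..2."""
    outdir = Path(outdir)
    paths = []
    for (entity, gene), sub in categories.groupby(["entity", "gene"], sort=True):
        path = outdir / f"cnv_{entity}_{gene}.{fmt}"
        sub = sub.sort_values("category")
        if sub["count"].sum() == 0:
            paths.append(_placeholder(path, f"{entity} {gene}"))
            continue
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        colors = ["#2166ac", "#92c5de", "#cccccc", "#f4a582", "#b2182b"]
        ax.bar([str(c) for c in sub["category"]], sub["count"], color=colors)
        ax.set_xlabel("GISTIC category")
        ax.set_ylabel("samples")
        ax.set_title(f"{entity} / {gene}")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths
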