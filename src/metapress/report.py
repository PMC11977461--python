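"""Figure and summary-table rendering for a completed pipeline run.

Produces the standard panels of a staged perturbation study: stacked
species-abundance bars per stage, PCA scatters coloured by stage, a sorted
log2FC bar panel for screened pathways, metabolite boxplots with
compact-letter significance annotations, and the expected dye time course.
Missing bundle entries skip their section with a notice rather than fail.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .design import STAGES
from .stats import compact_letters

log = logging.getLogger("metapress")

STAGE_COLORS = {"stabilization": "#4c72b0", "exposure": "#dd8452", "recovery": "#55a868"}


def stage_mean_abundance(profile: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean relative abundance per stage (stages x features; rows sum to 1)."""
    stage_of = design.set_index("sample")["stage"]
    grouped = profile.groupby(stage_of.reindex(profile.index)).mean()
    return grouped.reindex([s for s in STAGES if s in grouped.index])


def plot_species_bars(profile: pd.DataFrame, design: pd.DataFrame, path: Path) -> None:
    means = stage_mean_abundance(profile, design)
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(means))
    for sp in means.columns:
        ax.bar(means.index, means[sp], bottom=bottom, label=sp)
        bottom += means[sp].to_numpy()
    ax.set_ylabel("mean relative abundance")
    ax.legend(fontsize=6, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_pca(scores: pd.DataFrame, variance_ratio, design: pd.DataFrame, path: Path) -> None:
    stage_of = design.set_index("sample")["stage"].reindex(scores.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    for stage in STAGES:
        sel = stage_of == stage
        if sel.any():
            ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                       label=stage, color=STAGE_COLORS[stage], s=20)
    ax.set_xlabel(f"PC1 ({variance_ratio[0]:.1%})")
    ax.set_ylabel(f"PC2 ({variance_ratio[1]:.1%})")
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_log2fc_panel(stats_table: pd.DataFrame, screened: list[str], path: Path) -> None:
    sub = stats_table.loc[screened].sort_values("log2fc")
    fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * len(sub))))
    colors = ["#c44e52" if v < 0 else "#55a868" for v in sub["log2fc"]]
    ax.barh(sub.index, sub["log2fc"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("log2 fold change (exposure vs stabilization)")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_metabolite_boxes(
    table: pd.DataFrame,
    stats_table: pd.DataFrame,
    design: pd.DataFrame,
    path: Path,
    features: list[str] | None = None,
    alpha: float = 0.05,
) -> None:
    """Per-stage boxplots with compact-letter annotations from Dunn's test."""
    features = features or list(table.columns[:8])
    stage_of = design.set_index("sample")["stage"].reindex(table.index)
    ncol = min(4, len(features))
    nrow = int(np.ceil(len(features) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, feat in zip(axes.flat, features):
        data = [table.loc[stage_of == st, feat].dropna() for st in STAGES]
        ax.boxplot(data, tick_labels=[s[:4] for s in STAGES])
        dunn_cols = [c for c in stats_table.columns if c.startswith("dunn_p_")]
        pairs = []
        for c in dunn_cols:
            a, b = c[len("dunn_p_"):].split("_vs_")
            pairs.append({"group_a": a, "group_b": b, "p": stats_table.at[feat, c]})
        if pairs:
            letters = compact_letters(pd.DataFrame(pairs), alpha=alpha)
            top = max((d.max() for d in data if len(d)), default=1.0)
            for i, st in enumerate(STAGES):
                ax.text(i + 1, top * 1.05, letters.get(st, ""), ha="center", fontsize=8)
        ax.set_title(feat, fontsize=8)
    for ax in axes.flat[len(features):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dye_timecourse(timecourse: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    for stage in STAGES:
        sub = timecourse[timecourse["stage"] == stage]
        ax.plot(sub["day"], sub["concentration"], "o-", color=STAGE_COLORS[stage],
                label=stage)
    ax.set_xlabel("day")
    ax.set_ylabel("concentration (mg/ml)")
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def render_report(bundle: dict, out_dir: str | Path, design: pd.DataFrame | None = None) -> list[Path]:
    """Render every figure the bundle supports; skip missing parts with a notice."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if design is None:
        meta_path = bundle.get("config", {}).get("metadata")
        if meta_path is None:
            raise ValueError("render_report needs a design table")
        design = pd.read_csv(meta_path, sep="\t", comment="#")
    written: list[Path] = []

    def _try(name: str, fn) -> None:
        try:
            p = out_dir / name
            fn(p)
            written.append(p)
        except KeyError as exc:
            log.info("report section %s skipped: missing %s", name, exc)

    _try("species_bars.png",
         lambda p: plot_species_bars(bundle["species_profile"], design, p))
    _try("species_pca.png",
         lambda p: plot_pca(bundle["species_pca"].scores,
                            bundle["species_pca"].explained_variance_ratio, design, p))
    _try("pathway_pca.png",
         lambda p: plot_pca(bundle["pathway_pca"].scores,
                            bundle["pathway_pca"].explained_variance_ratio, design, p))
    _try("pathway_log2fc.png",
         lambda p: plot_log2fc_panel(bundle["pathway_stats"],
                                     bundle["screened_pathways"], p))
    if "scfa_table" in bundle:
        _try("scfa_boxplots.png",
             lambda p: plot_metabolite_boxes(bundle["scfa_table"],
                                             bundle["scfa_stats"], design, p))
    if "dye_timecourse" in bundle:
        _try("dye_timecourse.png",
             lambda p: plot_dye_timecourse(bundle["dye_timecourse"], p))
    return written
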