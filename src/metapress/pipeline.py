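"""End-to-end orchestration of the staged perturbation analysis.

Given an intensity table, annotations, pathway definitions, sample metadata
and optional metabolite tables, the pipeline produces species / pathway /
metabolite profiles, stage-wise statistics with the significance screen,
PCA + PERMANOVA ordination results, the abundance-decoupled temporal
correlation table, and a machine-readable run manifest.  All randomness
flows from one root seed split deterministically per stage, so identical
config + seed gives identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import STAGES, check_design
from .io import (
    read_feature_table,
    read_intensities,
    read_metadata,
    write_profile,
    write_table,
)
from .multivariate import stagewise_permanova, pca
from .quantify import (
    AnnotationMap,
    PathwayDefinitions,
    pathway_filter,
    pathway_intensity,
    pathway_relative_abundance,
    species_relative_abundance,
)
from .stats import screen_features, stage_statistics
from .temporal import correlation_report, pathway_day_correlations, species_stability_check

log = logging.getLogger("metapress")


@dataclass
class RunConfig:
    """Paths, thresholds and the root seed for one pipeline run."""

    intensities: str
    annotations: str
    metadata: str
    pathway_defs: str
    out_dir: str
    scfa: str | None = None
    metabolites: str | None = None
    seed: int = 0
    p_cut: float = 0.05
    fc_cut: float = 0.175
    rho_cut: float = 0.55
    min_proteins: int = 5
    min_coverage: float = 0.15
    bh_threshold: int = 20
    permutations: int = 999
    metric: str = "euclidean"
    compare: tuple[str, str] = ("exposure", "stabilization")
    correlation_window: tuple[int, int] = (7, 13)

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if self.fc_cut < 0 or self.rho_cut < 0 or self.rho_cut > 1:
            raise ValueError("fc_cut must be >= 0 and rho_cut in [0, 1]")
        if self.min_proteins < 1 or not 0 <= self.min_coverage <= 1:
            raise ValueError("min_proteins >= 1 and min_coverage in [0, 1] required")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        self.compare = tuple(self.compare)  # type: ignore[assignment]
        self.correlation_window = tuple(self.correlation_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class Diagnostic:
    level: str  # "fatal" | "warning"
    message: str


def validate_inputs(
    intensities: str | Path,
    annotations: str | Path,
    metadata: str | Path,
    pathway_defs: str | Path,
) -> list[Diagnostic]:
    """Structural checks on the input tables; fatal diagnostics block a run."""
    diags: list[Diagnostic] = []

    def fatal(msg: str) -> None:
        diags.append(Diagnostic("fatal", msg))

    try:
        tbl = read_intensities(intensities)
    except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
        fatal(f"cannot read intensity table: {exc}")
        return diags
    if tbl.index.duplicated().any():
        fatal(f"duplicate sample ids: {tbl.index[tbl.index.duplicated()].tolist()}")
    if tbl.columns.duplicated().any():
        fatal("duplicate protein-group columns in the intensity table")
    values = tbl.to_numpy()
    if not np.isfinite(values).all():
        fatal("non-finite intensities present")
    elif (values < 0).any():
        fatal("negative intensities present")

    try:
        ann = AnnotationMap.from_tsv(annotations)
    except Exception as exc:  # noqa: BLE001
        fatal(f"cannot read annotation table: {exc}")
        return diags
    unannotated = tbl.columns.difference(ann.table["protein_group"])
    if len(unannotated):
        fatal(
            f"{len(unannotated)} protein group(s) lack a species annotation, "
            f"e.g. {list(unannotated[:5])}"
        )

    try:
        meta = read_metadata(metadata)
        check_design(meta)
    except Exception as exc:  # noqa: BLE001
        fatal(f"invalid metadata table: {exc}")
        return diags
    missing = tbl.index.difference(meta["sample"])
    if len(missing):
        fatal(f"samples absent from metadata: {list(missing[:10])}")
    absent_stages = set(STAGES) - set(meta["stage"])
    if absent_stages:
        diags.append(
            Diagnostic("warning", f"stages with no samples: {sorted(absent_stages)}")
        )

    try:
        defs = PathwayDefinitions.from_tsv(pathway_defs)
    except Exception as exc:  # noqa: BLE001
        fatal(f"cannot read pathway definitions: {exc}")
        return diags
    referenced = ann.all_pathways()
    undefined = sorted(referenced - set(defs))
    if undefined:
        fatal(f"pathways referenced in annotations but missing from definitions: {undefined}")
    return diags


def run_pipeline(cfg: RunConfig) -> dict:
    """Run quantification, statistics, ordination and temporal correlation.

    Returns the result bundle (profiles, stat tables, ordinations,
    correlations, manifest) and writes every table under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diags = validate_inputs(cfg.intensities, cfg.annotations, cfg.metadata, cfg.pathway_defs)
    fatal = [d for d in diags if d.level == "fatal"]
    if fatal:
        raise ValueError("input validation failed: " + "; ".join(d.message for d in fatal))

    tbl = read_intensities(cfg.intensities)
    ann = AnnotationMap.from_tsv(cfg.annotations)
    meta = read_metadata(cfg.metadata)
    defs = PathwayDefinitions.from_tsv(cfg.pathway_defs)
    meta = meta[meta["sample"].isin(tbl.index)].reset_index(drop=True)
    log.info("inputs: %d samples x %d protein groups", *tbl.shape)

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    seed_of = {name: int(s.generate_state(1)[0]) for name, s in
               zip(("species_permanova", "pathway_permanova", "metabolite_permanova"), seeds)}

    bundle: dict = {"config": asdict(cfg), "diagnostics": [asdict(d) for d in diags]}

    # --- quantification -------------------------------------------------
    species_prof = species_relative_abundance(tbl, ann)
    retained = pathway_filter(ann, defs, cfg.min_proteins, cfg.min_coverage)
    pw_int = pathway_intensity(tbl, ann)
    pw_prof = pathway_relative_abundance(pw_int, retained)
    bundle.update(
        species_profile=species_prof,
        retained_pathways=retained,
        pathway_intensity=pw_int[retained],
        pathway_profile=pw_prof,
    )
    log.info("quantified %d species, %d/%d pathways retained",
             species_prof.shape[1], len(retained), pw_int.shape[1])

    # --- stage statistics ------------------------------------------------
    species_stats = stage_statistics(
        species_prof, meta, cfg.compare, cfg.bh_threshold, cfg.p_cut, cfg.fc_cut
    )
    pathway_stats = stage_statistics(
        pw_prof, meta, cfg.compare, cfg.bh_threshold, cfg.p_cut, cfg.fc_cut
    )
    pathway_stats_int = stage_statistics(
        pw_int[retained], meta, cfg.compare, cfg.bh_threshold, cfg.p_cut, cfg.fc_cut
    )
    bundle.update(
        species_stats=species_stats,
        pathway_stats=pathway_stats,
        pathway_stats_intensity=pathway_stats_int,
        screened_pathways=screen_features(pathway_stats, cfg.p_cut, cfg.fc_cut),
    )
    log.info("screen kept %d pathways", len(bundle["screened_pathways"]))

    # --- multivariate ----------------------------------------------------
    bundle["species_pca"] = pca(species_prof)
    bundle["pathway_pca"] = pca(pw_prof)
    bundle["species_permanova"] = stagewise_permanova(
        species_prof, meta, cfg.metric, cfg.permutations, seed_of["species_permanova"]
    )
    bundle["pathway_permanova"] = stagewise_permanova(
        pw_prof, meta, cfg.metric, cfg.permutations, seed_of["pathway_permanova"]
    )

    # --- metabolites (optional) -----------------------------------------
    for name, path in (("scfa", cfg.scfa), ("metabolites", cfg.metabolites)):
        if path is None:
            continue
        feats = read_feature_table(path)
        bundle[f"{name}_table"] = feats
        bundle[f"{name}_stats"] = stage_statistics(
            feats, meta, cfg.compare, cfg.bh_threshold, cfg.p_cut, cfg.fc_cut
        )
        if name == "metabolites":
            bundle["metabolite_pca"] = pca(feats)
            bundle["metabolite_permanova"] = stagewise_permanova(
                feats, meta, cfg.metric, cfg.permutations,
                seed_of["metabolite_permanova"],
            )

    # --- temporal correlation -------------------------------------------
    affected = species_stats.index[species_stats["p"] < cfg.p_cut].tolist()
    candidates = bundle["screened_pathways"]
    if affected and candidates:
        corr = pathway_day_correlations(
            tbl, ann, meta, affected, candidates,
            window=cfg.correlation_window, rho_cut=cfg.rho_cut,
            alpha=cfg.p_cut, bh_threshold=cfg.bh_threshold,
        )
        stability = species_stability_check(species_prof, meta, cfg.correlation_window)
        bundle["correlations"] = correlation_report(corr, stability)
    else:
        bundle["correlations"] = pd.DataFrame(
            columns=["species", "pathway", "rho", "p", "n", "contributing",
                     "p_adj", "adjusted", "passes"]
        )
    log.info("temporal correlations: %d records, %d passing",
             len(bundle["correlations"]),
             int(bundle["correlations"]["passes"].sum())
             if len(bundle["correlations"]) else 0)

    # --- outputs ---------------------------------------------------------
    write_profile(species_prof, out_dir / "species_profile.tsv")
    write_profile(pw_prof, out_dir / "pathway_profile.tsv")
    write_table(species_stats, out_dir / "species_stats.tsv", index=True)
    write_table(pathway_stats, out_dir / "pathway_stats.tsv", index=True)
    write_table(pathway_stats_int, out_dir / "pathway_stats_intensity.tsv", index=True)
    write_table(bundle["species_permanova"], out_dir / "species_permanova.tsv")
    write_table(bundle["pathway_permanova"], out_dir / "pathway_permanova.tsv")
    write_table(bundle["species_pca"].scores, out_dir / "species_pca_scores.tsv", index=True)
    write_table(bundle["correlations"], out_dir / "correlations.tsv")
    for name in ("scfa", "metabolites"):
        if f"{name}_stats" in bundle:
            write_table(bundle[f"{name}_stats"], out_dir / f"{name}_stats.tsv", index=True)
    if "metabolite_permanova" in bundle:
        write_table(bundle["metabolite_permanova"], out_dir / "metabolite_permanova.tsv")

    manifest = {
        "tool": "metapress",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_samples": int(tbl.shape[0]),
        "n_protein_groups": int(tbl.shape[1]),
        "retained_pathways": retained,
        "screened_pathways": bundle["screened_pathways"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
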