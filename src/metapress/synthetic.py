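"""Synthetic metaproteomic / metabolomic dataset generator.

Emulates the data structure of a three-stage press-perturbation experiment
on a defined eight-species gut community (SIHUMIx): protein-group intensity
tables from label-free DIA quantification, KEGG-ortholog / pathway
annotations, a targeted short-chain fatty acid (SCFA) panel and an
untargeted metabolite feature table, sampled daily from parallel
bioreactors across stabilization, exposure and recovery windows.

The intensity model is log-normal per protein group: each protein carries a
fixed base level (species base levels sum to the community's baseline
proportions), multiplied by any planted stage-specific species fold and
pathway fold, times mean-corrected log-normal noise
``exp(sigma * z - sigma**2 / 2)``.  The mean correction makes the expected
intensity equal the deterministic part, so planted effects translate
exactly into expected stage-mean fold changes.  Every planted effect, and
its exact implied expectation on the relative-abundance scale, is recorded
in the ground-truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import STAGES, StageWindows, make_design

SIHUMIX_SPECIES: tuple[str, ...] = (
    "Anaerostipes caccae",
    "Bacteroides thetaiotaomicron",
    "Bifidobacterium longum",
    "Blautia producta",
    "Clostridium butyricum",
    "Thomasclavelia ramosa",
    "Escherichia coli",
    "Lactiplantibacillus plantarum",
)

# Baseline proteomic-biomass proportions: a Bacteroides / E. coli dominated
# community, fixed once as the generator's default steady state.
DEFAULT_PROPORTIONS: tuple[float, ...] = (0.05, 0.30, 0.10, 0.15, 0.10, 0.05, 0.20, 0.05)

SCFA_BASELINES: dict[str, float] = {
    # mmol/l, plausible steady-state fermentation end-product levels
    "acetate": 60.0,
    "propionate": 20.0,
    "butyrate": 15.0,
    "lactate": 5.0,
    "formate": 3.0,
    "succinate": 2.0,
    "valerate": 1.5,
    "isovalerate": 1.0,
    "isobutyrate": 1.0,
    "caproate": 0.5,
}

_TOTAL_INTENSITY = 1e6  # arbitrary intensity units per sample (expected)


@dataclass(frozen=True)
class CommunitySpec:
    """Static structure of the synthetic community and its annotation space."""

    species: tuple[str, ...] = SIHUMIX_SPECIES
    proteins_per_species: int = 400
    baseline_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    pathway_count: int = 40
    kos_per_pathway: int = 20  # reference KO set size per pathway
    annotated_fraction: float = 0.70  # share of proteins carrying a KO
    untargeted_features: int = 556

    def __post_init__(self) -> None:
        if len(self.species) != len(set(self.species)):
            raise ValueError("species names must be unique")
        if len(self.baseline_proportions) != len(self.species):
            raise ValueError("baseline_proportions must match species count")
        props = np.asarray(self.baseline_proportions, dtype=float)
        if (props <= 0).any():
            raise ValueError("baseline proportions must be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"baseline proportions must sum to 1, got {props.sum()!r}")
        if self.proteins_per_species < 1 or self.pathway_count < 1 or self.kos_per_pathway < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.annotated_fraction <= 1:
            raise ValueError("annotated_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PerturbationSpec:
    """Planted effects and noise for one simulated run.

    species_effects maps species -> stage -> multiplicative fold on all of
    that species' protein intensities; pathway_effects maps
    (pathway, stage) -> planted log2 fold change applied multiplicatively to
    every protein annotated to that pathway; pathway_trends maps
    (pathway, stage) -> per-day log2 slope, applied as
    ``2 ** (slope * (day - stage_start))`` on top of any stage effect (a
    within-stage temporal drift); scfa/metabolite effects map
    (name, stage) -> multiplicative fold on the measured level.
    """

    windows: StageWindows = StageWindows()
    species_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    pathway_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    pathway_trends: Mapping[tuple[str, str], float] = field(default_factory=dict)
    scfa_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    metabolite_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma: float = 0.1  # log-normal sigma for protein / metabolite intensities
    scfa_sigma: float = 0.05  # Gaussian sd as a fraction of the SCFA baseline
    n_bioreactors: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.scfa_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_bioreactors < 1:
            raise ValueError("n_bioreactors must be >= 1")
        for sp, stage_folds in self.species_effects.items():
            for stage, fold in stage_folds.items():
                if stage not in STAGES:
                    raise ValueError(f"unknown stage {stage!r} in species_effects[{sp!r}]")
                if not fold > 0:
                    raise ValueError(f"fold for {sp!r}/{stage!r} must be > 0")
        for name, effects in (("pathway_effects", self.pathway_effects),
                              ("pathway_trends", self.pathway_trends)):
            for (pw, stage), _ in effects.items():
                if stage not in STAGES:
                    raise ValueError(f"unknown stage {stage!r} in {name}[{pw!r}]")
        for name, effects in (("scfa_effects", self.scfa_effects),
                              ("metabolite_effects", self.metabolite_effects)):
            for (feat, stage), fold in effects.items():
                if stage not in STAGES:
                    raise ValueError(f"unknown stage {stage!r} in {name}[{feat!r}]")
                if not fold > 0:
                    raise ValueError(f"fold for {feat!r}/{stage!r} must be > 0")


@dataclass
class SyntheticDataset:
    """One generated run: tables in the pipeline's on-disk column contracts."""

    intensities: pd.DataFrame  # samples x protein groups
    annotations: pd.DataFrame  # protein_group, species, ko, pathways
    metadata: pd.DataFrame  # sample, bioreactor, day, stage
    pathway_defs: pd.DataFrame  # pathway, ko (long)
    scfa: pd.DataFrame  # samples x SCFA panel (mmol/l)
    metabolites: pd.DataFrame  # samples x untargeted features
    truth: dict  # planted effects + exact implied expectations


def _build_structure(spec: CommunitySpec, rng: np.random.Generator):
    """Protein ids, base intensities, KO assignment and pathway definitions."""
    species_short = ["".join(w[0] for w in sp.split()).upper() + f"{i}" for i, sp in enumerate(spec.species)]
    proteins, base, species_of = [], [], []
    props = np.asarray(spec.baseline_proportions, dtype=float)
    for i, sp in enumerate(spec.species):
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=spec.proteins_per_species)
        scaled = raw / raw.sum() * props[i] * _TOTAL_INTENSITY
        for j in range(spec.proteins_per_species):
            proteins.append(f"{species_short[i]}_P{j:04d}")
            species_of.append(sp)
        base.append(scaled)
    base = np.concatenate(base)

    # Reference pathway definitions: mostly disjoint KO blocks, with the last
    # KO of each pathway shared with the next (multi-pathway KOs exist).
    pathways = [f"PW{k:03d}" for k in range(spec.pathway_count)]
    ko_universe = [f"K{k:05d}" for k in range(spec.pathway_count * spec.kos_per_pathway)]
    defs_rows = []
    for k, pw in enumerate(pathways):
        block = ko_universe[k * spec.kos_per_pathway:(k + 1) * spec.kos_per_pathway]
        defs_rows.extend({"pathway": pw, "ko": ko} for ko in block)
        if k + 1 < len(pathways):
            defs_rows.append({"pathway": pathways[k + 1], "ko": block[-1]})
    pathway_defs = pd.DataFrame(defs_rows).drop_duplicates(ignore_index=True)
    ko_to_pathways: dict[str, list[str]] = {}
    for row in pathway_defs.itertuples(index=False):
        ko_to_pathways.setdefault(row.ko, []).append(row.pathway)

    # KO annotation: per species, a random subset of proteins gets KOs drawn
    # round-robin from a shuffled universe, so coverage is spread evenly.
    n_annot = int(round(spec.annotated_fraction * spec.proteins_per_species))
    kos = np.full(len(proteins), "", dtype=object)
    for i in range(len(spec.species)):
        lo = i * spec.proteins_per_species
        chosen = rng.choice(spec.proteins_per_species, size=n_annot, replace=False)
        shuffled = rng.permutation(ko_universe)
        for j, prot_idx in enumerate(np.sort(chosen)):
            kos[lo + prot_idx] = shuffled[j % len(shuffled)]

    annotations = pd.DataFrame(
        {
            "protein_group": proteins,
            "species": species_of,
            "ko": kos,
            "pathways": [
                ";".join(ko_to_pathways.get(k, [])) if k else "" for k in kos
            ],
        }
    )
    return proteins, base, annotations, pathway_defs, ko_to_pathways


def _day_multipliers(
    spec: CommunitySpec,
    perturb: PerturbationSpec,
    annotations: pd.DataFrame,
) -> dict[int, np.ndarray]:
    """Deterministic per-protein multiplier for each sampled day."""
    species_idx = annotations["species"].to_numpy()
    pathway_sets = [set(p.split(";")) if p else set() for p in annotations["pathways"]]
    planted_pathways = {pw for pw, _ in perturb.pathway_effects} | {
        pw for pw, _ in perturb.pathway_trends
    }
    for pw in planted_pathways:
        if not any(pw in ps for ps in pathway_sets):
            raise ValueError(
                f"effect planted on pathway {pw!r}, but no annotated protein "
                f"belongs to it"
            )
    for sp in perturb.species_effects:
        if sp not in spec.species:
            raise ValueError(f"species effect planted on unknown species {sp!r}")
    n = len(annotations)
    member = {
        pw: np.fromiter((pw in ps for ps in pathway_sets), bool, n)
        for pw in planted_pathways
    }
    windows = perturb.windows
    mult: dict[int, np.ndarray] = {}
    for day in windows.all_days:
        stage = windows.stage_of(day)
        m = np.ones(n)
        for sp, stage_folds in perturb.species_effects.items():
            if stage in stage_folds:
                m[species_idx == sp] *= stage_folds[stage]
        for (pw, st), log2fc in perturb.pathway_effects.items():
            if st == stage:
                m[member[pw]] *= 2.0 ** log2fc
        for (pw, st), slope in perturb.pathway_trends.items():
            if st == stage:
                start = windows.days(stage).start
                m[member[pw]] *= 2.0 ** (slope * (day - start))
        mult[day] = m
    return mult


def _exact_truth(
    spec: CommunitySpec,
    perturb: PerturbationSpec,
    base: np.ndarray,
    annotations: pd.DataFrame,
    mult: dict[int, np.ndarray],
    ko_to_pathways: dict[str, list[str]],
) -> dict:
    """Exact expected stage-wise profiles implied by the planted effects.

    Expectations are taken over the noise (the log-normal factor has mean 1)
    and averaged over the stage's sampled days, matching the stage means the
    statistics module compares.
    """
    species = list(spec.species)
    species_arr = annotations["species"].to_numpy()
    windows = perturb.windows
    pairs = [
        ("exposure", "stabilization"),
        ("recovery", "exposure"),
        ("recovery", "stabilization"),
    ]
    exp_int = {
        stage: base * np.mean([mult[d] for d in windows.days(stage)], axis=0)
        for stage in STAGES
    }
    species_abund = {}
    for stage in STAGES:
        # expected relative abundance approximated at the expected intensities;
        # exact at sigma=0 and for stage-constant effects
        per_day = []
        for d in windows.days(stage):
            det = base * mult[d]
            tot = det.sum()
            per_day.append({sp: det[species_arr == sp].sum() / tot for sp in species})
        species_abund[stage] = {
            sp: float(np.mean([p[sp] for p in per_day])) for sp in species
        }
    pw_members: dict[str, list[int]] = {}
    for idx, ko in enumerate(annotations["ko"]):
        for pw in ko_to_pathways.get(ko, []) if ko else []:
            pw_members.setdefault(pw, []).append(idx)
    pw_int = {}
    for stage in STAGES:
        pw_int[stage] = {
            pw: float(exp_int[stage][idx].sum()) for pw, idx in pw_members.items()
        }
    truth: dict = {
        "seed": perturb.seed,
        "sigma": perturb.sigma,
        "baseline_proportions": dict(zip(species, spec.baseline_proportions)),
        "species_effects": {
            sp: dict(folds) for sp, folds in perturb.species_effects.items()
        },
        "pathway_effects": {
            f"{pw}|{stage}": fc for (pw, stage), fc in perturb.pathway_effects.items()
        },
        "pathway_trends": {
            f"{pw}|{stage}": s for (pw, stage), s in perturb.pathway_trends.items()
        },
        "scfa_effects": {
            f"{m}|{stage}": f for (m, stage), f in perturb.scfa_effects.items()
        },
        "metabolite_effects": {
            f"{m}|{stage}": f for (m, stage), f in perturb.metabolite_effects.items()
        },
        "expected_species_abundance": species_abund,
        "expected_species_log2fc": {},
        "expected_pathway_log2fc_intensity": {},
        "expected_pathway_log2fc_relabund": {},
    }
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        truth["expected_species_log2fc"][key] = {
            sp: float(np.log2(species_abund[a][sp] / species_abund[b][sp]))
            for sp in species
        }
        tot_a = sum(pw_int[a].values())
        tot_b = sum(pw_int[b].values())
        truth["expected_pathway_log2fc_intensity"][key] = {
            pw: float(np.log2(pw_int[a][pw] / pw_int[b][pw]))
            for pw in pw_members
            if pw_int[a][pw] > 0 and pw_int[b][pw] > 0
        }
        truth["expected_pathway_log2fc_relabund"][key] = {
            pw: float(np.log2((pw_int[a][pw] / tot_a) / (pw_int[b][pw] / tot_b)))
            for pw in pw_members
            if pw_int[a][pw] > 0 and pw_int[b][pw] > 0
        }
    return truth


def generate_dataset(
    spec: CommunitySpec | None = None,
    perturb: PerturbationSpec | None = None,
) -> SyntheticDataset:
    """Generate one synthetic run; identical specs + seed give identical data."""
    spec = spec or CommunitySpec()
    perturb = perturb or PerturbationSpec()
    ss = np.random.SeedSequence(perturb.seed)
    rng_struct, rng_noise, rng_scfa, rng_metab = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    proteins, base, annotations, pathway_defs, ko_to_pathways = _build_structure(
        spec, rng_struct
    )
    mult = _day_multipliers(spec, perturb, annotations)
    metadata = make_design(perturb.windows, perturb.n_bioreactors)
    samples = metadata["sample"].tolist()
    stages = metadata["stage"].tolist()
    days = metadata["day"].tolist()

    sigma = perturb.sigma
    det = np.vstack([base * mult[day] for day in days])
    if sigma > 0:
        z = rng_noise.standard_normal(det.shape)
        intensities = det * np.exp(sigma * z - sigma**2 / 2.0)
    else:
        intensities = det.copy()
    intensity_df = pd.DataFrame(intensities, index=pd.Index(samples, name="sample"),
                                columns=proteins)

    scfa_names = list(SCFA_BASELINES)
    scfa_det = np.empty((len(samples), len(scfa_names)))
    for j, name in enumerate(scfa_names):
        baseline = SCFA_BASELINES[name]
        for i, stage in enumerate(stages):
            fold = perturb.scfa_effects.get((name, stage), 1.0)
            scfa_det[i, j] = baseline * fold
    scfa_vals = scfa_det + rng_scfa.standard_normal(scfa_det.shape) * (
        perturb.scfa_sigma * np.array([SCFA_BASELINES[n] for n in scfa_names])
    )
    np.clip(scfa_vals, 0.0, None, out=scfa_vals)
    scfa_df = pd.DataFrame(scfa_vals, index=pd.Index(samples, name="sample"),
                           columns=scfa_names)

    feat_names = [f"M{i:04d}" for i in range(spec.untargeted_features)]
    feat_base = rng_metab.lognormal(mean=10.0, sigma=1.0, size=spec.untargeted_features)
    metab_det = np.tile(feat_base, (len(samples), 1))
    for (name, stage), fold in perturb.metabolite_effects.items():
        if name not in feat_names:
            raise ValueError(f"metabolite effect planted on unknown feature {name!r}")
        col = feat_names.index(name)
        rows = [i for i, st in enumerate(stages) if st == stage]
        metab_det[rows, col] *= fold
    if sigma > 0:
        zm = rng_metab.standard_normal(metab_det.shape)
        metab_vals = metab_det * np.exp(sigma * zm - sigma**2 / 2.0)
    else:
        metab_vals = metab_det
    metab_df = pd.DataFrame(metab_vals, index=pd.Index(samples, name="sample"),
                            columns=feat_names)

    truth = _exact_truth(spec, perturb, base, annotations, mult, ko_to_pathways)
    return SyntheticDataset(
        intensities=intensity_df,
        annotations=annotations,
        metadata=metadata,
        pathway_defs=pathway_defs,
        scfa=scfa_df,
        metabolites=metab_df,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write all tables as TSV plus the ground truth as JSON.

    Emits intensities.tsv, annotations.tsv, metadata.tsv, pathway_defs.tsv,
    scfa.tsv, metabolites.tsv and truth.json; returns the path map.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame, with_index in (
            ("intensities", ds.intensities, True),
            ("annotations", ds.annotations, False),
            ("metadata", ds.metadata, False),
            ("pathway_defs", ds.pathway_defs, False),
            ("scfa", ds.scfa, True),
            ("metabolites", ds.metabolites, True),
        ):
            p = directory / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=with_index)
            paths[name] = p
        truth_path = directory / "truth.json"
        truth_path.write_text(json.dumps(ds.truth, indent=1, sort_keys=True))
        paths["truth"] = truth_path
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset` (exact round trip)."""
    directory = Path(directory)

    def _read(name: str, index: bool) -> pd.DataFrame:
        p = directory / f"{name}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing table {p}")
        frame = pd.read_csv(p, sep="\t", index_col=0 if index else None)
        return frame

    annotations = pd.read_csv(
        directory / "annotations.tsv", sep="\t", keep_default_na=False, dtype=str
    )
    return SyntheticDataset(
        intensities=_read("intensities", True),
        annotations=annotations,
        metadata=_read("metadata", False),
        pathway_defs=_read("pathway_defs", False),
        scfa=_read("scfa", True),
        metabolites=_read("metabolites", True),
        truth=json.loads((directory / "truth.json").read_text()),
    )
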