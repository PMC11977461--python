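"""Species-, pathway- and within-species profiles from protein intensities.

Proteomic biomass: a species' relative abundance in a sample is the summed
intensity of all its protein groups divided by the total intensity of all
protein groups in that sample (rows live on the simplex).  Pathway signal
is the summed intensity of protein groups whose KEGG ortholog (KO) maps to
the pathway; pathways enter the analysis only if enough of them was seen
(protein count and KO coverage filters).  Within-species pathway abundance
normalizes a pathway's intensity by the species' own total, decoupling the
pathway signal from the species' overall abundance.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class AnnotationMap:
    """Protein group -> species (exactly one), KO (zero/one), pathways (any).

    Built from a table with columns protein_group, species, ko, pathways
    (semicolon-separated pathway ids; empty string = unannotated).  A protein
    group listed under more than one species is an error by default; with
    ``on_shared="split"`` its intensity is split equally between species.
    """

    def __init__(self, frame: pd.DataFrame, on_shared: str = "error") -> None:
        required = {"protein_group", "species"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        frame = frame.copy()
        for col in ("ko", "pathways"):
            if col not in frame.columns:
                frame[col] = ""
            frame[col] = frame[col].fillna("").astype(str)
        frame["weight"] = 1.0

        dup = frame["protein_group"].duplicated(keep=False)
        if dup.any():
            shared = frame.loc[dup]
            if on_shared == "error":
                offenders = sorted(shared["protein_group"].unique())
                raise ValueError(
                    f"protein groups annotated to multiple species: {offenders[:10]}"
                    + ("..." if len(offenders) > 10 else "")
                )
            if on_shared != "split":
                raise ValueError("on_shared must be 'error' or 'split'")
            counts = frame.groupby("protein_group")["species"].transform("size")
            frame["weight"] = 1.0 / counts
        self.table = frame.reset_index(drop=True)

    @property
    def protein_groups(self) -> pd.Index:
        return pd.Index(self.table["protein_group"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def ko_of(self) -> pd.Series:
        return self.table.set_index("protein_group")["ko"]

    def pathway_sets(self) -> pd.Series:
        """Per annotation row, the set of pathway ids (may be empty)."""
        return self.table["pathways"].map(
            lambda p: frozenset(p.split(";")) if p else frozenset()
        )

    def all_pathways(self) -> set[str]:
        out: set[str] = set()
        for s in self.pathway_sets():
            out |= s
        return out

    def pathway_members(self) -> dict[str, list[int]]:
        """Pathway id -> row indices of member annotations."""
        members: dict[str, list[int]] = {}
        for idx, s in enumerate(self.pathway_sets()):
            for pw in s:
                members.setdefault(pw, []).append(idx)
        return members

    @classmethod
    def from_tsv(cls, path: str | Path, on_shared: str = "error") -> "AnnotationMap":
        frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
        return cls(frame, on_shared=on_shared)


class PathwayDefinitions(Mapping):
    """Reference pathway -> KO set, the coverage denominator."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]) -> None:
        self._map = {pw: frozenset(kos) for pw, kos in mapping.items()}
        empty = [pw for pw, kos in self._map.items() if not kos]
        if empty:
            raise ValueError(f"pathway definitions with empty KO sets: {empty}")

    def __getitem__(self, pw: str) -> frozenset:
        return self._map[pw]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayDefinitions":
        if not {"pathway", "ko"} <= set(frame.columns):
            raise ValueError("pathway definition table needs columns pathway, ko")
        grouped = frame.groupby("pathway")["ko"].agg(set)
        return cls(grouped.to_dict())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayDefinitions":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#", dtype=str))


def _check_table(tbl: pd.DataFrame) -> None:
    if tbl.index.duplicated().any() or tbl.columns.duplicated().any():
        raise ValueError("intensity table has duplicate sample or protein ids")
    values = tbl.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("intensity table contains non-finite values")
    if (values < 0).any():
        raise ValueError("intensity table contains negative values")


def _drop_zero_rows(profile: pd.DataFrame, totals: pd.Series, what: str) -> pd.DataFrame:
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} sample(s) with zero total {what}: "
            f"{list(totals.index[zero])}",
            stacklevel=3,
        )
        profile = profile.loc[~zero]
    return profile


def species_relative_abundance(tbl: pd.DataFrame, ann: AnnotationMap) -> pd.DataFrame:
    """Samples x species profile of proteomic biomass; rows sum to 1.

    Each entry is the species' summed protein-group intensity divided by the
    total intensity of all protein groups in the sample.  Samples with zero
    total intensity are excluded with a warning.
    """
    _check_table(tbl)
    unknown = tbl.columns.difference(ann.table["protein_group"])
    if len(unknown):
        raise ValueError(
            f"protein groups without species annotation: {list(unknown[:10])}"
        )
    sums = {}
    for sp, rows in ann.table.groupby("species"):
        present = rows[rows["protein_group"].isin(tbl.columns)]
        if present.empty:
            sums[sp] = pd.Series(0.0, index=tbl.index)
        else:
            w = present["weight"].to_numpy()
            vals = tbl[present["protein_group"]].to_numpy() * w
            sums[sp] = pd.Series(vals.sum(axis=1), index=tbl.index)
    profile = pd.DataFrame(sums)
    totals = profile.sum(axis=1)
    profile = _drop_zero_rows(profile, totals, "intensity")
    profile = profile.div(profile.sum(axis=1), axis=0)
    profile.attrs["kind"] = "species"
    return profile


def pathway_intensity(
    tbl: pd.DataFrame,
    ann: AnnotationMap,
    split: bool = False,
    species: str | None = None,
) -> pd.DataFrame:
    """Samples x pathways summed-intensity matrix.

    A protein group annotated to k pathways contributes its full intensity
    to each of them (set ``split=True`` to divide by k instead).  With
    ``species`` given, only that species' protein groups are summed.
    """
    _check_table(tbl)
    table = ann.table
    psets = ann.pathway_sets()
    n_pw = psets.map(len).to_numpy()
    members = ann.pathway_members()
    keep = table["protein_group"].isin(tbl.columns).to_numpy()
    if species is not None:
        sp_mask = (table["species"] == species).to_numpy()
        if not sp_mask.any():
            raise ValueError(f"species {species!r} not present in annotations")
        keep = keep & sp_mask
    values = tbl.to_numpy()
    col_pos = {pg: j for j, pg in enumerate(tbl.columns)}
    prot = table["protein_group"].to_numpy()
    base_w = table["weight"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for pw in sorted(members):
        rows = [i for i in members[pw] if keep[i]]
        if not rows:
            out[pw] = np.zeros(len(tbl))
            continue
        cols = [col_pos[prot[i]] for i in rows]
        w = base_w[rows]
        if split:
            w = w / n_pw[rows]
        out[pw] = values[:, cols] @ w
    result = pd.DataFrame(out, index=tbl.index)
    result = result[sorted(result.columns)]
    result.attrs["kind"] = "pathway_intensity"
    return result


def pathway_filter(
    ann: AnnotationMap,
    defs: PathwayDefinitions,
    min_proteins: int = 5,
    min_coverage: float = 0.15,
    coverage_basis: str = "ko",
) -> list[str]:
    """Pathways passing the inclusion filter, sorted.

    A pathway is retained iff it has at least ``min_proteins`` distinct
    detected protein groups AND its coverage is at least ``min_coverage``
    (both thresholds inclusive).  Coverage is distinct detected KOs divided
    by the pathway's reference KO count (``coverage_basis="ko"``, default),
    or distinct detected protein groups over the same denominator
    (``coverage_basis="protein"``).
    """
    if coverage_basis not in ("ko", "protein"):
        raise ValueError("coverage_basis must be 'ko' or 'protein'")
    table = ann.table
    members = ann.pathway_members()
    missing = sorted(set(members) - set(defs))
    if missing:
        raise KeyError(
            f"pathways present in annotations but absent from definitions: {missing}"
        )
    retained = []
    for pw, rows in members.items():
        prots = set(table.loc[rows, "protein_group"])
        kos = set(table.loc[rows, "ko"]) - {""}
        n_ref = len(defs[pw])
        numerator = len(kos) if coverage_basis == "ko" else len(prots)
        coverage = numerator / n_ref
        if len(prots) >= min_proteins and coverage >= min_coverage:
            retained.append(pw)
    return sorted(retained)


def pathway_relative_abundance(
    pathway_int: pd.DataFrame, retained: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per sample, each retained pathway's share of the retained total."""
    if retained is not None:
        retained = list(retained)
        if not retained:
            raise ValueError("retained pathway set is empty")
        pathway_int = pathway_int[retained]
    totals = pathway_int.sum(axis=1)
    profile = _drop_zero_rows(pathway_int, totals, "pathway intensity")
    profile = profile.div(profile.sum(axis=1), axis=0)
    profile.attrs["kind"] = "pathway"
    return profile


def within_species_pathway_abundance(
    tbl: pd.DataFrame,
    ann: AnnotationMap,
    species: str,
    pathways: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pathway share of one species' own total intensity, per sample.

    Entry (sample, pathway) = summed intensity of the species' protein
    groups in the pathway / summed intensity of ALL the species' protein
    groups in that sample.  Dividing by the species' own total makes the
    profile invariant to the species' overall abundance — the property that
    lets pathway trends be read independently of biomass shifts.  Samples
    where the species total is zero become NaN rows (dropped pairwise
    downstream).
    """
    _check_table(tbl)
    mask = ann.table["species"] == species
    if not mask.any():
        raise ValueError(f"species {species!r} not present in annotations")
    sp_cols = ann.table.loc[mask, "protein_group"]
    sp_cols = sp_cols[sp_cols.isin(tbl.columns)]
    species_total = tbl[sp_cols].sum(axis=1)
    num = pathway_intensity(tbl, ann, species=species)
    if pathways is not None:
        pathways = list(pathways)
        num = num.reindex(columns=pathways, fill_value=0.0)
    profile = num.div(species_total.replace(0.0, np.nan), axis=0)
    profile.attrs["kind"] = "within_species_pathway"
    profile.attrs["species"] = species
    return profile
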