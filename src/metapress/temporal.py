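"""Abundance-decoupled temporal adaptation analysis.

For species whose biomass shifted under the press perturbation, each
candidate pathway's share of the species' own proteome (within-species
pathway abundance) is correlated against the day of the exposure window
with Spearman's rank coefficient.  Because the within-species share is
invariant to the species' overall abundance, a significant day trend
reflects functional adaptation rather than a biomass shift; a
Kruskal-Wallis stability check of the species' relative abundance across
the same days supports that reading.  The correlation family is
Benjamini-Hochberg adjusted and screened at |rho| >= 0.55, adjusted
p < 0.05.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import AnnotationMap, within_species_pathway_abundance
from .stats import bh_adjust, kruskal_wallis


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) and its t-approximation p.

    Pairs with a missing value are dropped; needs >= 3 complete pairs.
    Zero rank variance in either vector yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in ranks; Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pathway_day_correlations(
    tbl: pd.DataFrame,
    ann: AnnotationMap,
    design: pd.DataFrame,
    species: Iterable[str],
    pathways: Iterable[str],
    window: tuple[int, int] = (7, 13),
    rho_cut: float = 0.55,
    alpha: float = 0.05,
    bh_threshold: int = 20,
) -> pd.DataFrame:
    """Spearman correlation of within-species pathway share against day.

    For every (species, pathway) combination where the species contributes
    protein groups to the pathway, correlates the within-species pathway
    abundance with the sampling day over all bioreactor-day samples whose
    day falls in ``window`` (same-day samples from different bioreactors are
    genuine ties, handled by mid-ranks).  The whole tested family is BH
    adjusted in one pass; a record passes iff p_adj < ``alpha`` and
    |rho| >= ``rho_cut``.  Species contributing to none of the candidate
    pathways are recorded with contributing=False.
    """
    species = list(species)
    pathways = list(pathways)
    lo, hi = window
    if lo > hi:
        raise ValueError(f"day window {window} has start after end")
    in_window = design[(design["day"] >= lo) & (design["day"] <= hi)]
    if in_window.empty:
        raise ValueError(f"no samples in day window {window}")
    day_of = in_window.set_index("sample")["day"]
    rows = []
    for sp in species:
        shares = within_species_pathway_abundance(tbl, ann, sp, pathways=pathways)
        shares = shares.loc[shares.index.intersection(day_of.index)]
        days = day_of.reindex(shares.index).to_numpy(dtype=float)
        contributed = False
        for pw in pathways:
            y = shares[pw].to_numpy(dtype=float)
            if np.nansum(y) == 0:
                continue  # species does not contribute to this pathway
            contributed = True
            keep = ~np.isnan(y)
            n = int(keep.sum())
            if n < 3:
                rho, p = float("nan"), float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = spearman(days[keep], y[keep])
            rows.append(
                {"species": sp, "pathway": pw, "rho": rho, "p": p, "n": n,
                 "contributing": True}
            )
        if not contributed:
            rows.append(
                {"species": sp, "pathway": "", "rho": float("nan"),
                 "p": float("nan"), "n": 0, "contributing": False}
            )
    records = pd.DataFrame(rows)
    tested = records["contributing"] & records["p"].notna()
    p_adj = np.full(len(records), np.nan)
    if tested.any():
        adj, adjusted = bh_adjust(records.loc[tested, "p"].to_numpy(), bh_threshold)
        p_adj[tested.to_numpy()] = adj
    else:
        adjusted = False
    records["p_adj"] = p_adj
    records["adjusted"] = adjusted
    records["passes"] = (
        (records["p_adj"] < alpha) & (records["rho"].abs() >= rho_cut)
    ).fillna(False)
    records.attrs["window"] = window
    return records


def species_stability_check(
    species_profiles: pd.DataFrame,
    design: pd.DataFrame,
    window: tuple[int, int] = (7, 13),
) -> pd.Series:
    """Kruskal-Wallis p of each species' relative abundance across window days.

    Large p supports the claim that correlations found by
    :func:`pathway_day_correlations` are not driven by biomass drift.
    """
    lo, hi = window
    in_window = design[(design["day"] >= lo) & (design["day"] <= hi)]
    days = sorted(in_window["day"].unique())
    if len(days) < 2:
        raise ValueError("stability check needs at least two distinct days")
    sample_day = in_window.set_index("sample")["day"]
    common = species_profiles.index.intersection(sample_day.index)
    out = {}
    for sp in species_profiles.columns:
        vals = species_profiles.loc[common, sp]
        groups = [
            vals[sample_day.reindex(common) == d].dropna().to_numpy() for d in days
        ]
        groups = [g for g in groups if len(g)]
        _, p = kruskal_wallis(groups)
        out[sp] = p
    return pd.Series(out, name="stability_p")


def correlation_report(
    correlations: pd.DataFrame, stability: pd.Series
) -> pd.DataFrame:
    """Join correlation records with the per-species abundance stability p."""
    report = correlations.merge(
        stability.rename("species_stability_p"),
        left_on="species",
        right_index=True,
        how="left",
    )
    return report
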