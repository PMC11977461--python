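"""Stage-wise univariate statistics: Kruskal-Wallis, Dunn, BH, log2FC, screen.

Each bioreactor-day sample is one observation.  Features (species, pathways,
metabolites) are compared across the cultivation stages with the
Kruskal-Wallis rank test, followed by Dunn's pairwise post-hoc on the shared
ranking.  P-values are Benjamini-Hochberg adjusted only when the family
exceeds a configurable size (default 20 independent tests; smaller families
keep raw p-values, flagged as unadjusted).  Effect sizes are log2 fold
changes of stage means, and the screen keeps features with p < 0.05 and
|log2FC| >= 0.175 (both thresholds configurable; the fold-change threshold
is inclusive).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import STAGES


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p across >= 2 groups.

    Mid-ranks with the standard tie correction; a degenerate family where
    every pooled value is identical returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need at least three observations in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z and two-sided normal p for every group pair.

    Uses the ranking shared across all groups (the Kruskal-Wallis context):
    z_AB = (Rbar_A - Rbar_B) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_A + 1/n_B))
    with tie term T = sum(t^3 - t) over tied values.  Empty groups are
    excluded with a warning.
    """
    clean = {}
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        if len(g) == 0:
            warnings.warn(f"excluding empty group {name!r} from Dunn's test")
            continue
        clean[name] = g
    if len(clean) < 2:
        raise ValueError("Dunn's test needs at least two non-empty groups")
    names = list(clean)
    pooled = np.concatenate([clean[n] for n in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for name in names:
        k = len(clean[name])
        mean_rank[name] = ranks[start:start + k].mean()
        sizes[name] = k
        start += k
    var_core = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def bh_adjust(
    pvalues: Sequence[float], apply_threshold: int = 20
) -> tuple[np.ndarray, bool]:
    """Benjamini-Hochberg step-up adjustment with a family-size rule.

    Families of size <= ``apply_threshold`` keep their raw p-values (returned
    flag False); larger families are adjusted (flag True).  Set
    ``apply_threshold=0`` to always adjust.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
    if p.size == 0:
        return p.copy(), False
    if len(p) <= apply_threshold:
        return p.copy(), False
    mask = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj, True


def log2_fold_change(
    values: pd.Series, design: pd.DataFrame, stage_a: str, stage_b: str
) -> float:
    """log2 of the ratio of stage means, stage_a over stage_b.

    The stage mean runs over every sample assigned to the stage.  A zero (or
    undefined) mean in either stage yields NaN with a warning; such features
    are excluded from the fold-change screen.
    """
    for stage in (stage_a, stage_b):
        if stage not in set(design["stage"]):
            raise ValueError(f"stage {stage!r} absent from the design")
    by_stage = design.set_index("sample")["stage"]
    aligned = values.reindex(by_stage.index)
    mean_a = aligned[by_stage == stage_a].mean()
    mean_b = aligned[by_stage == stage_b].mean()
    if not (mean_a > 0 and mean_b > 0):
        warnings.warn(
            f"undefined log2FC ({stage_a} mean {mean_a!r}, {stage_b} mean {mean_b!r})"
        )
        return float("nan")
    return float(np.log2(mean_a / mean_b))


def stage_statistics(
    profiles: pd.DataFrame,
    design: pd.DataFrame,
    compare: tuple[str, str] = ("exposure", "stabilization"),
    bh_threshold: int = 20,
    p_cut: float = 0.05,
    fc_cut: float = 0.175,
) -> pd.DataFrame:
    """Per-feature stage statistics table (one StatRecord per row).

    Kruskal-Wallis across all stages present in the design, Dunn's post-hoc
    per stage pair, BH adjustment of the KW family (when larger than
    ``bh_threshold``), log2FC for the ``compare`` stage pair, and the
    combined screen flag.  Features with NaN in a stage are compared on
    their non-missing samples.
    """
    stages = [s for s in STAGES if s in set(design["stage"])]
    if len(stages) < 2:
        raise ValueError("need at least two stages in the design")
    sample_stage = design.set_index("sample")["stage"]
    common = profiles.index.intersection(sample_stage.index)
    if len(common) < len(profiles.index):
        missing = profiles.index.difference(sample_stage.index)
        raise ValueError(f"samples missing from the design: {list(missing[:10])}")
    records = []
    pair_cols = [f"{a}_vs_{b}" for a, b in itertools.combinations(stages, 2)]
    for feature in profiles.columns:
        vals = profiles[feature]
        groups = {
            st: vals[sample_stage[sample_stage == st].index].dropna().to_numpy()
            for st in stages
        }
        groups = {st: g for st, g in groups.items() if len(g) > 0}
        rec: dict = {"feature": feature}
        try:
            rec["H"], rec["p"] = kruskal_wallis(list(groups.values()))
        except ValueError:
            rec["H"], rec["p"] = np.nan, np.nan
        if len(groups) >= 2 and np.isfinite(rec["H"]):
            dunn = dunn_posthoc(groups)
            for row in dunn.itertuples(index=False):
                rec[f"dunn_z_{row.group_a}_vs_{row.group_b}"] = row.z
                rec[f"dunn_p_{row.group_a}_vs_{row.group_b}"] = row.p
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec["log2fc"] = log2_fold_change(vals, design, *compare)
            for a, b in itertools.combinations(stages, 2):
                rec[f"log2fc_{a}_vs_{b}"] = log2_fold_change(vals, design, a, b)
        records.append(rec)
    table = pd.DataFrame(records).set_index("feature")
    table["p_adj"], adjusted = bh_adjust(table["p"].to_numpy(), bh_threshold)
    table["adjusted"] = adjusted
    decisive = table["p_adj"] if adjusted else table["p"]
    table["passes"] = (decisive < p_cut) & (table["log2fc"].abs() >= fc_cut)
    table.attrs["compare"] = f"{compare[0]}_vs_{compare[1]}"
    table.attrs["pair_columns"] = pair_cols
    return table


def screen_features(
    stats_table: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 0.175
) -> list[str]:
    """Features passing p (adjusted when applicable) < p_cut and |log2FC| >= fc_cut."""
    decisive = stats_table["p_adj"] if stats_table["adjusted"].any() else stats_table["p"]
    ok = (decisive < p_cut) & (stats_table["log2fc"].abs() >= fc_cut)
    return stats_table.index[ok.fillna(False)].tolist()


def compact_letters(
    pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from a Dunn pairwise table.

    Groups sharing a letter are not significantly different at ``alpha``
    (insert-and-absorb algorithm on the significance graph).
    """
    names: list[str] = []
    for row in pairwise_p.itertuples(index=False):
        for g in (row.group_a, row.group_b):
            if g not in names:
                names.append(g)
    sig = {
        frozenset((row.group_a, row.group_b))
        for row in pairwise_p.itertuples(index=False)
        if row.p < alpha
    }
    letters: list[set[str]] = [set(names)]
    for pair in sig:
        a, b = tuple(pair)
        for i in range(len(letters)):
            if a in letters[i] and b in letters[i]:
                without_a = letters[i] - {a}
                without_b = letters[i] - {b}
                letters[i] = without_a
                if not any(without_b <= other for j, other in enumerate(letters) if j != i):
                    letters.append(without_b)
    # absorb letter sets contained in others
    letters = [
        s for i, s in enumerate(letters)
        if s and not any(s < other for j, other in enumerate(letters) if j != i)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for s, letter in zip(letters, alphabet):
        for name in names:
            if name in s:
                out[name] += letter
    return out
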