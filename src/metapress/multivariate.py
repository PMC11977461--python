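"""Ordination and permutation-based multivariate testing of profiles.

PCA on centered (optionally standardized) profiles, and one-way PERMANOVA
in Anderson's sum-of-squares formulation: the total sum of squared
distances is partitioned into among- and within-group parts, giving a
pseudo-F whose null distribution is obtained by permuting group labels.
The permutation p-value is (1 + #{permuted F >= observed}) / (1 + n_perm),
matching vegan's adonis2.  Distances default to Euclidean on
relative-abundance profiles (adonis2's default); Bray-Curtis and Aitchison
(CLR then Euclidean) are available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .design import STAGES

METRICS = ("euclidean", "braycurtis", "aitchison")


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray  # non-increasing, sums to <= 1
    loadings: pd.DataFrame  # features x components


def pca(profiles: pd.DataFrame, center: bool = True, scale: bool = False) -> OrdinationResult:
    """Principal component analysis by SVD of the (centered) data matrix.

    With ``scale=True`` features are divided by their standard deviation
    (correlation PCA); constant features are then dropped with a warning.
    Component signs follow a deterministic convention: the largest-magnitude
    loading of each component is positive.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    x = profiles.to_numpy(dtype=float)
    cols = profiles.columns
    if scale:
        sd = x.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"dropping constant feature(s) before scaling: {list(cols[constant])}"
            )
            x, cols = x[:, ~constant], cols[~constant]
            sd = sd[~constant]
    if center:
        x = x - x.mean(axis=0)
    if scale:
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2 / max(profiles.shape[0] - 1, 1)
    total_var = var.sum()
    ratio = var / total_var if total_var > 0 else np.zeros_like(var)
    names = [f"PC{i + 1}" for i in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(u * s, index=profiles.index, columns=names),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(vt.T, index=cols, columns=names),
    )


def clr_transform(profiles: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform with a pseudocount for zeros.

    Default pseudocount: half the smallest positive value in the table.
    """
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("CLR requires non-negative data")
    if pseudocount is None:
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all-zero table cannot be CLR-transformed")
        pseudocount = positive.min() / 2.0
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=profiles.index, columns=profiles.columns)


def distance_matrix(
    profiles: pd.DataFrame, metric: str = "euclidean", pseudocount: float | None = None
) -> pd.DataFrame:
    """Square symmetric sample-by-sample distance matrix."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if metric == "aitchison":
        data = clr_transform(profiles, pseudocount)
        condensed = pdist(data.to_numpy(), metric="euclidean")
    else:
        condensed = pdist(profiles.to_numpy(dtype=float), metric=metric)
    dm = pd.DataFrame(
        squareform(condensed), index=profiles.index, columns=profiles.index
    )
    dm.attrs["metric"] = metric
    return dm


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss += block.sum() / (2.0 * len(idx))
    return ss


def permanova(
    dist: pd.DataFrame,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with seeded label permutation.

    ``grouping`` is a sequence or Series of group labels aligned with the
    distance matrix.  p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if isinstance(grouping, pd.Series):
        grouping = grouping.reindex(dist.index) if hasattr(dist, "index") else grouping
    labels = np.asarray(grouping)
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length does not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    n, a = len(labels), len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    if ss_within <= 0:
        f_obs = np.inf if ss_among > 0 else 0.0
    else:
        f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssw = _ss_within(d2, perm, uniq)
        ssa = ss_total - ssw
        f_perm = np.inf if ssw <= 0 and ssa > 0 else (
            0.0 if ssw <= 0 else (ssa / df_among) / (ssw / df_within)
        )
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, n, a)


def stagewise_permanova(
    profiles: pd.DataFrame,
    design: pd.DataFrame,
    metric: str = "euclidean",
    n_perm: int = 999,
    seed: int | None = None,
    pairs: list[tuple[str, str]] | None = None,
    include_all: bool = True,
) -> pd.DataFrame:
    """PERMANOVA per stage pair plus the all-stages comparison.

    Default comparisons: stabilization vs exposure, exposure vs recovery,
    stabilization vs recovery, and all stages combined; each gets its own
    reproducible child seed derived from ``seed``.
    """
    present = [s for s in STAGES if s in set(design["stage"])]
    if pairs is None:
        pairs = list(itertools.combinations(present, 2))
    for a, b in pairs:
        for st in (a, b):
            if st not in present:
                raise ValueError(f"stage {st!r} missing from the design")
    sample_stage = design.set_index("sample")["stage"].reindex(profiles.index)
    if sample_stage.isna().any():
        missing = profiles.index[sample_stage.isna()]
        raise ValueError(f"samples missing from the design: {list(missing[:10])}")
    comparisons: list[tuple[str, list[str]]] = [
        (f"{a}_vs_{b}", [a, b]) for a, b in pairs
    ]
    if include_all and len(present) > 2:
        comparisons.append(("all_stages", present))
    children = np.random.SeedSequence(seed).spawn(len(comparisons))
    rows = []
    for (name, stages), child in zip(comparisons, children):
        mask = sample_stage.isin(stages)
        sub = profiles.loc[mask]
        dm = distance_matrix(sub, metric=metric)
        res = permanova(dm, sample_stage[mask], n_perm=n_perm,
                        seed=child.generate_state(1)[0])
        rows.append(
            {
                "comparison": name,
                "pseudo_F": res.pseudo_f,
                "R2": res.r_squared,
                "p": res.p_value,
                "n_permutations": res.n_permutations,
                "n_samples": res.n_samples,
            }
        )
    return pd.DataFrame(rows)
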