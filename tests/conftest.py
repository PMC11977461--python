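import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metapress import (
    AnnotationMap,
    CommunitySpec,
    PerturbationSpec,
    generate_dataset,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec() -> CommunitySpec:
    return CommunitySpec(proteins_per_species=100, pathway_count=20, untargeted_features=30)


@pytest.fixture(scope="session")
def noise_free_dataset(small_spec):
    """sigma = 0, no planted effects: every bioreactor/day deterministic."""
    return generate_dataset(
        small_spec, PerturbationSpec(sigma=0.0, scfa_sigma=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def perturbed_dataset(small_spec):
    """A run with planted species, pathway and SCFA effects at sigma = 0.1."""
    perturb = PerturbationSpec(
        species_effects={
            "Bacteroides thetaiotaomicron": {"exposure": 1.6, "recovery": 1.4},
            "Clostridium butyricum": {"exposure": 0.6},
            "Bifidobacterium longum": {"exposure": 0.6},
        },
        pathway_effects={("PW003", "exposure"): -1.0, ("PW007", "exposure"): 0.4},
        scfa_effects={("butyrate", "exposure"): 0.7, ("lactate", "exposure"): 0.5},
        sigma=0.1,
        seed=23,
    )
    return generate_dataset(small_spec, perturb)


@pytest.fixture(scope="session")
def perturbed_annotation(perturbed_dataset) -> AnnotationMap:
    return AnnotationMap(perturbed_dataset.annotations)


@pytest.fixture()
def tiny_intensities() -> pd.DataFrame:
    """Two samples, five protein groups across two species, hand-checkable."""
    return pd.DataFrame(
        {
            "a1": [3.0, 2.0],
            "a2": [1.0, 2.0],
            "b1": [4.0, 4.0],
            "b2": [0.0, 1.0],
            "b3": [0.0, 1.0],
        },
        index=pd.Index(["s1", "s2"], name="sample"),
    )


@pytest.fixture()
def tiny_annotation() -> AnnotationMap:
    frame = pd.DataFrame(
        {
            "protein_group": ["a1", "a2", "b1", "b2", "b3"],
            "species": ["A", "A", "B", "B", "B"],
            "ko": ["K1", "K2", "K3", "K2", ""],
            "pathways": ["P1", "P1;P2", "P2", "P1;P2", ""],
        }
    )
    return AnnotationMap(frame)


def hand_midranks(values):
    """Mid-ranks computed from the definition, independent of scipy."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j + 2) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def hand_kruskal_h(groups):
    """Kruskal-Wallis H from the rank-sum definition with tie correction."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    ranks = hand_midranks(pooled)
    h0, start = 0.0, 0
    for g in groups:
        r = sum(ranks[start:start + len(g)])
        h0 += r * r / len(g)
        start += len(g)
    h0 = 12.0 / (n_total * (n_total + 1)) * h0 - 3.0 * (n_total + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n_total**3 - n_total)
    return h0 / correction if correction > 0 else 0.0


def hand_spearman_rho(x, y):
    """Pearson correlation of mid-ranks, from the definition."""
    rx = np.array(hand_midranks(x))
    ry = np.array(hand_midranks(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def hand_permanova_f(dist, labels):
    """Pseudo-F from the squared-distance partition, coded independently."""
    d2 = np.asarray(dist, dtype=float) ** 2
    labels = np.asarray(labels)
    n = len(labels)
    uniq = sorted(set(labels))
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = [i for i in range(n) if labels[i] == g]
        pair_sum = sum(d2[i, j] for i in idx for j in idx)
        ss_within += pair_sum / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    a = len(uniq)
    return (ss_among / (a - 1)) / (ss_within / (n - a))
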