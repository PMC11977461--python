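import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import hand_kruskal_h, hand_midranks
from metapress import (
    bh_adjust,
    compact_letters,
    dunn_posthoc,
    kruskal_wallis,
    log2_fold_change,
    make_design,
    screen_features,
    stage_statistics,
)


def exact_kw_permutation_p(group_a, group_b):
    """Exhaustive two-group permutation p for the Kruskal-Wallis H."""
    pooled = list(group_a) + list(group_b)
    n_a = len(group_a)
    h_obs = hand_kruskal_h([group_a, group_b])
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if hand_kruskal_h([a, b]) >= h_obs - 1e-9:
            count += 1
        total += 1
    return count / total


class TestKruskalWallis:
    def test_hand_rank_computation(self):
        # ranks 1..6; R1=6, R2=15; H = 12/(6*7)*(36/3+225/3) - 21 = 27/7
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(27 / 7, df=1), rel=1e-12)

    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_hand_formula_with_ties(self):
        groups = [[1, 1, 2, 5], [2, 3, 3], [4, 4, 9]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(hand_kruskal_h(groups), rel=1e-12)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 5, 2], [3, 4, 6, 7]),
            ([1.5, 2.5], [0.5, 3.5, 4.5]),
            ([1, 1, 2], [2, 3, 3]),
            ([10, 3, 7, 1], [2, 8, 5, 6]),
        ],
    )
    def test_chi2_p_tracks_exact_permutation_p(self, a, b):
        """For N <= 8 the chi-square p stays within the documented 0.15
        absolute error of the exhaustive permutation p in the
        decision-relevant region; with a near-null statistic both p values
        agree on clear non-significance (the asymptotic approximation is
        known to be coarse below N ~ 9)."""
        _, p_chi2 = kruskal_wallis([a, b])
        p_exact = exact_kw_permutation_p(a, b)
        assert abs(p_chi2 - p_exact) < 0.15 or min(p_chi2, p_exact) > 0.3

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=6),
           st.lists(st.floats(-100, 100), min_size=2, max_size=6))
    def test_invariant_under_monotone_transform(self, a, b):
        h1, _ = kruskal_wallis([a, b])
        # strictly increasing map that exactly preserves order and ties
        order = {v: float(i * i + i) for i, v in enumerate(sorted(set(a + b)))}
        f = lambda xs: [order[x] for x in xs]
        h2, _ = kruskal_wallis([f(a), f(b)])
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError, match="one observation"):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ValueError, match="three observations"):
            kruskal_wallis([[1], [2]])


def scalar_dunn_z(groups, pair):
    """Independent Dunn z from the closed form, one pair at a time."""
    names = list(groups)
    pooled = [v for n in names for v in groups[n]]
    ranks = hand_midranks(pooled)
    mean_rank, start = {}, 0
    for n in names:
        k = len(groups[n])
        mean_rank[n] = sum(ranks[start:start + k]) / k
        start += k
    n_total = len(pooled)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n_total - 1))
    var = n_total * (n_total + 1) / 12.0 - tie_term
    a, b = pair
    se = math.sqrt(var * (1 / len(groups[a]) + 1 / len(groups[b])))
    return (mean_rank[a] - mean_rank[b]) / se


class TestDunnPosthoc:
    def test_closed_form_three_groups(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        table = dunn_posthoc(groups).set_index(["group_a", "group_b"])
        # mean ranks 2, 5, 8; var core = 9*10/12 = 7.5; se = sqrt(5)
        assert table.loc[("g1", "g2"), "z"] == pytest.approx(-3 / math.sqrt(5), rel=1e-12)
        assert table.loc[("g1", "g3"), "z"] == pytest.approx(-6 / math.sqrt(5), rel=1e-12)
        for pair in table.index:
            assert table.loc[pair, "z"] == pytest.approx(
                scalar_dunn_z(groups, pair), rel=1e-12
            )

    def test_tie_correction_hand_computation(self):
        groups = {"A": [1, 1, 2], "B": [2, 3, 3]}
        table = dunn_posthoc(groups)
        # mid-ranks 1.5,1.5,3.5 | 3.5,5.5,5.5; tie term 18/(12*5)=0.3
        # var core 3.5-0.3=3.2; z = (13/6 - 29/6)/sqrt(3.2*2/3)
        expected = (13 / 6 - 29 / 6) / math.sqrt(3.2 * 2 / 3)
        assert table.loc[0, "z"] == pytest.approx(expected, rel=1e-12)
        assert table.loc[0, "z"] == pytest.approx(scalar_dunn_z(groups, ("A", "B")))

    def test_antisymmetry(self):
        groups = {"A": [3, 1, 4], "B": [1, 5, 9], "C": [2, 6, 5]}
        z_ab = scalar_dunn_z(groups, ("A", "B"))
        z_ba = scalar_dunn_z(groups, ("B", "A"))
        assert z_ab == pytest.approx(-z_ba, rel=1e-12)

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty group"):
            table = dunn_posthoc({"A": [1, 2], "B": [], "C": [3, 4]})
        assert set(table["group_a"]) | set(table["group_b"]) == {"A", "C"}


class TestBHAdjust:
    def test_step_up_hand_calculation(self):
        adj, adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04], apply_threshold=0)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert adjusted

    def test_small_family_stays_raw(self):
        adj, adjusted = bh_adjust([0.01, 0.5], apply_threshold=20)
        np.testing.assert_array_equal(adj, [0.01, 0.5])
        assert not adjusted

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.3], apply_threshold=0)
        assert adj[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=21, max_size=60))
    def test_monotone_order_preserving_and_bounded(self, ps):
        adj, adjusted = bh_adjust(ps)
        assert adjusted
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_equal_ps_unchanged(self):
        adj, _ = bh_adjust([0.2] * 25)
        np.testing.assert_allclose(adj, 0.2)


class TestLog2FoldChange:
    @pytest.fixture()
    def design(self):
        return make_design(n_bioreactors=1)

    def test_half_is_minus_one(self, design):
        vals = pd.Series(
            [1.0] * 3 + [2.0] * 7 + [2.0] * 4, index=design["sample"]
        )
        fc = log2_fold_change(vals, design, "stabilization", "exposure")
        assert fc == pytest.approx(-1.0)

    def test_equal_means_zero(self, design):
        vals = pd.Series(3.0, index=design["sample"])
        assert log2_fold_change(vals, design, "exposure", "stabilization") == 0.0

    def test_zero_mean_flagged_undefined(self, design):
        vals = pd.Series([0.0] * 3 + [1.0] * 11, index=design["sample"])
        with pytest.warns(UserWarning, match="undefined"):
            fc = log2_fold_change(vals, design, "exposure", "stabilization")
        assert math.isnan(fc)

    def test_unknown_stage_rejected(self, design):
        vals = pd.Series(1.0, index=design["sample"])
        with pytest.raises(ValueError, match="washout"):
            log2_fold_change(vals, design, "washout", "exposure")


class TestScreen:
    def _table(self, p, fc):
        return pd.DataFrame(
            {"p": [p], "p_adj": [p], "adjusted": [False], "log2fc": [fc]},
            index=["f"],
        )

    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            (0.04, 0.18, True),   # both criteria met
            (0.04, 0.175, True),  # fold threshold is inclusive
            (0.04, 0.10, False),  # below the fold threshold
            (0.2, 5.0, False),    # not significant
            (0.05, 0.5, False),   # p threshold is strict
        ],
    )
    def test_boundary_logic(self, p, fc, expected):
        passing = screen_features(self._table(p, fc))
        assert (passing == ["f"]) is expected


class TestStageStatistics:
    def test_planted_effects_recovered(self, perturbed_dataset, perturbed_annotation):
        from metapress import species_relative_abundance

        profile = species_relative_abundance(
            perturbed_dataset.intensities, perturbed_annotation
        )
        table = stage_statistics(profile, perturbed_dataset.metadata)
        truth = perturbed_dataset.truth["expected_species_log2fc"][
            "exposure_vs_stabilization"
        ]
        bt = "Bacteroides thetaiotaomicron"
        assert table.loc[bt, "p"] < 0.05
        assert table.loc[bt, "log2fc"] == pytest.approx(truth[bt], abs=0.05)
        cb = "Clostridium butyricum"
        assert table.loc[cb, "p"] < 0.05
        assert table.loc[cb, "log2fc"] == pytest.approx(truth[cb], abs=0.05)

    def test_contains_dunn_and_pairwise_fc_columns(self, perturbed_dataset,
                                                   perturbed_annotation):
        from metapress import species_relative_abundance

        profile = species_relative_abundance(
            perturbed_dataset.intensities, perturbed_annotation
        )
        table = stage_statistics(profile, perturbed_dataset.metadata)
        assert "dunn_p_stabilization_vs_exposure" in table.columns
        assert "log2fc_exposure_vs_recovery" in table.columns
        assert not table["adjusted"].any()  # only 8 species: family <= 20


class TestCompactLetters:
    def test_hand_checked_three_group_fixture(self):
        # g1 != g3 significant; g2 indistinguishable from both
        pairs = pd.DataFrame(
            [
                {"group_a": "g1", "group_b": "g2", "p": 0.20},
                {"group_a": "g1", "group_b": "g3", "p": 0.001},
                {"group_a": "g2", "group_b": "g3", "p": 0.30},
            ]
        )
        letters = compact_letters(pairs)
        assert set(letters["g1"]) != set(letters["g3"])
        assert not set(letters["g1"]) & set(letters["g3"])
        assert set(letters["g2"]) & set(letters["g1"])
        assert set(letters["g2"]) & set(letters["g3"])

    def test_all_different(self):
        pairs = pd.DataFrame(
            [
                {"group_a": "a", "group_b": "b", "p": 0.001},
                {"group_a": "a", "group_b": "c", "p": 0.001},
                {"group_a": "b", "group_b": "c", "p": 0.001},
            ]
        )
        letters = compact_letters(pairs)
        assert len({letters["a"], letters["b"], letters["c"]}) == 3

    def test_no_differences_share_one_letter(self):
        pairs = pd.DataFrame(
            [{"group_a": "a", "group_b": "b", "p": 0.9}]
        )
        letters = compact_letters(pairs)
        assert letters["a"] == letters["b"]
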