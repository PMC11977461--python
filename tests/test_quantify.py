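import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metapress import (
    AnnotationMap,
    PathwayDefinitions,
    pathway_filter,
    pathway_intensity,
    pathway_relative_abundance,
    species_relative_abundance,
    within_species_pathway_abundance,
)


class TestSpeciesRelativeAbundance:
    def test_hand_summation(self):
        # one sample: A has 3 + 1, B has 4 -> 0.5 / 0.5
        tbl = pd.DataFrame({"a1": [3.0], "a2": [1.0], "b1": [4.0]}, index=["s1"])
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["a1", "a2", "b1"],
            "species": ["A", "A", "B"],
        }))
        profile = species_relative_abundance(tbl, ann)
        assert profile.loc["s1", "A"] == pytest.approx(0.5)
        assert profile.loc["s1", "B"] == pytest.approx(0.5)

    def test_single_species_is_one(self):
        tbl = pd.DataFrame({"a1": [3.0], "a2": [9.0]}, index=["s1"])
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["a1", "a2"], "species": ["A", "A"],
        }))
        assert species_relative_abundance(tbl, ann).loc["s1", "A"] == 1.0

    def test_rows_on_simplex(self, perturbed_dataset, perturbed_annotation):
        profile = species_relative_abundance(
            perturbed_dataset.intensities, perturbed_annotation
        )
        np.testing.assert_allclose(profile.sum(axis=1), 1.0, atol=1e-9)
        assert ((profile >= 0) & (profile <= 1)).all().all()

    def test_zero_total_sample_excluded_with_warning(self, tiny_annotation):
        tbl = pd.DataFrame(
            {"a1": [1.0, 0.0], "a2": [1.0, 0.0], "b1": [1.0, 0.0],
             "b2": [0.0, 0.0], "b3": [0.0, 0.0]},
            index=["ok", "empty"],
        )
        with pytest.warns(UserWarning, match="empty"):
            profile = species_relative_abundance(tbl, tiny_annotation)
        assert list(profile.index) == ["ok"]

    def test_unannotated_protein_rejected(self, tiny_annotation):
        tbl = pd.DataFrame({"a1": [1.0], "zz": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="zz"):
            species_relative_abundance(tbl, tiny_annotation)

    def test_shared_protein_error_and_split(self):
        frame = pd.DataFrame({
            "protein_group": ["x", "x"], "species": ["A", "B"],
        })
        with pytest.raises(ValueError, match="multiple species"):
            AnnotationMap(frame)
        ann = AnnotationMap(frame, on_shared="split")
        tbl = pd.DataFrame({"x": [2.0]}, index=["s1"])
        profile = species_relative_abundance(tbl, ann)
        assert profile.loc["s1", "A"] == pytest.approx(0.5)

    @given(scale=st.floats(0.1, 100.0))
    def test_scale_invariance_per_sample(self, scale):
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame(
            rng.uniform(0.1, 10, size=(3, 4)),
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "b1", "b2"],
        )
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["a1", "a2", "b1", "b2"],
            "species": ["A", "A", "B", "B"],
        }))
        base = species_relative_abundance(tbl, ann)
        scaled = species_relative_abundance(tbl * scale, ann)
        pd.testing.assert_frame_equal(base, scaled)


class TestPathwayIntensity:
    def test_hand_sums(self, tiny_intensities, tiny_annotation):
        pw = pathway_intensity(tiny_intensities, tiny_annotation)
        # P1: a1 + a2 + b2; P2: a2 + b1 + b2 (multi-pathway proteins count fully)
        assert pw.loc["s1", "P1"] == pytest.approx(3 + 1 + 0)
        assert pw.loc["s1", "P2"] == pytest.approx(1 + 4 + 0)
        assert pw.loc["s2", "P1"] == pytest.approx(2 + 2 + 1)
        assert pw.loc["s2", "P2"] == pytest.approx(2 + 4 + 1)

    def test_multi_pathway_protein_contributes_fully(self):
        tbl = pd.DataFrame({"x": [5.0]}, index=["s1"])
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["x"], "species": ["A"],
            "ko": ["K1"], "pathways": ["P1;P2"],
        }))
        pw = pathway_intensity(tbl, ann)
        assert pw.loc["s1", "P1"] == 5.0
        assert pw.loc["s1", "P2"] == 5.0
        halved = pathway_intensity(tbl, ann, split=True)
        assert halved.loc["s1", "P1"] == 2.5

    def test_undetected_pathway_yields_zero_column(self, tiny_annotation):
        tbl = pd.DataFrame({"b1": [4.0]}, index=["s1"])  # only b1 detected
        ann = tiny_annotation
        sub = AnnotationMap(ann.table[ann.table["protein_group"].isin(["b1", "a1"])]
                            .drop(columns="weight"))
        pw = pathway_intensity(tbl, sub)
        assert pw.loc["s1", "P1"] == 0.0  # a1 annotated to P1 but not detected
        assert pw.loc["s1", "P2"] == 4.0

    def test_exhaustive_resummation_oracle(self):
        """All aggregations match a direct per-cell re-summation (<=10 proteins)."""
        rng = np.random.default_rng(5)
        proteins = [f"p{i}" for i in range(10)]
        species = [rng.choice(["A", "B", "C"]) for _ in proteins]
        kos = [f"K{i}" for i in range(10)]
        pathways = [";".join(rng.choice(["P1", "P2", "P3"],
                                        size=rng.integers(0, 3), replace=False))
                    for _ in proteins]
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": proteins, "species": species,
            "ko": kos, "pathways": pathways,
        }))
        tbl = pd.DataFrame(rng.uniform(0, 5, size=(4, 10)),
                           index=[f"s{i}" for i in range(4)], columns=proteins)
        sp_prof = species_relative_abundance(tbl, ann)
        pw_int = pathway_intensity(tbl, ann)
        for s in tbl.index:
            total = sum(tbl.loc[s, p] for p in proteins)
            for target in ("A", "B", "C"):
                manual = sum(tbl.loc[s, p] for p, sp in zip(proteins, species)
                             if sp == target)
                assert sp_prof.loc[s, target] == pytest.approx(manual / total)
            for pw in pw_int.columns:
                manual = sum(tbl.loc[s, p] for p, ps in zip(proteins, pathways)
                             if pw in ps.split(";"))
                assert pw_int.loc[s, pw] == pytest.approx(manual)


class TestPathwayFilter:
    @pytest.fixture()
    def crafted(self):
        """Five pathways spanning both filter boundaries.

        P_pass: 6 proteins, 6/20 KOs (coverage 0.30)        -> retained
        P_few: 4 proteins, 10/20 KOs (coverage 0.50)        -> excluded (proteins)
        P_edge: exactly 5 proteins, 3/20 KOs (coverage 0.15) -> retained (inclusive)
        P_thin: 10 proteins, 2/20 KOs (coverage 0.10)        -> excluded (coverage)
        P_none: 1 protein, 1/20 KOs                          -> excluded (both)
        """
        rows = []
        for i in range(6):
            rows.append(("pass%d" % i, "A", "KP%d" % i, "P_pass"))
        for i in range(4):
            rows.append(("few%d" % i, "A", "KF%d" % i, "P_few"))
        # 5 proteins over 3 distinct KOs
        for i, ko in enumerate(["KE0", "KE1", "KE2", "KE0", "KE1"]):
            rows.append(("edge%d" % i, "B", ko, "P_edge"))
        for i in range(10):
            rows.append(("thin%d" % i, "B", "KT%d" % (i % 2), "P_thin"))
        rows.append(("none0", "C", "KN0", "P_none"))
        ann = AnnotationMap(pd.DataFrame(
            rows, columns=["protein_group", "species", "ko", "pathways"]
        ))
        defs = PathwayDefinitions({
            "P_pass": [f"KP{i}" for i in range(6)] + [f"X{i}" for i in range(14)],
            "P_few": [f"KF{i}" for i in range(10)] + [f"Y{i}" for i in range(10)],
            "P_edge": ["KE0", "KE1", "KE2"] + [f"Z{i}" for i in range(17)],
            "P_thin": ["KT0", "KT1"] + [f"W{i}" for i in range(18)],
            "P_none": ["KN0"] + [f"V{i}" for i in range(19)],
        })
        return ann, defs

    def test_boundary_cases(self, crafted):
        ann, defs = crafted
        assert pathway_filter(ann, defs) == ["P_edge", "P_pass"]

    def test_monotone_in_thresholds(self, crafted):
        ann, defs = crafted
        base = set(pathway_filter(ann, defs))
        for mp in (5, 6, 7, 10):
            for mc in (0.15, 0.2, 0.31, 0.5):
                tighter = set(pathway_filter(ann, defs, mp, mc))
                assert tighter <= base

    def test_protein_coverage_basis(self, crafted):
        ann, defs = crafted
        # P_edge: 5 proteins / 20 reference KOs = 0.25 under the protein basis
        retained = pathway_filter(ann, defs, coverage_basis="protein")
        assert "P_edge" in retained

    def test_missing_definition_is_an_error(self, crafted):
        ann, _ = crafted
        defs = PathwayDefinitions({"P_pass": ["KP0"]})
        with pytest.raises(KeyError, match="P_few"):
            pathway_filter(ann, defs)


class TestRelativeAbundanceProfiles:
    def test_pathway_shares_hand_arithmetic(self):
        pw = pd.DataFrame({"P1": [2.0], "P2": [6.0]}, index=["s1"])
        prof = pathway_relative_abundance(pw)
        assert prof.loc["s1", "P1"] == pytest.approx(0.25)
        assert prof.loc["s1", "P2"] == pytest.approx(0.75)

    def test_single_pathway_is_one(self):
        pw = pd.DataFrame({"P1": [2.0, 5.0]}, index=["s1", "s2"])
        assert (pathway_relative_abundance(pw)["P1"] == 1.0).all()

    def test_rows_sum_to_one(self, perturbed_dataset, perturbed_annotation):
        pw = pathway_intensity(perturbed_dataset.intensities, perturbed_annotation)
        prof = pathway_relative_abundance(pw)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_retained_set_rejected(self):
        pw = pd.DataFrame({"P1": [2.0]}, index=["s1"])
        with pytest.raises(ValueError, match="empty"):
            pathway_relative_abundance(pw, retained=[])


class TestWithinSpeciesPathwayAbundance:
    def test_hand_arithmetic(self):
        # species proteins: pathway P has 2, elsewhere 6 -> share 0.25
        tbl = pd.DataFrame({"a1": [2.0], "a2": [6.0]}, index=["s1"])
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["a1", "a2"], "species": ["A", "A"],
            "ko": ["K1", "K2"], "pathways": ["P", ""],
        }))
        prof = within_species_pathway_abundance(tbl, ann, "A")
        assert prof.loc["s1", "P"] == pytest.approx(0.25)

    def test_species_entirely_in_one_pathway(self):
        tbl = pd.DataFrame({"a1": [2.0], "a2": [6.0]}, index=["s1"])
        ann = AnnotationMap(pd.DataFrame({
            "protein_group": ["a1", "a2"], "species": ["A", "A"],
            "ko": ["K1", "K2"], "pathways": ["P", "P"],
        }))
        assert within_species_pathway_abundance(tbl, ann, "A").loc["s1", "P"] == 1.0

    @given(factor=st.floats(0.01, 100.0))
    def test_invariant_to_species_abundance(self, factor, tiny_intensities, tiny_annotation):
        """Doubling (or any scaling of) a species' intensities leaves its
        within-species profile unchanged - the defining decoupling property."""
        base = within_species_pathway_abundance(tiny_intensities, tiny_annotation, "B")
        scaled_tbl = tiny_intensities.copy()
        b_cols = ["b1", "b2", "b3"]
        scaled_tbl[b_cols] = scaled_tbl[b_cols] * factor
        scaled = within_species_pathway_abundance(scaled_tbl, tiny_annotation, "B")
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-9)

    def test_zero_species_total_becomes_missing(self, tiny_annotation):
        tbl = pd.DataFrame(
            {"a1": [1.0, 1.0], "a2": [1.0, 1.0], "b1": [2.0, 0.0],
             "b2": [1.0, 0.0], "b3": [0.0, 0.0]},
            index=["s1", "s2"],
        )
        prof = within_species_pathway_abundance(tbl, tiny_annotation, "B")
        assert prof.loc["s2"].isna().all()
        assert np.isfinite(prof.loc["s1"]).all()

    def test_unknown_species_rejected(self, tiny_intensities, tiny_annotation):
        with pytest.raises(ValueError, match="not present"):
            within_species_pathway_abundance(tiny_intensities, tiny_annotation, "Z")
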