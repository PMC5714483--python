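"""Severity-matrix analytics, chromosome-loss calling, and silencing calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from histscreen.catalog import Mutant, MutantCatalog
from histscreen.phenotypes import (
    PhenotypeError,
    analyze_chromosome_loss,
    analyze_silencing,
    call_silencing,
    call_unstable,
    chromosome_loss_rate,
    class_label,
    conservation_compare,
    count_phenotype_classes,
    fraction_with_phenotype,
    residue_severity,
    subset_relation,
    validate_severity_matrix,
)


def _catalog():
    return MutantCatalog(
        [
            Mutant("K34E", "H2B", "K34E", (34,), "A" * 20, "C" * 20),
            Mutant("K34Q", "H2B", "K34Q", (34,), "G" * 20, "T" * 20),
            Mutant("S121D", "H2A", "S121D", (121,), "AC" * 10, "GT" * 10),
        ]
    )


CLASS_MAP = {"HU": "DNA_damage", "MMS": "DNA_damage", "UV": "DNA_damage",
             "benomyl": "microtubule", "39C": "temperature", "caffeine": "other"}


class TestResidueSeverity:
    def test_max_rule_over_mutants_of_one_residue(self):
        matrix = pd.DataFrame(
            {"HU": [2, 3, 0]}, index=["K34E", "K34Q", "S121D"]
        )
        out = residue_severity(matrix, _catalog())
        assert out.loc[("H2B", 34), "HU"] == 3
        assert out.loc[("H2A", 121), "HU"] == 0

    def test_single_mutant_residue_passes_through(self):
        matrix = pd.DataFrame({"HU": [0, 0, 4]}, index=["K34E", "K34Q", "S121D"])
        out = residue_severity(matrix, _catalog())
        assert out.loc[("H2A", 121), "HU"] == 4

    def test_unknown_mutant_named_in_error(self):
        matrix = pd.DataFrame({"HU": [1]}, index=["nope"])
        with pytest.raises(PhenotypeError, match="nope"):
            residue_severity(matrix, _catalog())

    def test_matches_brute_force_group_by_max(self, rng):
        catalog = _catalog()
        matrix = pd.DataFrame(
            rng.integers(0, 5, size=(3, 4)),
            index=["K34E", "K34Q", "S121D"],
            columns=["HU", "MMS", "UV", "benomyl"],
        )
        out = residue_severity(matrix, catalog)
        for (histone, residue), row in out.iterrows():
            touching = [m.id for m in catalog
                        if m.histone == histone and residue in m.residues]
            for cond in matrix.columns:
                assert row[cond] == max(matrix.loc[m, cond] for m in touching)

    def test_idempotent_and_bounded(self, rng):
        matrix = pd.DataFrame(
            rng.integers(0, 5, size=(3, 2)), index=["K34E", "K34Q", "S121D"],
            columns=["HU", "MMS"],
        )
        out = residue_severity(matrix, _catalog())
        assert out.to_numpy().max() <= matrix.to_numpy().max()


class TestClassCounts:
    def test_two_conditions_same_class_count_one(self):
        matrix = pd.DataFrame({"HU": [2], "MMS": [1]}, index=["K34E"])
        assert count_phenotype_classes(matrix, CLASS_MAP).iloc[0] == 1
        assert class_label(1) == "I"

    def test_two_distinct_classes(self):
        matrix = pd.DataFrame({"HU": [2], "benomyl": [1]}, index=["K34E"])
        assert count_phenotype_classes(matrix, CLASS_MAP).iloc[0] == 2

    def test_all_zero_row_counts_zero(self):
        matrix = pd.DataFrame({"HU": [0], "benomyl": [0]}, index=["K34E"])
        assert count_phenotype_classes(matrix, CLASS_MAP).iloc[0] == 0

    def test_unmapped_condition_errors(self):
        matrix = pd.DataFrame({"mystery": [1]}, index=["K34E"])
        with pytest.raises(PhenotypeError, match="mystery"):
            count_phenotype_classes(matrix, CLASS_MAP)

    def test_invariant_to_all_zero_condition_columns(self, rng):
        matrix = pd.DataFrame(
            rng.integers(0, 5, size=(5, 3)),
            index=[f"m{i}" for i in range(5)], columns=["HU", "benomyl", "39C"],
        )
        widened = matrix.assign(caffeine=0)
        base = count_phenotype_classes(matrix, CLASS_MAP)
        wide = count_phenotype_classes(widened, CLASS_MAP)
        assert base.equals(wide)


class TestFractionAndSets:
    def test_all_zero_matrix(self):
        matrix = pd.DataFrame(np.zeros((10, 2), dtype=int),
                              columns=["HU", "MMS"])
        assert fraction_with_phenotype(matrix) == (0, 10, 0.0)

    def test_two_of_three(self):
        matrix = pd.DataFrame({"HU": [1, 0, 3]}, index=list("abc"))
        num, den, frac = fraction_with_phenotype(matrix)
        assert (num, den) == (2, 3)
        assert frac == pytest.approx(2 / 3)

    def test_severity_bounds_enforced(self):
        with pytest.raises(PhenotypeError):
            validate_severity_matrix(pd.DataFrame({"HU": [5]}))

    @pytest.mark.parametrize(
        "a,b,relation,counts",
        [
            ({"a", "b"}, {"a", "b", "c"}, "A_subset_B", (0, 1, 2)),
            ({"a"}, {"b"}, "disjoint", (1, 1, 0)),
            ({"a", "b"}, {"a", "b"}, "equal", (0, 0, 2)),
            ({"a", "c"}, {"a", "b"}, "overlap", (1, 1, 1)),
            ({"a", "b", "c"}, {"b"}, "B_subset_A", (2, 0, 1)),
        ],
    )
    def test_subset_relation(self, a, b, relation, counts):
        assert subset_relation(a, b) == (relation, counts)

    @given(st.sets(st.integers(0, 8)), st.sets(st.integers(0, 8)))
    @settings(max_examples=200, deadline=None)
    def test_subset_relation_mirror_consistency(self, a, b):
        rel_ab, (a_only, b_only, both) = subset_relation(a, b)
        rel_ba, (b_only2, a_only2, both2) = subset_relation(b, a)
        assert (a_only, b_only, both) == (a_only2, b_only2, both2)
        mirror = {"A_subset_B": "B_subset_A", "B_subset_A": "A_subset_B",
                  "equal": "equal", "overlap": "overlap", "disjoint": "disjoint"}
        assert rel_ba == mirror[rel_ab]


class TestConservationCompare:
    def test_identical_groups_equal_means(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=[f"m{i}" for i in range(6)])
        counts = pd.Series([0, 0, 0, 1, 1, 1], index=scores.index)
        summary, pairwise = conservation_compare(scores, counts)
        assert summary["mean"].iloc[0] == summary["mean"].iloc[1]
        assert pairwise["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_match_exact_permutation_p(self):
        scores = pd.Series([1, 2, 3, 101, 102, 103], dtype=float,
                           index=[f"m{i}" for i in range(6)])
        counts = pd.Series([1, 1, 1, 2, 2, 2], index=scores.index)
        summary, pairwise = conservation_compare(scores, counts)
        assert summary.set_index("group").loc[1, "mean"] == 2.0
        assert summary.set_index("group").loc[2, "mean"] == 102.0
        # exhaustive rank-permutation oracle for complete separation, n=3 vs 3
        pool = [1, 2, 3, 101, 102, 103]
        u_obs = 0  # no (a, b) pair with a > b across groups
        count_le = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pool[i] for i in combo]
            b = [pool[i] for i in range(6) if i not in combo]
            u = sum(x > y for x in a for y in b)
            total += 1
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count_le += 1
        oracle = count_le / total
        assert pairwise["p_value"].iloc[0] == pytest.approx(oracle)

    def test_sem_textbook_formula(self):
        scores = pd.Series([2.0, 4.0, 6.0, 0.0], index=list("abcd"))
        counts = pd.Series([1, 1, 1, 0], index=list("abcd"))
        summary, _ = conservation_compare(scores, counts)
        row = summary.set_index("group").loc[1]
        assert row["sem"] == pytest.approx(np.std([2, 4, 6], ddof=1) / np.sqrt(3))

    def test_singleton_group_sem_flagged_nan(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        counts = pd.Series([0, 0, 1], index=list("abc"))
        summary, _ = conservation_compare(scores, counts)
        assert np.isnan(summary.set_index("group").loc[1, "sem"])


class TestChromosomeLoss:
    def test_zero_sectored_rate_zero(self):
        assert chromosome_loss_rate(0, 200) == 0.0

    def test_direct_ratio(self):
        assert chromosome_loss_rate(5, 500) == pytest.approx(0.01)

    def test_total_zero_errors(self):
        with pytest.raises(PhenotypeError):
            chromosome_loss_rate(0, 0)

    def test_binomial_sampling_recovers_rate(self, rng):
        r, n = 0.013, 10_000
        est = chromosome_loss_rate(int(rng.binomial(n, r)), n)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(est - r) <= 3 * se

    @pytest.mark.parametrize("fold,expected", [(4.5, True), (4.0, False), (1.0, False)])
    def test_fourfold_rule_is_strict(self, fold, expected):
        unstable, got_fold = call_unstable(fold * 0.001, 0.001)
        assert got_fold == pytest.approx(fold)
        assert unstable is expected

    def test_monotone_in_mutant_rate(self):
        rates = np.linspace(0, 0.02, 50)
        calls = [call_unstable(r, 0.001)[0] for r in rates]
        assert calls == sorted(calls)  # False...False True...True

    def test_table_analysis_flags_wt_relative_folds(self):
        table = pd.DataFrame(
            {
                "strain_id": ["WT", "mutA", "mutB"],
                "total_colonies": [1000, 1000, 1000],
                "half_sectored": [2, 10, 8],
            }
        )
        out = analyze_chromosome_loss(table).set_index("strain_id")
        assert bool(out.loc["mutA", "unstable"]) is True   # fold 5
        assert bool(out.loc["mutB", "unstable"]) is False  # fold 4 exactly

    def test_missing_wt_errors(self):
        table = pd.DataFrame({"strain_id": ["a"], "total_colonies": [10],
                              "half_sectored": [1]})
        with pytest.raises(PhenotypeError, match="WT"):
            analyze_chromosome_loss(table)


class TestSilencing:
    def test_score_equal_wt_is_wt(self):
        assert call_silencing(2.0, 2.0, "telomere") == "WT"

    def test_telomere_derepression_is_lts(self):
        assert call_silencing(4.0, 2.0, "telomere", delta_cut=1.0) == "LTS"

    def test_telomere_hyper_silencing_is_its(self):
        assert call_silencing(0.0, 2.0, "telomere", delta_cut=1.0) == "ITS"

    def test_rdna_derepression_is_lrs_and_never_its(self):
        assert call_silencing(4.0, 2.0, "rdna", delta_cut=1.0) == "LRS"
        assert call_silencing(0.0, 2.0, "rdna", delta_cut=1.0) == "WT"

    def test_unknown_locus_errors(self):
        with pytest.raises(PhenotypeError):
            call_silencing(1.0, 1.0, "centromere")

    def test_table_analysis(self):
        table = pd.DataFrame(
            {
                "mutant_id": ["WT", "m1", "m2", "WT", "m1"],
                "locus": ["telomere", "telomere", "telomere", "rdna", "rdna"],
                "score": [2.0, 5.0, -1.0, 1.0, 3.0],
            }
        )
        out = analyze_silencing(table).set_index("mutant_id")
        assert out.loc["m1", "telomere"] == "LTS"
        assert out.loc["m2", "telomere"] == "ITS"
        assert out.loc["m1", "rdna"] == "LRS"

    def test_missing_wt_reference_errors(self):
        table = pd.DataFrame({"mutant_id": ["m1"], "locus": ["telomere"],
                              "score": [1.0]})
        with pytest.raises(PhenotypeError, match="WT"):
            analyze_silencing(table)
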