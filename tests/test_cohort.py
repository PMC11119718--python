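"""Count matrices, group-comparison cascade, morphotype tests, survey."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sig70arch.cohort import (
    CountMatrix,
    accessory_survey,
    bin_for_heatmap,
    build_count_matrix,
    compare_two_groups,
    counts_vs_genome_size,
    family_morphotype_tests,
    merge_small_orders,
    stars_for_p,
)


def genomes_frame(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "order", "morphotype", "cds_count"]
    )


def units_frame(pairs):
    return pd.DataFrame(
        [{"genome_id": g, "family": f} for g, f in pairs]
    )


class TestCountMatrix:
    def test_row_margin_is_homolog_total(self):
        units = units_frame([("G1", "A.1")] * 3 + [("G1", "F.1")])
        genomes = genomes_frame([("G1", "Nostocales", "H", 5000)])
        m = build_count_matrix(units, genomes)
        assert m.row_totals["G1"] == 4
        assert m.counts.loc["G1", "A.1"] == 3

    def test_genome_without_units_gets_zero_row(self):
        units = units_frame([("G1", "A.1")])
        genomes = genomes_frame(
            [("G1", "Nostocales", "H", 5000), ("G2", "Chroococcales", "U", 3000)]
        )
        m = build_count_matrix(units, genomes)
        assert m.row_totals["G2"] == 0
        assert (m.counts.loc["G2"] == 0).all()

    def test_orphan_genome_errors_with_offenders(self):
        units = units_frame([("GX", "A.1")])
        genomes = genomes_frame([("G1", "Nostocales", "H", 5000)])
        with pytest.raises(ValueError, match="GX"):
            build_count_matrix(units, genomes)

    def test_margins_equal_brute_force_recount(self):
        rng = np.random.default_rng(5)
        fams = ["A.1", "C.1", "F.1", "K.3"]
        gids = [f"G{i}" for i in range(12)]
        pairs = [
            (str(rng.choice(gids)), str(rng.choice(fams))) for _ in range(200)
        ]
        m = build_count_matrix(
            units_frame(pairs),
            genomes_frame([(g, "Nostocales", "H", 4000) for g in gids]),
        )
        for g in gids:
            assert m.row_totals[g] == sum(1 for gg, _ in pairs if gg == g)
        for f in fams:
            assert m.col_totals[f] == sum(1 for _, ff in pairs if ff == f)
        assert m.total == 200


class TestHeatmapBinning:
    def test_bins_follow_the_scale(self):
        m = CountMatrix(pd.DataFrame({"A.1": [0, 2, 7]}, index=["a", "b", "c"]))
        assert list(bin_for_heatmap(m)["A.1"]) == [0, 2, 3]

    def test_identity_below_three_and_idempotent(self):
        m = CountMatrix(pd.DataFrame({"A.1": [0, 1, 2]}, index=["a", "b", "c"]))
        binned = bin_for_heatmap(m)
        pd.testing.assert_frame_equal(binned, m.counts)
        pd.testing.assert_frame_equal(bin_for_heatmap(CountMatrix(binned)), binned)


class TestMergeSmallOrders:
    def test_boundary_at_min_n(self):
        rows = [(f"G{i}", "Tiny", "U", 3000) for i in range(9)]
        rows += [(f"H{i}", "Big", "U", 3000) for i in range(10)]
        merged = merge_small_orders(genomes_frame(rows), min_n=10)
        assert set(merged.loc[merged["genome_id"].str.startswith("G"), "order"]) == {"Others"}
        assert set(merged.loc[merged["genome_id"].str.startswith("H"), "order"]) == {"Big"}

    def test_empty_cohort(self):
        assert merge_small_orders(genomes_frame([])).empty


def wilcoxon_oracle(a, b):
    """Exhaustive rank enumeration: brute-force U and exact two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    comb = np.concatenate([a, b])
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    us = []
    idxs = range(len(comb))
    for grp in itertools.combinations(idxs, len(a)):
        rest = [i for i in idxs if i not in grp]
        us.append(
            sum((comb[i] > comb[j]) + 0.5 * (comb[i] == comb[j])
                for i in grp for j in rest)
        )
    us = np.array(us)
    p = 2 * min((us >= u_obs).mean(), (us <= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestCompareTwoGroups:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_two_groups(vals, vals)
        assert res.p_value > 0.9
        assert res.stars == ""

    def test_separated_normal_samples_take_t_branch(self):
        rng = np.random.default_rng(30)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        res = compare_two_groups(a, b)
        assert res.test_name == "t-test"
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_non_normal_data_takes_wilcoxon_branch(self):
        rng = np.random.default_rng(31)
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3
        res = compare_two_groups(a, b)
        assert res.test_name == "wilcoxon"

    def test_branch_is_pure_function_of_shapiro_p(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            a = rng.normal(size=12) if rng.random() < 0.5 else rng.exponential(size=12) ** 2
            b = rng.normal(size=12)
            res = compare_two_groups(a, b)
            expected = "t-test" if min(res.shapiro_p) > 0.05 else "wilcoxon"
            assert res.test_name == expected

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(33)
        for _ in range(40):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 9 - n1))
            a = rng.normal(size=n1)  # continuous: tie-free
            b = rng.normal(size=n2)
            u, p = wilcoxon_oracle(a, b)
            res = compare_two_groups(a, b)
            if res.test_name != "wilcoxon":
                continue
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p)

    def test_group_too_small_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_constant_groups_degenerate_to_null(self):
        res = compare_two_groups([2.0] * 5, [2.0] * 5)
        assert res.p_value == 1.0 and res.stars == ""

    def test_star_thresholds(self):
        assert stars_for_p(0.04) == "*"
        assert stars_for_p(0.009) == "**"
        assert stars_for_p(0.0009) == "***"
        assert stars_for_p(0.06) == ""


def _cohort_counts(rng, n_u, n_h, mean_u, mean_h, family="A.5"):
    rows, units = [], []
    for i in range(n_u + n_h):
        morph = "U" if i < n_u else "H"
        g = f"G{i:03d}"
        rows.append((g, "Synechococcales" if morph == "U" else "Nostocales", morph, 3000))
        lam = mean_u if morph == "U" else mean_h
        for _ in range(rng.poisson(lam)):
            units.append((g, family))
        units.append((g, "A.1"))  # anchor family present everywhere
    return units_frame(units), genomes_frame(rows)


class TestFamilyMorphotypeTests:
    def test_planted_h_enrichment_detected_with_direction(self):
        rng = np.random.default_rng(40)
        units, genomes = _cohort_counts(rng, 60, 60, mean_u=0.3, mean_h=1.5)
        m = build_count_matrix(units, genomes)
        report = family_morphotype_tests(m, genomes)
        row = report.h_vs_rest.set_index("family").loc["A.5"]
        assert row["stars"] != ""
        assert row["direction"] == "H>rest"
        pair = report.pairwise.query("family == 'A.5'")
        assert (pair["stars"] != "").any()

    def test_null_cohort_mostly_unstarred(self):
        rng = np.random.default_rng(41)
        units, genomes = _cohort_counts(rng, 50, 50, mean_u=1.0, mean_h=1.0)
        m = build_count_matrix(units, genomes)
        report = family_morphotype_tests(m, genomes)
        # identical distributions: no systematic enrichment direction expected;
        # allow the occasional alpha-level false positive
        assert (report.pairwise["stars"] == "").mean() >= 0.5

    def test_single_morphotype_degrades_with_warning(self):
        units = units_frame([("G1", "A.1"), ("G2", "A.1"), ("G3", "A.1")])
        genomes = genomes_frame([(f"G{i}", "Nostocales", "H", 5000) for i in (1, 2, 3)])
        m = build_count_matrix(units, genomes)
        report = family_morphotype_tests(m, genomes)
        assert report.pairwise.empty
        assert report.warnings

    def test_bh_column_present(self):
        rng = np.random.default_rng(42)
        units, genomes = _cohort_counts(rng, 30, 30, mean_u=0.5, mean_h=0.5)
        m = build_count_matrix(units, genomes)
        report = family_morphotype_tests(m, genomes)
        assert "p_bh" in report.pairwise.columns
        assert (report.pairwise["p_bh"] >= report.pairwise["p_value"] - 1e-12).all()


class TestCountsVsGenomeSize:
    def test_proportional_counts_give_perfect_rank_correlation(self):
        genomes = genomes_frame(
            [(f"G{i}", "Nostocales", "H", 2000 + 500 * i) for i in range(8)]
        )
        units = units_frame(
            [(f"G{i}", "A.1") for i in range(8) for _ in range(i + 1)]
        )
        m = build_count_matrix(units, genomes)
        corr = counts_vs_genome_size(m, genomes)
        assert corr.rho == pytest.approx(1.0)

    def test_independent_counts_give_near_zero_correlation(self):
        rng = np.random.default_rng(50)
        genomes = genomes_frame(
            [(f"G{i}", "Nostocales", "H", int(rng.integers(2000, 8000)))
             for i in range(200)]
        )
        units = units_frame(
            [(f"G{i}", "A.1") for i in range(200) for _ in range(rng.poisson(5))]
        )
        m = build_count_matrix(units, genomes)
        corr = counts_vs_genome_size(m, genomes)
        assert abs(corr.rho) < 0.15

    def test_tiny_cohort_flagged_low_n(self):
        genomes = genomes_frame([(f"G{i}", "Nostocales", "H", 3000 + i) for i in range(3)])
        units = units_frame([("G0", "A.1")])
        corr = counts_vs_genome_size(build_count_matrix(units, genomes), genomes)
        assert corr.low_n and np.isfinite(corr.rho)


def proteins_frame(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "protein_id", "architecture_string", "family"]
    )


class TestAccessorySurvey:
    def _genomes(self, clade_sizes):
        rows = []
        i = 0
        for clade, n in clade_sizes.items():
            for _ in range(n):
                rows.append(
                    {"genome_id": f"G{i:03d}", "order": "o", "morphotype": "U",
                     "cds_count": 3000, "clade": clade}
                )
                i += 1
        return pd.DataFrame(rows)

    def test_planted_f3_composition(self):
        genomes = self._genomes({"Actinobacteria": 20})
        rows = [
            (f"G{i:03d}", f"G{i:03d}_P1", "r2*r4_2*DUF6596", "F.3") for i in range(10)
        ]
        survey = accessory_survey(proteins_frame(rows), genomes)
        row = survey.per_clade.set_index("clade").loc["Actinobacteria"]
        assert row["pct_genomes_with_domain"] == pytest.approx(50.0)
        assert row["pct_in_sigma70"] == pytest.approx(100.0)
        bd = survey.breakdown.query("clade == 'Actinobacteria'")
        assert list(bd["family"]) == ["F.3"] and bd["pct"].iloc[0] == pytest.approx(100.0)

    def test_clade_without_domain(self):
        genomes = self._genomes({"Firmicutes": 20})
        rows = [("G000", "G000_P1", "r1_2*r2*r3*r4", "A.1")]
        survey = accessory_survey(proteins_frame(rows), genomes)
        row = survey.per_clade.set_index("clade").loc["Firmicutes"]
        assert row["pct_genomes_with_domain"] == 0.0
        assert row["n_domain_proteins"] == 0

    def test_accessory_only_protein_counted_as_ud(self):
        genomes = self._genomes({"Actinobacteria": 20})
        rows = [("G000", "G000_P1", "DUF6596", None)]
        survey = accessory_survey(proteins_frame(rows), genomes)
        row = survey.per_clade.set_index("clade").loc["Actinobacteria"]
        assert row["pct_in_sigma70"] == 0.0
        bd = survey.breakdown.query("clade == 'Actinobacteria'")
        assert list(bd["family"]) == ["Ud"]

    def test_small_clades_merged_into_catch_all(self):
        genomes = self._genomes({"Actinobacteria": 20, "Rare1": 5, "Rare2": 4})
        survey = accessory_survey(proteins_frame([]), genomes, min_clade_size=15)
        clades = set(survey.per_clade["clade"])
        assert clades == {"Actinobacteria", "Other Bacteria"}
        merged = survey.per_clade.set_index("clade").loc["Other Bacteria"]
        assert merged["n_genomes"] == 9
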