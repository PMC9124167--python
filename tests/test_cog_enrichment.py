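"""Annotation parsing, the 2x26 chi-squared test and the 5% indicator rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonclust import cog_enrichment as ce


def brute_force_chi2(table):
    """Expected counts and Pearson statistic written out longhand."""
    table = np.asarray(table, dtype=float)
    grand = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / grand
            stat += (table[i, j] - e) ** 2 / e
    return stat


def make_counts(small, large):
    cats = list(ce.COG_CATEGORIES)
    cs = ce.CategoryCounts("SMALL", dict(zip(cats, small)), int(sum(small)))
    clg = ce.CategoryCounts("LARGE", dict(zip(cats, large)), int(sum(large)))
    return cs, clg


class TestCategorySet:
    def test_twenty_six_letters_in_four_groups(self):
        sizes = [len(v) for v in ce.SUPER_CATEGORIES.values()]
        assert sizes == [5, 11, 8, 2]
        assert len(ce.COG_CATEGORIES) == 26
        assert set("JKLAB") <= set(ce.COG_CATEGORIES) and set("RS") <= set(ce.COG_CATEGORIES)


class TestReadAnnotation:
    def test_tsv_rows(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g7\tP\ng8\tKL\n")
        assert ce.read_cog_annotation(path, "tsv") == {"g7": ["P"], "g8": ["K", "L"]}

    def test_tsv_unknown_letter_raises(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\t!\n")
        with pytest.raises(ValueError, match="ann.tsv:1"):
            ce.read_cog_annotation(path, "tsv")

    def test_ptt_dialect(self, tmp_path):
        path = tmp_path / "genome.ptt"
        path.write_text(
            "Synthetic genome - 1..100000\n"
            "4 proteins\n"
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
            "190..255\t+\t21\t1001\tthrA\tg1\t-\tCOG0583K\tregulator\n"
            "300..500\t+\t66\t1002\t-\tg2\t-\tCOG1234KL\tthing\n"
            "600..700\t-\t33\t1003\t-\tg3\t-\t-\thypothetical\n"
            "800..900\t-\t33\t1004\t-\tg4\t-\tCOG0001P\ttransporter\n"
        )
        ann = ce.read_cog_annotation(path, "ptt")
        assert ann == {"g1": ["K"], "g2": ["K", "L"], "g4": ["P"]}

    def test_ptt_bad_letter_names_line(self, tmp_path):
        path = tmp_path / "genome.ptt"
        path.write_text(
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
            "1..9\t+\t2\t1\t-\tg1\t-\tCOG0001E9\tx\n"
        )
        with pytest.raises(ValueError, match="genome.ptt:2"):
            ce.read_cog_annotation(path, "ptt")

    def test_ptt_short_row_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "genome.ptt"
        path.write_text(
            "1..9\t+\t2\n"
            "10..19\t+\t2\t1\t-\tg1\t-\tCOG0001P\tx\n"
        )
        with caplog.at_level("WARNING"):
            ann = ce.read_cog_annotation(path, "ptt")
        assert ann == {"g1": ["P"]}
        assert "skipped 1" in caplog.text

    def test_synthetic_roundtrip(self, tmp_path, synthetic_genome):
        from codonclust.synthetic_data import write_genome

        paths = write_genome(synthetic_genome, tmp_path / "g")
        back = ce.read_cog_annotation(paths["annotation"], "tsv")
        assert back == synthetic_genome.annotation


class TestCountCategories:
    def test_small_counts_and_total(self):
        labels = {"a": "SMALL", "b": "SMALL", "c": "SMALL"}
        ann = {"a": ["P"], "b": ["P"], "c": ["J"]}
        cs, cl = ce.count_categories(labels, ann)
        assert cs.counts["P"] == 2 and cs.counts["J"] == 1 and cs.total == 3
        assert cl.total == 0

    @pytest.mark.parametrize(
        "policy,expected_k,expected_l,total",
        [("first_letter", 1, 0, 1), ("all_letters", 1, 1, 2)],
    )
    def test_multi_letter_policy(self, policy, expected_k, expected_l, total):
        cs, _ = ce.count_categories({"g": "SMALL"}, {"g": ["K", "L"]}, policy=policy)
        assert cs.counts["K"] == expected_k and cs.counts["L"] == expected_l
        assert cs.total == total

    def test_unannotated_genes_excluded(self):
        labels = {"a": "SMALL", "b": "LARGE"}
        cs, cl = ce.count_categories(labels, {"a": ["P"]})
        assert cs.total == 1 and cl.total == 0

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="clustered and COG-annotated"):
            ce.count_categories({"a": "SMALL"}, {"b": ["P"]})

    def test_counts_match_generator_ledger(self, synthetic_genome):
        truth = synthetic_genome.truth
        labels = {
            g: ("SMALL" if c == "small" else "LARGE")
            for g, c in zip(truth.gene_id, truth.component)
        }
        cs, cl = ce.count_categories(labels, synthetic_genome.annotation)
        expected_small = truth[(truth.component == "small") & (truth.letters != "")]
        assert cs.total == len(expected_small)
        for cat in ce.COG_CATEGORIES:
            assert cs.counts[cat] == (expected_small.letters == cat).sum()


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        counts = [10] * 26
        res = ce.chi_square_2xC(*make_counts(counts, counts))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 25

    def test_hand_computed_2x2(self):
        small = [10, 0] + [0] * 24
        large = [0, 10] + [0] * 24
        res = ce.chi_square_2xC(*make_counts(small, large))
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1
        assert len(res.dropped_categories) == 24

    def test_zero_columns_dropped_and_dof_reduced(self, rng):
        small = list(rng.integers(1, 30, size=20)) + [0] * 6
        large = list(rng.integers(1, 30, size=20)) + [0] * 6
        res = ce.chi_square_2xC(*make_counts(small, large))
        assert res.dof == 19
        assert len(res.dropped_categories) == 6

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            small = rng.integers(1, 50, size=26)
            large = rng.integers(1, 50, size=26)
            res = ce.chi_square_2xC(*make_counts(small, large))
            table = np.vstack([small, large])
            assert res.statistic == pytest.approx(brute_force_chi2(table), abs=1e-9)

    def test_invariant_under_column_permutation(self, rng):
        small = rng.integers(1, 50, size=26)
        large = rng.integers(1, 50, size=26)
        base = ce.chi_square_2xC(*make_counts(small, large))
        perm = rng.permutation(26)
        permuted = ce.chi_square_2xC(*make_counts(small[perm], large[perm]))
        assert base.statistic == pytest.approx(permuted.statistic, abs=1e-9)

    def test_fewer_than_two_columns_is_undefined(self):
        small = [5] + [0] * 25
        large = [7] + [0] * 25
        with pytest.raises(ValueError, match="test undefined"):
            ce.chi_square_2xC(*make_counts(small, large))


class TestProportionsAndIndicator:
    def test_simple_ratio(self):
        counts = ce.CategoryCounts("SMALL", {"P": 25}, 100)
        assert ce.category_proportions(counts, "P") == pytest.approx(0.25)
        assert ce.category_proportions(counts, "J") == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            ce.category_proportions(ce.CategoryCounts("SMALL", {}, 0), "P")

    def test_proportions_sum_to_one_under_first_letter(self, rng):
        labels = {f"g{i}": "SMALL" for i in range(200)}
        ann = {f"g{i}": [ce.COG_CATEGORIES[rng.integers(26)]] for i in range(200)}
        cs, _ = ce.count_categories(labels, ann)
        total = sum(ce.category_proportions(cs, c) for c in ce.COG_CATEGORIES)
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "fs,fl,mode,expected",
        [
            (0.10, 0.10, "relative", (0, 0)),  # exact equality
            (0.20, 0.10, "relative", (1, 0)),  # 0.10 > 0.05 * 0.10
            (0.100, 0.104, "relative", (0, 0)),  # 0.004 < 0.005
            (0.10, 0.20, "relative", (0, 1)),
            (0.20, 0.10, "absolute", (1, 0)),  # 0.10 > 0.05
            (0.14, 0.10, "absolute", (0, 0)),  # 0.04 < 0.05
            (0.0, 0.001, "relative", (0, 1)),  # any gap above a zero floor counts
        ],
    )
    def test_indicator_rule(self, fs, fl, mode, expected):
        assert ce.overrepresentation_indicator(fs, fl, threshold_mode=mode) == expected

    @given(
        fs=st.floats(0, 1, allow_nan=False),
        fl=st.floats(0, 1, allow_nan=False),
        mode=st.sampled_from(["relative", "absolute"]),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_indicator_antisymmetry_and_validity(self, fs, fl, mode):
        ind = ce.overrepresentation_indicator(fs, fl, threshold_mode=mode)
        swapped = ce.overrepresentation_indicator(fl, fs, threshold_mode=mode)
        assert ind in {(1, 0), (0, 1), (0, 0)}
        assert swapped == (ind[1], ind[0])
        if ind == (1, 0):
            assert fs > fl
        if ind == (0, 1):
            assert fl > fs


class TestEnrichmentReport:
    def test_report_on_ledger_labels_recovers_boosts(self, synthetic_genome):
        truth = synthetic_genome.truth
        labels = {
            g: ("SMALL" if c == "small" else "LARGE")
            for g, c in zip(truth.gene_id, truth.component)
        }
        rep = ce.enrichment_report(labels, synthetic_genome.annotation, genome_id="shared")
        assert set(rep.verdicts) == set(ce.COG_CATEGORIES)
        for cat, v in rep.verdicts.items():
            assert (v.indicator_small, v.indicator_large) in {(1, 0), (0, 1), (0, 0)}
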