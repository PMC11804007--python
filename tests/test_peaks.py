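"""Peak QC, consensus, Fisher tests and differential binding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from statewitch import (
    GenomicInterval,
    PeakSet,
    combine_marks,
    compare_annotation_distributions,
    consensus_peaks,
    differential_binding,
    fisher_exact_2x2,
    qc_filter,
    specific_and_common,
    track_correlation,
)
from statewitch.genome import annotate_regions


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: hypergeometric enumeration at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestQC:
    def test_below_threshold_excluded(self):
        ps = PeakSet("s", "GIC", "H3K4me3",
                     [iv(i * 10, i * 10 + 5) for i in range(4999)])
        kept, excl, log = qc_filter([ps])
        assert not kept and excl == [ps]
        assert log.iloc[0]["decision"] == "excluded"

    def test_boundary_kept(self):
        ps = PeakSet("s", "GIC", "H3K4me3",
                     [iv(i * 10, i * 10 + 5) for i in range(5000)])
        kept, excl, _ = qc_filter([ps])
        assert kept == [ps] and not excl

    def test_empty_set_excluded(self):
        kept, excl, _ = qc_filter([PeakSet("s", "GIC", "H3K4me3", [])])
        assert not kept and len(excl) == 1


class TestTrackCorrelation:
    def test_self_and_anticorrelated(self):
        x = np.arange(10.0)
        corr, _ = track_correlation([x, -x])
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_shuffled_track_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.random(400)
        tracks = [base + rng.normal(0, 0.01, 400) for _ in range(5)]
        shuffled = base.copy()
        rng.shuffle(shuffled)
        tracks.append(shuffled)
        _, outliers = track_correlation(tracks, marks=["m"] * 6)
        assert outliers == [5]

    def test_zero_variance_flagged_not_error(self):
        corr, outliers = track_correlation(
            [np.ones(10), np.arange(10.0)], marks=["m", "m"]
        )
        assert 0 in outliers
        assert np.isnan(corr[0, 1])


class TestConsensus:
    def test_identical_sets(self):
        a = PeakSet("a", "", "H3K27ac", [iv(0, 100), iv(300, 400)])
        b = PeakSet("b", "", "H3K27ac", [iv(0, 100), iv(300, 400)])
        cons = consensus_peaks([a, b], min_support=2)
        assert [(p.start, p.end) for p in cons.peaks] == [(0, 100),
                                                          (300, 400)]

    def test_partial_overlap_intersection(self):
        a = PeakSet("a", "", "m", [iv(0, 100)])
        b = PeakSet("b", "", "m", [iv(50, 150)])
        cons = consensus_peaks([a, b], min_support=2)
        assert [(p.start, p.end) for p in cons.peaks] == [(50, 100)]

    def test_min_support_one_is_union(self):
        a = PeakSet("a", "", "m", [iv(0, 100)])
        b = PeakSet("b", "", "m", [iv(50, 150), iv(500, 600)])
        cons = consensus_peaks([a, b], min_support=1)
        assert [(p.start, p.end) for p in cons.peaks] == [(0, 150),
                                                          (500, 600)]

    def test_mixed_marks_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks(
                [PeakSet("a", "", "m1", [iv(0, 10)]),
                 PeakSet("b", "", "m2", [iv(0, 10)])],
                min_support=1,
            )

    @given(st.integers(1, 4))
    def test_monotone_decreasing_in_support(self, k):
        sets = [
            PeakSet(f"s{i}", "", "m", [iv(i * 20, i * 20 + 100)])
            for i in range(4)
        ]
        cov_k = sum(p.length for p in consensus_peaks(sets, k).peaks)
        cov_k1 = sum(
            p.length for p in consensus_peaks(sets, min(k + 1, 4)).peaks
        )
        assert cov_k1 <= cov_k


class TestSpecificCommon:
    def test_constructed_50_25_25(self, genes):
        # GA promoter (TSS 2000), GB promoter (TSS 8999), GC promoter
        shared = [iv(1900, 2100)]
        gic = PeakSet("g", "GIC", "H3K4me3",
                      shared + [iv(8900, 9000)])
        insc = PeakSet("i", "iNSC", "H3K4me3",
                       shared + [iv(900, 1100, "chr2")])
        res = specific_and_common(gic, insc, genes)
        assert res["pct_common"] == pytest.approx(100 / 3)
        assert res["pct_gic_specific"] == pytest.approx(100 / 3)
        assert res["pct_insc_specific"] == pytest.approx(100 / 3)
        total = (res["pct_common"] + res["pct_gic_specific"]
                 + res["pct_insc_specific"])
        assert total == pytest.approx(100, abs=1e-6)

    def test_identical_sets_all_common(self, genes):
        ps = PeakSet("g", "", "H3K4me3", [iv(1900, 2100)])
        res = specific_and_common(ps, ps, genes)
        assert res["pct_common"] == 100.0

    def test_disjoint_zero_common(self, genes):
        gic = PeakSet("g", "", "H3K4me3", [iv(1900, 2100)])
        insc = PeakSet("i", "", "H3K4me3", [iv(8900, 9000)])
        res = specific_and_common(gic, insc, genes)
        assert res["pct_common"] == 0.0


class TestFisher:
    def test_modal_table_p_one(self):
        _, p = fisher_exact_2x2([[2, 2], [2, 2]])
        assert p == pytest.approx(1.0)

    def test_small_table_vs_enumeration(self):
        odds, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(fisher_enumeration(3, 1, 1, 3), rel=1e-9)
        assert odds == pytest.approx(9.0)

    def test_extreme_table_vs_enumeration(self):
        _, p = fisher_exact_2x2([[0, 5], [5, 0]])
        assert p == pytest.approx(fisher_enumeration(0, 5, 5, 0), rel=1e-9)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8),
            st.integers(0, 8), st.integers(0, 8),
        )
    )
    def test_random_tables_match_enumeration(self, tbl):
        a, b, c, d = tbl
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-7)


class TestCompareAnnotations:
    def test_identical_distributions_null(self, genes):
        calls = annotate_regions([iv(1900, 2100)] * 10, genes)
        df = compare_annotation_distributions(calls, calls)
        assert np.allclose(df["fold_change"], 1.0)
        assert np.allclose(df["p"], 1.0)

    def test_promoter_enrichment_fold_and_p(self, genes):
        prom, dist = iv(1900, 2100), iv(5100, 5150)
        gic = annotate_regions([prom] * 40 + [dist] * 60, genes,
                               promoter_window=3000)
        insc = annotate_regions([prom] * 20 + [dist] * 80, genes,
                                promoter_window=3000)
        df = compare_annotation_distributions(gic, insc)
        row = df[df["category"] == "promoter"].iloc[0]
        assert row["fold_change"] == pytest.approx(2.0)
        assert row["p"] == pytest.approx(
            fisher_enumeration(40, 60, 20, 80), rel=1e-7
        )

    def test_single_category(self, genes):
        calls = annotate_regions([iv(1900, 2100)] * 3, genes)
        df = compare_annotation_distributions(calls, calls)
        assert list(df["category"]) == ["promoter"]


class TestDifferentialBinding:
    @staticmethod
    def design(n_pairs):
        conds = ["GIC"] * n_pairs + ["iNSC"] * n_pairs
        pats = list(range(n_pairs)) * 2
        return conds, pats

    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(200, 5))
        X = np.hstack([base, base])
        conds, pats = self.design(5)
        df = differential_binding(X, conds, pats)
        assert (df["class"] == "shared").all()

    def test_planted_eightfold_sites_recovered(self):
        rng = np.random.default_rng(2)
        n_sites, n_pairs, n_planted = 300, 10, 20
        lam = np.full((n_sites, n_pairs * 2), 40.0)
        lam[:n_planted, :n_pairs] *= 8  # enriched in GIC
        X = rng.poisson(lam)
        conds, pats = self.design(n_pairs)
        df = differential_binding(X, conds, pats)
        called = set(df.index[df["class"] == "gic_only"])
        assert len(called & set(range(n_planted))) >= int(0.9 * n_planted)
        assert len(called - set(range(n_planted))) <= 3

    def test_single_pair_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="pairs"):
            differential_binding(X, ["GIC", "iNSC"], [0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            differential_binding(
                np.array([[1, -2, 3, 4]]), ["GIC", "GIC", "iNSC", "iNSC"],
                [0, 1, 0, 1],
            )


class TestCombineMarks:
    def test_and_not_is_set_difference(self):
        sets = {
            "H3K27ac": PeakSet("s", "", "H3K27ac", [iv(0, 1000)]),
            "H3K4me3": PeakSet("s", "", "H3K4me3", [iv(200, 400),
                                                    iv(600, 700)]),
        }
        out = combine_marks(sets, "H3K27ac AND NOT H3K4me3")
        assert [(p.start, p.end) for p in out.peaks] == [
            (0, 200), (400, 600), (700, 1000)
        ]

    def test_idempotence(self):
        sets = {"m1": PeakSet("s", "", "m1", [iv(10, 50), iv(80, 120)])}
        out = combine_marks(sets, "m1 AND m1")
        assert [(p.start, p.end) for p in out.peaks] == [(10, 50),
                                                         (80, 120)]

    def test_contradiction_is_empty(self):
        sets = {"m1": PeakSet("s", "", "m1", [iv(10, 50)])}
        assert combine_marks(sets, "m1 AND NOT m1").peaks == []

    def test_or_with_parentheses(self):
        sets = {
            "a": PeakSet("s", "", "a", [iv(0, 100)]),
            "b": PeakSet("s", "", "b", [iv(200, 300)]),
            "c": PeakSet("s", "", "c", [iv(50, 250)]),
        }
        out = combine_marks(sets, "(a OR b) AND c")
        assert [(p.start, p.end) for p in out.peaks] == [(50, 100),
                                                         (200, 250)]

    def test_unknown_mark_rejected(self):
        sets = {"m1": PeakSet("s", "", "m1", [iv(0, 10)])}
        with pytest.raises(ValueError, match="unknown mark"):
            combine_marks(sets, "m1 AND m2")
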