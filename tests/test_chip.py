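import numpy as np
import pandas as pd
import pytest

from groseqtk.chip import (
    Peak,
    PeakSet,
    associate_to_genes,
    call_peaks,
    categorize_genomic,
    cluster_matrix,
    cooccurrence,
    replicate_consensus,
    timepoint_venn,
)
from groseqtk.coverage import StrandedCoverage

from conftest import genes_frame
from oracles import brute_force_cooccurrence, brute_force_venn


def unstranded(bins, bin_width=50, chrom="chr1", extra_chrom=None):
    chroms = {}
    arr = np.asarray(bins, dtype=np.int64)
    chroms[chrom] = (arr, arr)
    if extra_chrom is not None:
        filler = np.asarray(extra_chrom, dtype=np.int64)
        chroms["chrZ"] = (filler, filler)
    return StrandedCoverage(chroms=chroms, bin_width=bin_width, stranded=False)


def peakset(intervals, factor="AR", condition="t2") -> PeakSet:
    peaks = [
        Peak(chrom=c, start=s, end=e, summit=(s + e) // 2, norm_tags=100.0,
             fold_over_control=8.0)
        for c, s, e in intervals
    ]
    return PeakSet(factor=factor, condition=condition, peaks=peaks)


def random_intervals(rng, n, chrom="chr1", span=100_000, width=(100, 2000)):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append((chrom, s, s + int(rng.integers(*width))))
    return sorted(set(out))


class TestCallPeaks:
    def exact_coverage(self, treat_site, ctrl_site):
        """Arrays whose totals are exactly 1e7 so scaling is the identity."""
        n = 2000
        t = np.zeros(n, dtype=np.int64)
        c = np.zeros(n, dtype=np.int64)
        t[100] = treat_site
        c[100] = ctrl_site
        t_fill = np.full(n, (10_000_000 - treat_site) // n, dtype=np.int64)
        t_fill[0] += 10_000_000 - treat_site - t_fill.sum()
        c_fill = np.full(n, (10_000_000 - ctrl_site) // n, dtype=np.int64)
        c_fill[0] += 10_000_000 - ctrl_site - c_fill.sum()
        return (
            unstranded(t, extra_chrom=t_fill),
            unstranded(c, extra_chrom=c_fill),
        )

    def test_flat_equal_signals_yield_no_peaks(self):
        cov = unstranded(np.full(1000, 5))
        assert len(call_peaks(cov, cov)) == 0

    def test_single_window_gate_arithmetic(self):
        treat, ctrl = self.exact_coverage(40, 0)
        ps = call_peaks(treat, ctrl)
        chr1 = [p for p in ps.peaks if p.chrom == "chr1"]
        assert len(chr1) == 1
        assert chr1[0].norm_tags == pytest.approx(40.0)

    def test_exact_fourfold_and_exact_ten_tags_retained(self):
        # control 2 (+0.5/window) -> threshold 10; treatment exactly 10
        treat, ctrl = self.exact_coverage(10, 2)
        chr1 = [p for p in call_peaks(treat, ctrl).peaks if p.chrom == "chr1"]
        assert len(chr1) == 1
        assert chr1[0].norm_tags == pytest.approx(10.0)
        # one tag below either gate drops the peak
        treat, ctrl = self.exact_coverage(9, 2)
        assert not [p for p in call_peaks(treat, ctrl).peaks if p.chrom == "chr1"]

    def test_min_norm_tags_gate(self):
        treat, ctrl = self.exact_coverage(9, 0)
        assert not [p for p in call_peaks(treat, ctrl).peaks if p.chrom == "chr1"]

    def test_summit_at_max_bin(self):
        treat, ctrl = self.exact_coverage(40, 0)
        chr1 = [p for p in call_peaks(treat, ctrl).peaks if p.chrom == "chr1"]
        assert chr1[0].start <= 100 * 50 + 25 <= chr1[0].end
        assert chr1[0].summit == 100 * 50 + 25

    def test_fold_at_most_one_refused(self):
        cov = unstranded([1, 2, 3, 4])
        with pytest.raises(ValueError, match="fold"):
            call_peaks(cov, cov, fold=1.0)

    def test_grid_mismatch_rejected(self):
        a = unstranded(np.ones(100))
        b = unstranded(np.ones(200))
        with pytest.raises(ValueError, match="grids"):
            call_peaks(a, b)


class TestConsensus:
    def test_identical_sets_identical_spans(self):
        a = peakset([("chr1", 100, 300), ("chr1", 900, 1100)])
        out = replicate_consensus(a, peakset([("chr1", 100, 300), ("chr1", 900, 1100)]))
        assert [(p.start, p.end) for p in out.peaks] == [(100, 300), (900, 1100)]

    def test_disjoint_sets_empty(self):
        a = peakset([("chr1", 100, 300)])
        b = peakset([("chr1", 500, 700)])
        assert len(replicate_consensus(a, b)) == 0

    def test_partial_overlap_brute_force(self):
        rng = np.random.default_rng(11)
        a_iv = random_intervals(rng, 5, width=(200, 400))
        b_iv = random_intervals(rng, 5, width=(200, 400))
        out = replicate_consensus(peakset(a_iv), peakset(b_iv))
        expected = sum(
            any(s < be and e > bs for _, bs, be in b_iv) for _, s, e in a_iv
        )
        assert len(out) == expected

    def test_factor_mismatch_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus(peakset([("chr1", 0, 100)], factor="AR"),
                                peakset([("chr1", 0, 100)], factor="ERG"))


class TestCategorize:
    GENES = genes_frame(("g1", "chr1", 10_000, 30_000, "+"))

    def test_summit_near_tss_is_promoter(self):
        ps = peakset([("chr1", 10_100, 10_300)])  # summit 10200, TSS 10000
        out = categorize_genomic(ps, self.GENES)
        assert out.iloc[0]["category"] == "promoter"

    def test_mid_gene_summit_is_intragenic(self):
        ps = peakset([("chr1", 19_900, 20_100)])
        out = categorize_genomic(ps, self.GENES)
        assert out.iloc[0]["category"] == "intragenic"

    def test_distal_summit_is_intergenic(self):
        ps = peakset([("chr1", 50_000, 50_200)])
        out = categorize_genomic(ps, self.GENES)
        assert out.iloc[0]["category"] == "intergenic"

    def test_random_summits_match_brute_force(self):
        rng = np.random.default_rng(5)
        genes = genes_frame(
            ("g1", "chr1", 10_000, 30_000, "+"), ("g2", "chr1", 60_000, 90_000, "-")
        )
        intervals = [("chr1", s, s + 200) for s in rng.integers(0, 100_000, size=1000)]
        ps = peakset(sorted(set(intervals)))
        out = categorize_genomic(ps, genes)
        tss = {"g1": 10_000, "g2": 89_999}
        for row, p in zip(out.itertuples(index=False), ps.peaks):
            if any(abs(p.summit - t) <= 1000 for t in tss.values()):
                expected = "promoter"
            elif 10_000 <= p.summit < 30_000 or 60_000 <= p.summit < 90_000:
                expected = "intragenic"
            else:
                expected = "intergenic"
            assert row.category == expected


class TestVenn:
    def test_anchored_categories(self):
        a = peakset([("chr1", 100, 300), ("chr1", 5000, 5200)], condition="t0.5")
        b = peakset([("chr1", 150, 350)], condition="t2")
        c = peakset([("chr1", 120, 320)], condition="t4")
        out = timepoint_venn(a, b, c)
        cats = dict(zip(zip(out["start"], out["end"]), out["category"]))
        assert cats[(100, 350)] == 1  # merged region present in all three
        assert cats[(5000, 5200)] == 4  # 0.5 h only

    def test_sizes_match_brute_force_and_sum_to_universe(self):
        rng = np.random.default_rng(21)
        a = random_intervals(rng, 15)
        b = random_intervals(rng, 12)
        c = random_intervals(rng, 10)
        out = timepoint_venn(peakset(a), peakset(b), peakset(c))
        expected = brute_force_venn(a, b, c)
        got = out["category"].value_counts().to_dict()
        assert got == expected
        assert out["category"].size == sum(expected.values())


class TestAssociate:
    GENES = genes_frame(
        ("g_up", "chr1", 100_000, 120_000, "+"),
        ("g_down", "chr1", 300_000, 320_000, "+"),
        ("g_non", "chr1", 500_000, 520_000, "+"),
        ("g_far", "chr1", 900_000, 920_000, "+"),
    )
    DIFF = pd.DataFrame(
        {
            "feature_id": ["g_up", "g_down", "g_non", "g_far"],
            "class": ["up", "down", "non", "non"],
        }
    )

    def test_window_boundary_inclusive(self):
        # summits 49,999 and 50,001 bp from the g_up TSS at 100,000
        ps = peakset([("chr1", 49_901, 50_101), ("chr1", 49_899, 50_099)])
        out = associate_to_genes(ps, self.GENES, self.DIFF)
        table = out["table"].sort_values("summit").reset_index(drop=True)
        assert table.iloc[0]["gene_id"] is None  # 50,001 away
        assert table.iloc[1]["gene_id"] == "g_up"  # 49,999 away

    def test_nearest_tss_wins(self):
        # summit at 110,000: g_up TSS 10 kb away; place another gene 40 kb away
        genes = genes_frame(
            ("g_up", "chr1", 100_000, 120_000, "+"),
            ("g_other", "chr1", 150_000, 170_000, "+"),
        )
        diff = pd.DataFrame({"feature_id": ["g_up", "g_other"], "class": ["up", "non"]})
        ps = peakset([("chr1", 109_900, 110_100)])
        out = associate_to_genes(ps, genes, diff)
        assert out["table"].iloc[0]["gene_id"] == "g_up"

    def test_toy_fractions_brute_force(self):
        ps = peakset(
            [
                ("chr1", 99_900, 100_100),   # at g_up TSS
                ("chr1", 130_000, 130_200),  # 30 kb from g_up TSS
                ("chr1", 299_900, 300_100),  # at g_down
                ("chr1", 340_000, 340_200),  # 40 kb from g_down
                ("chr1", 499_900, 500_100),  # at g_non
                ("chr1", 700_000, 700_200),  # unassociated
                ("chr1", 705_000, 705_200),  # unassociated
                ("chr1", 930_000, 930_200),  # 30 kb from g_far (non)
            ]
        )
        out = associate_to_genes(ps, self.GENES, self.DIFF)
        assert out["fractions"]["up"] == pytest.approx(2 / 8)
        assert out["fractions"]["down"] == pytest.approx(2 / 8)
        assert out["fractions"]["non"] == pytest.approx(2 / 8)
        assert out["fractions"]["unassociated"] == pytest.approx(2 / 8)
        assert out["peaks_per_gene"]["g_up"] == 2

    def test_order_invariance(self):
        iv = [("chr1", 99_900, 100_100), ("chr1", 130_000, 130_200)]
        a = associate_to_genes(peakset(iv), self.GENES, self.DIFF)
        b = associate_to_genes(peakset(list(reversed(iv))), self.GENES, self.DIFF)
        assert a["fractions"] == b["fractions"]

    def test_incomplete_diff_table_rejected(self):
        with pytest.raises(ValueError, match="misses"):
            associate_to_genes(
                peakset([("chr1", 0, 100)]), self.GENES, self.DIFF.iloc[:2]
            )


class TestCooccurrence:
    def test_diagonal_and_identity(self):
        a = random_intervals(np.random.default_rng(1), 5)
        mat = cooccurrence({"a": pd.DataFrame(a, columns=["chrom", "start", "end"])})
        assert mat.loc["a", "a"] == 100.0

    def test_rule_arithmetic(self):
        small = [("chr1", 0, 100), ("chr1", 1000, 1100), ("chr1", 2000, 2100),
                 ("chr1", 3000, 3100)]
        big = [("chr1", 50, 150), ("chr1", 1050, 1150), ("chr1", 2050, 2150)]
        big += [("chr1", 10_000 + i * 1000, 10_100 + i * 1000) for i in range(7)]
        mat = cooccurrence(
            {
                "A": pd.DataFrame(small, columns=["chrom", "start", "end"]),
                "B": pd.DataFrame(big, columns=["chrom", "start", "end"]),
            }
        )
        assert mat.loc["A", "B"] == pytest.approx(75.0)  # 3 of 4 in the smaller set
        assert mat.loc["B", "A"] == pytest.approx(75.0)

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(33)
        sets = {
            f"s{i}": random_intervals(rng, int(rng.integers(3, 21)))
            for i in range(5)
        }
        frames = {
            k: pd.DataFrame(v, columns=["chrom", "start", "end"]) for k, v in sets.items()
        }
        mat = cooccurrence(frames)
        expected = brute_force_cooccurrence(sets)
        for a in sets:
            for b in sets:
                assert mat.loc[a, b] == pytest.approx(expected[(a, b)])
                assert mat.loc[a, b] == mat.loc[b, a]

    def test_empty_set_flagged_nan(self):
        mat = cooccurrence(
            {
                "a": pd.DataFrame([("chr1", 0, 10)], columns=["chrom", "start", "end"]),
                "empty": pd.DataFrame(columns=["chrom", "start", "end"]),
            }
        )
        assert np.isnan(mat.loc["empty", "a"])
        assert np.isnan(mat.loc["empty", "empty"])


class TestClusterMatrix:
    def block_matrix(self):
        labels = [f"x{i}" for i in range(6)]
        m = np.full((6, 6), 5.0)
        m[:3, :3] = 90.0
        m[3:, 3:] = 90.0
        np.fill_diagonal(m, 100.0)
        return pd.DataFrame(m, index=labels, columns=labels)

    def test_identical_rows_adjacent(self):
        m = self.block_matrix()
        out = cluster_matrix(m)
        order = out["order"]
        assert abs(order.index("x0") - order.index("x1")) <= 2  # same block

    def test_blocks_form_subtrees(self):
        out = cluster_matrix(self.block_matrix())
        order = out["order"]
        first_half = set(order[:3])
        assert first_half in ({"x0", "x1", "x2"}, {"x3", "x4", "x5"})
        assert out["newick"].endswith(";")

    def test_label_permutation_equivariance(self):
        m = self.block_matrix()
        perm = ["x3", "x0", "x4", "x1", "x5", "x2"]
        mp = m.loc[perm, perm]
        a = cluster_matrix(m)["order"]
        b = cluster_matrix(mp)["order"]
        # same block structure either way
        assert {frozenset(a[:3]), frozenset(a[3:])} == {frozenset(b[:3]), frozenset(b[3:])}

    def test_non_square_rejected(self):
        m = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError, match="square"):
            cluster_matrix(m)


class TestPeakSetInvariants:
    def test_sorted_and_deduplicated(self):
        with pytest.raises(ValueError, match="duplicated"):
            peakset([("chr1", 0, 100), ("chr1", 0, 100)])

    def test_sorting_applied(self):
        ps = peakset([("chr1", 500, 600), ("chr1", 0, 100)])
        assert [p.start for p in ps.peaks] == [0, 500]
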