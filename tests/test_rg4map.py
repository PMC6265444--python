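import numpy as np
import pandas as pd
import pytest

from rg4i import rg4map
from rg4i.formats import AlignmentRecord, TranscriptModel
from rg4i.iclae_proc import BindingRegion, Peak
from rg4i.rg4map import (
    classify_peaks,
    differential_binding,
    expressed_set,
    expression_binding_correlation,
    g4_fraction_and_test,
    has_g4,
    peak_overlap,
    scan_g4,
    select_targets,
    shuffle_enrichment,
    term_enrichment,
    two_proportion_test,
)

from oracles import g4_presence_bruteforce, hypergeom_right_tail, yates_chi2


def region(ref="tx1", ps=0, pe=40, start=0, end=100, g4=False):
    return BindingRegion(ref, ps, pe, start, end, "A" * (end - start), g4)


def tx(tid, gid=None, biotype="protein_coding", length=300, features=None):
    if features is None and biotype == "protein_coding":
        features = [
            ("five_prime_utr", 0, 60),
            ("cds", 60, 240),
            ("three_prime_utr", 240, length),
        ]
    return TranscriptModel(tid, gid or f"g_{tid}", biotype, features or [], length)


class TestScanG4:
    def test_canonical_motif(self):
        (m,) = scan_g4("GGAGGAGGAGG")
        assert (m.start, m.end) == (0, 11)

    def test_two_runs_no_match(self):
        assert scan_g4("GGAGG") == []

    def test_u_equivalent_to_t(self):
        assert has_g4("GGUGGUGGUGG")
        assert has_g4("GGTGGTGGTGG")

    def test_loops_may_contain_g(self):
        # 11 consecutive Gs decompose into 4 runs with G loops
        assert has_g4("G" * 11)
        # but 8 Gs cannot host 4 runs + 3 loops (minimum span is 11)
        assert not has_g4("G" * 8)

    def test_long_loop_rejected(self):
        assert not has_g4("GG" + "A" * 13 + "GGAGGAGG")
        assert has_g4("GG" + "A" * 12 + "GGAGGAGG")

    def test_empty_sequence(self):
        assert scan_g4("") == []

    def test_non_overlapping_left_to_right(self):
        seq = "GGAGGAGGAGG" + "T" * 20 + "GGAGGAGGAGG"
        matches = scan_g4(seq)
        assert len(matches) == 2
        assert matches[0].end <= matches[1].start

    def test_presence_agrees_with_enumerator_oracle(self):
        rng = np.random.default_rng(13)
        probs = np.array([0.18, 0.18, 0.46, 0.18])  # G-rich to exercise matches
        for _ in range(1500):
            seq = "".join(np.random.default_rng(rng.integers(1 << 30)).choice(
                list("ACGT"), size=120, p=probs))
            assert has_g4(seq) == g4_presence_bruteforce(seq), seq


class TestProportionTest:
    def test_equal_proportions_p_one(self):
        a = [region(g4=i < 50) for i in range(100)]
        b = [region(g4=i < 50) for i in range(100)]
        pa, pb, _, p = g4_fraction_and_test(a, b)
        assert pa == pb == 0.5
        assert p == pytest.approx(1.0)

    def test_agrees_with_yates_formula(self):
        stat, p = two_proportion_test(90, 100, 10, 100)
        o_stat, o_p = yates_chi2(90, 100, 10, 100)
        assert stat == pytest.approx(o_stat, rel=1e-9)
        assert p == pytest.approx(o_p, rel=1e-9)

    def test_extreme_contrast(self):
        stat, p = two_proportion_test(100, 100, 0, 100)
        o_stat, o_p = yates_chi2(100, 100, 0, 100)
        assert stat == pytest.approx(o_stat, rel=1e-9)
        assert p < 1e-20

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
                continue
            stat, p = two_proportion_test(k1, n1, k2, n2)
            o_stat, o_p = yates_chi2(k1, n1, k2, n2)
            assert stat == pytest.approx(o_stat, rel=1e-8, abs=1e-12)
            assert p == pytest.approx(o_p, rel=1e-8, abs=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            g4_fraction_and_test([], [region()])


class TestClassifyPeaks:
    ANN = [
        tx("tx1"),
        tx("tx2", biotype="pseudogene", features=[], length=200),
    ]

    def test_midpoint_in_5utr(self):
        cats, tallies = classify_peaks([Peak("tx1", 10, 50)], self.ANN)
        assert cats == ["five_prime_utr"]
        assert tallies["five_prime_utr"] == 1

    def test_unknown_reference_intergenic(self):
        cats, _ = classify_peaks([Peak("nowhere", 0, 40)], self.ANN)
        assert cats == ["intergenic"]

    def test_pseudogene_biotype(self):
        cats, _ = classify_peaks([Peak("tx2", 0, 40)], self.ANN)
        assert cats == ["pseudogene"]

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            classify_peaks([], [])


class TestExpressedSet:
    def test_boundary_at_least(self):
        df = pd.DataFrame(
            {"transcript_id": ["t1", "t1"], "condition": ["WT", "WT"],
             "fpkm": [0.1, 0.1]}
        )
        assert expressed_set(df) == {"t1"}

    def test_below_everywhere_dropped(self):
        df = pd.DataFrame(
            {"transcript_id": ["t1", "t1"], "condition": ["WT", "mut"],
             "fpkm": [0.09, 0.05]}
        )
        assert expressed_set(df) == set()

    def test_replicates_averaged(self):
        # mean(0.05, 0.25) = 0.15 >= 0.1 even though one replicate is below
        df = pd.DataFrame(
            {"transcript_id": ["t1", "t1"], "condition": ["WT", "WT"],
             "fpkm": [0.05, 0.25]}
        )
        assert expressed_set(df) == {"t1"}

    def test_empty_table(self):
        assert expressed_set(pd.DataFrame(columns=["transcript_id", "condition", "fpkm"])) == set()


class TestShuffleEnrichment:
    def _uniform_annotation(self, n=40, length=500):
        return [tx(f"tx{i}", length=length, features=[
            ("five_prime_utr", 0, 100), ("cds", 100, 400),
            ("three_prime_utr", 400, 500),
        ]) for i in range(n)]

    def test_deterministic_for_fixed_seed(self):
        ann = self._uniform_annotation()
        peaks = [Peak("tx0", 10, 60), Peak("tx1", 200, 260)]
        a = shuffle_enrichment(peaks, ann, n_shuffles=50, seed=5)
        b = shuffle_enrichment(peaks, ann, n_shuffles=50, seed=5)
        assert [(e.category, e.fold) for e in a] == [(e.category, e.fold) for e in b]

    def test_concentrated_placement_fold_matches_space_share(self):
        ann = self._uniform_annotation(n=30)
        width = 50
        peaks = [Peak(f"tx{i % 30}", 20, 20 + width) for i in range(60)]  # all 5'UTR
        enr = {e.category: e for e in shuffle_enrichment(peaks, ann, 1000, seed=1)}
        # analytic: enumerate every placement slot's midpoint category
        slots_5utr = sum(
            1 for s in range(500 - width + 1) if (2 * s + width) // 2 < 100
        )
        share = slots_5utr / (500 - width + 1)
        assert enr["five_prime_utr"].fold == pytest.approx(1 / share, rel=0.05)

    def test_oversized_peak_errors(self):
        ann = [tx(f"tx{i}", biotype="lncRNA", features=[], length=100) for i in range(2)]
        with pytest.raises(ValueError, match="wider"):
            shuffle_enrichment([Peak("tx0", 0, 400)], ann, n_shuffles=5, seed=0)


class TestPeakOverlap:
    def test_identical_lists_all_shared(self):
        a = [Peak("tx1", 0, 50), Peak("tx2", 10, 60)]
        b = [Peak("tx1", 0, 50), Peak("tx2", 10, 60)]
        wt_s, mut_s, wt_o, mut_o = peak_overlap(a, b)
        assert len(wt_s) == len(mut_s) == 2
        assert wt_o == mut_o == []

    def test_disjoint_lists_none_shared(self):
        a = [Peak("tx1", 0, 50)]
        b = [Peak("tx1", 100, 150)]
        wt_s, mut_s, wt_o, mut_o = peak_overlap(a, b)
        assert wt_s == mut_s == []
        assert len(wt_o) == len(mut_o) == 1

    def test_single_overlapping_pair(self):
        a = [Peak("tx1", 0, 50), Peak("tx1", 200, 250), Peak("tx2", 0, 50)]
        b = [Peak("tx1", 40, 90), Peak("tx3", 0, 50), Peak("tx1", 500, 550)]
        wt_s, mut_s, _, _ = peak_overlap(a, b)
        assert len(wt_s) == 1 and len(mut_s) == 1
        assert (wt_s[0].start, mut_s[0].start) == (0, 40)


class TestDifferentialBinding:
    def _alns(self, n, ref="tx1", start=100, sample="wt"):
        rec = AlignmentRecord(ref, start, start + 35, "+", 40, "AAAAA", sample)
        return [rec] * n

    def test_equal_cpm_null(self):
        peak = Peak("tx1", 90, 150)
        wt = self._alns(20) + self._alns(80, ref="tx2")
        mut = self._alns(20, sample="mut") + self._alns(80, ref="tx2", sample="mut")
        (rec,) = differential_binding([peak], wt, mut)
        assert rec.log2fc == pytest.approx(0.0)
        assert rec.pvalue > 0.9

    def test_closed_form_with_pseudocount(self):
        # wt_cpm = 8c = 4, mut_cpm = 0 -> log2((4 + 0.5) / 0.5) = log2(9)
        peak = Peak("tx1", 90, 150)
        wt = self._alns(2) + self._alns(499998, ref="tx2")
        mut = self._alns(100, ref="tx2", sample="mut")
        (rec,) = differential_binding([peak], wt, mut)
        assert rec.wt_cpm == pytest.approx(4.0)
        assert rec.mut_cpm == 0.0
        assert rec.log2fc == pytest.approx(np.log2(9))

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            differential_binding([Peak("tx1", 0, 50)], [], self._alns(5))


class TestSelectTargets:
    def _setup(self):
        ann = [tx(f"tx{i}", gid=f"gene{i}") for i in range(4)]
        peaks = [Peak(f"tx{i}", 50, 110, cpm=float(10 * (i + 1))) for i in range(4)]
        regions = [
            BindingRegion(f"tx{i}", 50, 110, 30, 130, "N" * 100, True)
            for i in range(4)
        ]
        return ann, peaks, regions

    def _rec(self, peak, wt_cpm, log2fc=2.0, p=0.01):
        return rg4map.DiffBindRecord(peak, 10, 1, wt_cpm, 1.0, log2fc, p)

    def test_failing_only_quartile_excluded(self):
        ann, peaks, regions = self._setup()
        diffbind = [self._rec(p, wt_cpm=float(10 * (i + 1))) for i, p in enumerate(peaks)]
        # 75th percentile of (10,20,30,40) = 32.5 -> only tx3 qualifies
        assert select_targets(diffbind, regions, ann) == ["gene3"]

    def test_g4_required(self):
        ann, peaks, regions = self._setup()
        for r in regions:
            r.g4 = False
        diffbind = [self._rec(p, wt_cpm=100.0) for p in peaks]
        assert select_targets(diffbind, regions, ann) == []

    def test_monotone_in_thresholds(self):
        ann, peaks, regions = self._setup()
        rng = np.random.default_rng(6)
        diffbind = [
            self._rec(
                p,
                wt_cpm=float(rng.uniform(0, 50)),
                log2fc=float(rng.uniform(-1, 3)),
                p=float(rng.uniform(0, 0.2)),
            )
            for p in peaks
        ]
        base = set(select_targets(diffbind, regions, ann))
        assert set(select_targets(diffbind, regions, ann, logfc_min=2.0)) <= base
        assert set(select_targets(diffbind, regions, ann, p_max=0.01)) <= base
        assert set(select_targets(diffbind, regions, ann, quantile=0.9)) <= base

    def test_empty_diffbind(self):
        assert select_targets([], [], []) == []


class TestTermEnrichment:
    def test_term_covering_everything_p_one(self):
        terms = pd.DataFrame(
            {"term_id": ["T1"] * 4, "term_name": ["all"] * 4,
             "gene_id": ["a", "b", "c", "d"]}
        )
        df = term_enrichment({"a", "b"}, {"a", "b", "c", "d"}, terms)
        assert df["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_five_of_five(self):
        terms = pd.DataFrame(
            {"term_id": ["T1"] * 5, "term_name": ["t"] * 5,
             "gene_id": [f"g{i}" for i in range(5)]}
        )
        background = {f"g{i}" for i in range(10)}
        fg = {f"g{i}" for i in range(5)}
        df = term_enrichment(fg, background, terms)
        assert df["pvalue"].iloc[0] == pytest.approx(1 / 252, rel=1e-9)
        assert df["pvalue"].iloc[0] == pytest.approx(
            hypergeom_right_tail(5, 10, 5, 5), rel=1e-9
        )

    def test_disjoint_foreground_p_one(self):
        terms = pd.DataFrame(
            {"term_id": ["T1"] * 2, "term_name": ["t"] * 2, "gene_id": ["x", "y"]}
        )
        df = term_enrichment({"a"}, {"a", "x", "y"}, terms)
        assert df["pvalue"].iloc[0] == pytest.approx(1.0)


class TestCorrelation:
    def test_identity_r_one(self):
        x = np.linspace(1, 100, 50)
        r, n = expression_binding_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert n == 50

    def test_independent_near_zero(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(1, 1, 10_000)
        y = rng.lognormal(1, 1, 10_000)
        r, _ = expression_binding_correlation(x, y)
        assert abs(r) < 0.05

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            expression_binding_correlation([1, 2, 3], [5, 5, 5])
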