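"""Upstream candidate generation, empirical FDR and call categorisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtss.annotation_io import (
    GenomeTable,
    GenomicInterval,
    TranscriptAnnotation,
    TssCall,
    parse_region,
)
from mirtss.tss_scan import (
    CandidateTss,
    NullScoreSet,
    bh_qvalues,
    call_tss,
    candidate_bins,
    categorize,
    distance_summaries,
    empirical_pvalues,
)


def _mirna(start, end, strand, chrom="chr1", mid="mir"):
    return TranscriptAnnotation(mid, GenomicInterval(chrom, start, end, strand), "miRNA")


class TestCandidateBins:
    def test_plus_strand_window_covers_ten_kb(self):
        anchors = candidate_bins(_mirna(20_000, 20_150, "+"))
        assert len(anchors) == 100
        starts = [a.position for a in anchors]
        assert starts[0] == 19_900 and starts[-1] == 10_000  # proximal -> distal
        assert min(starts) == 10_000 and max(starts) == 19_900

    def test_minus_strand_candidates_extend_to_higher_coordinates(self):
        mir = _mirna(3961347, 3961464, "-")
        anchors = candidate_bins(mir)
        assert all(a.position >= 3961400 for a in anchors)
        assert anchors[0].position < anchors[-1].position
        assert len(anchors) == 100

    def test_window_is_clipped_at_the_chromosome_start(self):
        anchors = candidate_bins(_mirna(350, 500, "+"))
        assert [a.position for a in anchors] == [300, 200, 100, 0]

    def test_window_is_clipped_at_the_chromosome_end(self):
        genome = GenomeTable({"chr1": 1000})
        anchors = candidate_bins(_mirna(400, 600, "-"), genome=genome)
        assert all(a.position < 1000 for a in anchors)
        assert len(anchors) == 4  # bins 600..900

    def test_unstranded_mirna_errors(self):
        with pytest.raises(ValueError):
            candidate_bins(_mirna(100, 200, "."))

    def test_mirroring_the_genome_mirrors_the_candidate_set(self):
        L = 100_000
        mir = _mirna(20_000, 20_150, "+")
        mirrored = _mirna(L - 20_150, L - 20_000, "-")
        fwd = [a.position for a in candidate_bins(mir)]
        rev = [a.position for a in candidate_bins(mirrored, genome=GenomeTable({"chr1": L}))]
        assert sorted(L - 100 - p for p in fwd) == sorted(rev)


class TestEmpiricalPvalues:
    def test_add_one_correction(self):
        null = NullScoreSet(np.arange(999, dtype=float))
        assert empirical_pvalues([2000.0], null)[0] == pytest.approx(1 / 1000)

    def test_score_below_all_nulls_gives_one(self):
        null = NullScoreSet(np.arange(10, dtype=float))
        assert empirical_pvalues([-5.0], null)[0] == pytest.approx(1.0)

    def test_tie_counts_as_greater_equal(self):
        null = NullScoreSet(np.array([0.5]))
        assert empirical_pvalues([0.5], null)[0] == pytest.approx(1.0)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            NullScoreSet(np.array([]))


class TestBhQvalues:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_step_up_examples(self, pvals, expected):
        np.testing.assert_allclose(bh_qvalues(pvals), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_qvalues([1.5])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_manual_step_up_formula(self, pvals):
        """q_(i) = min_{j>=i} m p_(j) / j, mapped back to input order."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_qvalues(p), expected, rtol=1e-10)


def _cand(mid, start, score, q, strand="+"):
    return CandidateTss(
        mirna_id=mid,
        bin=GenomicInterval("chr1", start, start + 100, strand),
        score=score,
        qvalue=q,
    )


class TestCallTss:
    def test_no_passing_candidate_returns_none(self):
        mir = _mirna(20_000, 20_150, "+")
        assert call_tss(mir, [_cand("mir", 19_900, 1.0, 0.5)], fdr=0.1) is None

    def test_single_passing_candidate_wins(self):
        mir = _mirna(20_000, 20_150, "+")
        call = call_tss(mir, [_cand("mir", 19_900, 1.0, 0.01)], fdr=0.1)
        assert call.tss.start == 19_900 and call.qvalue == 0.01

    def test_score_tie_breaks_to_most_proximal(self):
        mir = _mirna(20_000, 20_150, "+")
        proximal = _cand("mir", 19_700, 2.0, 0.01)
        distal = _cand("mir", 17_900, 2.0, 0.01)
        call = call_tss(mir, [proximal, distal], fdr=0.1)
        assert call.tss.start == 19_700


def _gene(gid, start, end, strand, exons=(), chrom="chr1"):
    return TranscriptAnnotation(
        gid,
        GenomicInterval(chrom, start, end, strand),
        "protein_coding",
        [GenomicInterval(chrom, a, b, strand) for a, b in exons],
    )


class TestCategorize:
    def test_call_near_upstream_gene_tss_is_shared(self):
        gene = _gene("g", 9_000, 12_000, "+")
        call = TssCall(
            mirna_id="m", mirna=GenomicInterval("chr1", 20_000, 20_150, "+"),
            category="uncategorized", tss=GenomicInterval("chr1", 8_990, 9_090, "+"),
        )
        out = categorize(call, [gene])  # midpoint 9040, gene TSS 9000 -> 40 bp
        assert out.category == "shared_upstream"
        assert out.distance_to_upstream_gene_tss == 40

    def test_call_two_kb_from_upstream_gene_is_independent(self):
        gene = _gene("g", 9_000, 12_000, "+")
        call = TssCall(
            mirna_id="m", mirna=GenomicInterval("chr1", 20_000, 20_150, "+"),
            category="uncategorized", tss=GenomicInterval("chr1", 11_000, 11_100, "+"),
        )
        assert categorize(call, [gene]).category == "independent"

    def test_mirna_inside_host_intron_is_flagged(self):
        host = _gene(
            "host", 9_000, 12_000, "+", exons=[(9_000, 9_300), (11_300, 12_000)]
        )
        call = TssCall(
            mirna_id="m", mirna=GenomicInterval("chr1", 9_500, 9_650, "+"),
            category="uncategorized", tss=GenomicInterval("chr1", 8_950, 9_050, "+"),
        )
        out = categorize(call, [host])
        assert out.intronic and out.category == "shared_upstream"

    def test_no_upstream_gene_defaults_to_independent(self):
        call = TssCall(
            mirna_id="m", mirna=GenomicInterval("chr1", 20_000, 20_150, "+"),
            category="uncategorized", tss=GenomicInterval("chr1", 18_000, 18_100, "+"),
        )
        out = categorize(call, [])
        assert out.category == "independent"
        assert out.distance_to_upstream_gene_tss is None


class TestPrintedDistances:
    """Gap values reproduce plain subtraction of the published boundary
    coordinates (verified rows of the packaged table)."""

    @pytest.mark.parametrize(
        "mirna_region, tss_span, expected_gap",
        [
            ("chr1:3961348-3961464(-)", (3961763, 3961863), 300),
            ("chr1:7058194-7058310(+)", (7055993, 7056093), 2100),
            ("chr3:8108072-8108209(+)", (8107971, 8108071), 0),
        ],
    )
    def test_gap_matches_printed_subtraction(self, mirna_region, tss_span, expected_gap):
        mirna = parse_region(mirna_region)
        call = TssCall(
            mirna_id="m", mirna=mirna, category="uncategorized",
            tss=GenomicInterval(mirna.chrom, tss_span[0], tss_span[1], mirna.strand),
        )
        assert categorize(call, []).distance_to_mirna == expected_gap


class TestDistanceSummaries:
    def test_upstream_distances_and_histogram(self):
        genes = [_gene("g1", 9_000, 12_000, "+"), _gene("g2", 30_000, 33_000, "+")]
        mirnas = [
            _mirna(10_500, 10_650, "+", mid="near"),   # 1500 bp from g1 TSS
            _mirna(36_200, 36_350, "+", mid="far"),    # 6200 bp from g2 TSS
            _mirna(500, 650, "+", mid="orphan"),       # nothing upstream
        ]
        out = distance_summaries(mirnas, genes)
        d = out["mirna_upstream_distances"]
        assert d["near"] == 1500 and d["far"] == 6200
        assert "orphan" not in d.index
        hist = out["mirna_upstream_hist"]
        assert hist["[1000,2000)"] == 1 and hist["[6000,7000)"] == 1

    def test_independent_call_gaps_are_collected(self):
        genes = [_gene("g1", 9_000, 12_000, "+")]
        mirnas = [_mirna(20_000, 20_150, "+", mid="m1")]
        call = TssCall(
            mirna_id="m1", mirna=mirnas[0].interval, category="uncategorized",
            tss=GenomicInterval("chr1", 19_600, 19_700, "+"),
        )
        call = categorize(call, genes)
        out = distance_summaries(mirnas, genes, [call])
        assert out["independent_gap_distances"]["m1"] == 300


class TestScanProperties:
    def test_lowering_fdr_never_adds_calls(self, tiny_sim, tiny_results):
        called = {}
        for fdr in (0.02, 0.1, 0.3):
            scan = tiny_results.scan(tiny_sim.mirnas, fdr=fdr, n_decoys=2000)
            called[fdr] = {c.mirna_id for c in scan.calls if c.tss is not None}
        assert called[0.02] <= called[0.1] <= called[0.3]

    def test_called_bins_have_bin_width_and_valid_qvalues(self, tiny_sim, tiny_results):
        scan = tiny_results.scan(tiny_sim.mirnas, n_decoys=2000)
        for c in scan.calls:
            if c.tss is not None:
                assert c.tss.width == tiny_sim.config.bin_size
                assert 0 < c.qvalue <= 1
        assert scan.null.n == 2000
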