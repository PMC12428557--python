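import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicedown.events import (
    COORD_COLUMNS, PsiUndefinedError, SpliceEvent, call_dases_from_counts,
    compute_psi, dase_region, filter_dases, mean_event_coverage,
    read_rmats_events,
)
from splicedown.intervals import (
    GenomicInterval, GenomeSource, extract_sequence, reverse_complement,
)
from oracles import oracle_bh


def make_event(event_class="SE", coords=None, inc_t=(10, 10), skp_t=(10, 10),
               inc_c=(10, 10), skp_c=(10, 10), strand="+", delta_psi=0.2,
               fdr=0.01, **kw):
    defaults = {
        "SE": {"exonStart_0base": 300, "exonEnd": 400, "upstreamES": 100,
               "upstreamEE": 200, "downstreamES": 500, "downstreamEE": 600},
        "MXE": {"1stExonStart_0base": 300, "1stExonEnd": 400,
                "2ndExonStart_0base": 500, "2ndExonEnd": 600,
                "upstreamES": 100, "upstreamEE": 200,
                "downstreamES": 700, "downstreamEE": 800},
        "RI": {"riExonStart_0base": 100, "riExonEnd": 600, "upstreamES": 100,
               "upstreamEE": 200, "downstreamES": 500, "downstreamEE": 600},
        "A3SS": {"longExonStart_0base": 100, "longExonEnd": 300,
                 "shortES": 250, "shortEE": 300,
                 "flankingES": 10, "flankingEE": 50},
        "A5SS": {"longExonStart_0base": 100, "longExonEnd": 300,
                 "shortES": 100, "shortEE": 220,
                 "flankingES": 400, "flankingEE": 500},
    }
    return SpliceEvent(
        event_id=kw.get("event_id", "ev1"), event_class=event_class,
        gene_id="G1", gene_symbol="GENE1", chrom=kw.get("chrom", "chr1"),
        strand=strand,
        coords=coords or defaults[event_class],
        inclusion_counts={"treatment": list(inc_t), "control": list(inc_c)},
        skipping_counts={"treatment": list(skp_t), "control": list(skp_c)},
        inclusion_length=kw.get("inclusion_length", 2),
        skipping_length=kw.get("skipping_length", 1),
        delta_psi=delta_psi, pvalue=kw.get("pvalue", 0.001), fdr=fdr,
    )


class TestComputePsi:
    def test_length_normalized_formula(self):
        assert compute_psi(18, 2, 2, 1) == pytest.approx(9 / 11)

    def test_no_skipping_evidence_gives_one(self):
        assert compute_psi(5, 0, 7, 3) == 1.0

    def test_no_inclusion_evidence_gives_zero(self):
        assert compute_psi(0, 7, 2, 1) == 0.0

    def test_undefined_when_no_reads(self):
        with pytest.raises(PsiUndefinedError):
            compute_psi(0, 0, 2, 1)

    @settings(deadline=None, max_examples=100)
    @given(i=st.integers(1, 500), s=st.integers(1, 500),
           scale=st.integers(2, 20))
    def test_monotone_and_scale_invariant(self, i, s, scale):
        base = compute_psi(i, s, 2, 1)
        assert compute_psi(i + 1, s, 2, 1) > base
        assert compute_psi(i, s + 1, 2, 1) < base
        assert compute_psi(i * scale, s * scale, 2, 1) == pytest.approx(base)


class TestRmatsReader:
    HEAD = ("ID\tGeneID\tgeneSymbol\tchr\tstrand\t" +
            "\t".join(COORD_COLUMNS["RI"]) +
            "\tIJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\t"
            "IncFormLen\tSkipFormLen\tPValue\tFDR\tIncLevel1\tIncLevel2\t"
            "IncLevelDifference")

    def write(self, tmp_path, row):
        p = tmp_path / "RI.MATS.JC.txt"
        p.write_text(self.HEAD + "\n" + row + "\n")
        return str(p)

    def test_ri_intron_gap(self, tmp_path):
        row = ("1\tG1\t\"X\"\tchr1\t+\t50\t250\t50\t100\t200\t250\t"
               "18,22\t3,4\t10,11\t5,6\t2\t1\tNA\tNA\tNA\tNA\tNA")
        ev, = read_rmats_events(self.write(tmp_path, row), "RI")
        assert ev.inclusion_counts["treatment"] == [18, 22]
        region = dase_region(ev)
        assert (region.start, region.end) == (100, 200)

    def test_missing_psi_recomputed(self, tmp_path):
        row = ("1\tG1\t\"X\"\tchr1\t+\t50\t250\t50\t100\t200\t250\t"
               "10,10\t0,0\t0,0\t10,10\t2\t1\tNA\tNA\tNA\tNA\tNA")
        ev, = read_rmats_events(self.write(tmp_path, row), "RI")
        assert ev.psi["treatment"] == [1.0, 1.0]
        assert ev.psi["control"] == [0.0, 0.0]

    def test_negative_coordinate_names_row_and_column(self, tmp_path):
        row = ("1\tG1\t\"X\"\tchr1\t+\t-5\t250\t50\t100\t200\t250\t"
               "1,1\t1,1\t1,1\t1,1\t2\t1\tNA\tNA\tNA\tNA\tNA")
        with pytest.raises(ValueError, match="row 1"):
            read_rmats_events(self.write(tmp_path, row), "RI")

    def test_unknown_class_tag(self, tmp_path):
        with pytest.raises(ValueError, match="unknown event class"):
            read_rmats_events(str(tmp_path / "x.txt"), "XX")


class TestCoverageAndFilter:
    def test_mean_coverage_over_all_replicates(self):
        ev = make_event(inc_t=(10, 2), skp_t=(0, 2), inc_c=(3, 0), skp_c=(3, 0))
        assert mean_event_coverage(ev) == 5.0

    def test_single_replicate(self):
        ev = make_event(inc_t=(4,), skp_t=(3,), inc_c=(5,), skp_c=(2,))
        assert mean_event_coverage(ev) == 7.0

    def test_table2_style_event_kept(self):
        ev = make_event(delta_psi=0.357, fdr=0.0043, inc_t=(40, 40),
                        skp_t=(10, 10), inc_c=(40, 40), skp_c=(10, 10))
        assert filter_dases([ev]) == [ev]

    def test_small_dpsi_removed(self):
        ev = make_event(delta_psi=0.09, fdr=0.04)
        assert filter_dases([ev]) == []

    def test_coverage_exactly_five_removed(self):
        ev = make_event(delta_psi=0.5, fdr=0.01, inc_t=(5, 5), skp_t=(0, 0),
                        inc_c=(5, 5), skp_c=(0, 0))
        assert mean_event_coverage(ev) == 5.0
        assert filter_dases([ev]) == []

    def test_missing_fdr_rejected(self):
        ev = make_event(fdr=None)
        assert filter_dases([ev]) == []

    def test_subset_and_idempotent(self):
        events = [make_event(event_id=f"e{k}", delta_psi=d, fdr=f)
                  for k, (d, f) in enumerate(
                      [(0.357, 0.0043), (0.05, 0.01), (0.2, 0.2), (-0.3, 0.01)])]
        once = filter_dases(events)
        assert set(e.event_id for e in once) <= set(e.event_id for e in events)
        assert filter_dases(once) == once


class TestDaseRegion:
    def test_se_is_alt_exon(self):
        region = dase_region(make_event("SE"))
        assert (region.start, region.end) == (300, 400)

    def test_mxe_strand_rule(self):
        assert dase_region(make_event("MXE", strand="+")).start == 300
        assert dase_region(make_event("MXE", strand="-")).start == 500

    def test_ri_is_intron_gap(self):
        region = dase_region(make_event("RI"))
        assert (region.start, region.end) == (200, 500)
        assert len(region) == 300

    def test_a3ss_excludes_short_exon(self):
        region = dase_region(make_event("A3SS"))
        assert (region.start, region.end) == (100, 250)

    def test_a5ss_excludes_short_exon(self):
        region = dase_region(make_event("A5SS"))
        assert (region.start, region.end) == (220, 300)

    def test_short_exon_not_at_boundary_is_error(self):
        coords = {"longExonStart_0base": 100, "longExonEnd": 300,
                  "shortES": 150, "shortEE": 250,
                  "flankingES": 10, "flankingEE": 50}
        with pytest.raises(ValueError, match="boundary"):
            dase_region(make_event("A3SS", coords=coords))

    @settings(deadline=None, max_examples=100)
    @given(ls=st.integers(0, 100), llen=st.integers(2, 300),
           slen=st.integers(1, 299), at_end=st.booleans())
    def test_long_minus_short_length(self, ls, llen, slen, at_end):
        # brute-force interval subtraction on random nested intervals
        slen = min(slen, llen - 1)
        le = ls + llen
        short = (le - slen, le) if at_end else (ls, ls + slen)
        coords = {"longExonStart_0base": ls, "longExonEnd": le,
                  "shortES": short[0], "shortEE": short[1],
                  "flankingES": 1000, "flankingEE": 1100}
        region = dase_region(make_event("A3SS", coords=coords))
        brute = [p for p in range(ls, le) if not short[0] <= p < short[1]]
        assert len(region) == len(brute) == llen - slen
        assert region.start == brute[0] and region.end == brute[-1] + 1


class TestSequenceExtraction:
    def test_forward_substring(self):
        g = GenomeSource({"c": "ACGTACGT"})
        assert extract_sequence(g, GenomicInterval("c", 2, 5, "+")) == "GTA"

    def test_reverse_complement(self):
        g = GenomeSource({"c": "ACGTACGT"})
        assert extract_sequence(g, GenomicInterval("c", 2, 5, "-")) == "TAC"

    def test_out_of_bounds_names_contig(self):
        g = GenomeSource({"c": "ACGTACGT"})
        with pytest.raises(ValueError, match="c:6-12"):
            extract_sequence(g, GenomicInterval("c", 6, 12, "+"))

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    def test_double_reverse_complement_is_identity(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestCallDases:
    def test_identical_counts_null(self):
        ev = make_event(delta_psi=None, fdr=None, pvalue=None)
        call_dases_from_counts([ev])
        assert ev.delta_psi == 0.0
        assert ev.pvalue == 1.0

    def test_extreme_separation(self):
        ev = make_event(inc_t=(100,), skp_t=(0,), inc_c=(0,), skp_c=(100,),
                        inclusion_length=1, skipping_length=1,
                        delta_psi=None, fdr=None, pvalue=None)
        call_dases_from_counts([ev])
        assert ev.delta_psi == pytest.approx(1.0)  # treatment minus control
        assert ev.pvalue < 1e-6

    def test_zero_read_group_flagged_untestable(self):
        ev = make_event(inc_t=(0, 0), skp_t=(0, 0), delta_psi=None, fdr=None)
        call_dases_from_counts([ev])
        assert not ev.testable and ev.fdr is None

    def test_bh_adjustment_matches_hand_formula(self):
        events = [make_event(event_id=f"e{k}") for k in range(3)]
        # engineer distinct p-values through different count separations
        for ev, (it, ic) in zip(events, [(18, 6), (16, 8), (14, 10)]):
            ev.inclusion_counts = {"treatment": [it], "control": [ic]}
            ev.skipping_counts = {"treatment": [24 - it], "control": [24 - ic]}
        call_dases_from_counts(events)
        expected = oracle_bh([ev.pvalue for ev in events])
        for ev, q in zip(events, expected):
            assert ev.fdr == pytest.approx(q)

    def test_bh_monotone_over_sorted_pvalues(self):
        adj = oracle_bh([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])
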