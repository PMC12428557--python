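import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from splicedown.events import read_rmats_events
from splicedown.motifs import (IUPAC_RNA, CoherentOccurrence, Motif,
                               RBPNetwork, RegionLayout, SubRegion,
                               build_region_layout, coherent_occurrences,
                               density_profile, motif_scan, reduce_rbp_network,
                               summarize_enrichment, wilcoxon_window_test)
from oracles import oracle_motif_positions, oracle_ranksum_p

from test_events import make_event
from splicedown.intervals import GenomeSource

UGCAUG = Motif("RBFOX1", ("UGCAUG",))


class TestMotifScan:
    def test_overlapping_matches_against_naive_oracle(self):
        seq = "AUGCAUGCAUG"
        positions = motif_scan(seq, UGCAUG)
        assert positions == oracle_motif_positions(seq, "UGCAUG", IUPAC_RNA)
        assert positions == [1, 5]

    def test_iupac_degenerate_semantics(self):
        ry = Motif("X", ("RY",))
        assert motif_scan("AG", ry) == []      # G is not a pyrimidine
        assert motif_scan("AC", ry) == [0]
        assert motif_scan("GU", ry) == [0]

    def test_n_in_sequence_never_matches(self):
        assert motif_scan("N" * 30, Motif("X", ("NNN",))) == []

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=200))
            pat = "".join(rng.choice(list("ACGURYSWN"), size=5))
            m = Motif("X", (pat,))
            assert motif_scan(seq, m) == oracle_motif_positions(seq, pat, IUPAC_RNA)

    def test_multiple_patterns_union(self):
        m = Motif("X", ("AAA", "CCC"))
        assert motif_scan("AAACCC", m) == [0, 3]


class TestRegionLayout:
    def _se_event(self, exon=300, introns=1000, flanks=300):
        a = 100
        coords = {"upstreamES": a, "upstreamEE": a + flanks,
                  "exonStart_0base": a + flanks + introns,
                  "exonEnd": a + flanks + introns + exon,
                  "downstreamES": a + flanks + introns + exon + introns,
                  "downstreamEE": a + flanks + introns + exon + introns + flanks}
        return make_event("SE", coords=coords)

    def _genome(self, n=10000):
        rng = np.random.default_rng(5)
        return GenomeSource({"chr1": "".join(rng.choice(list("ACGT"), size=n))})

    def test_nominal_sizes_with_long_features(self):
        lay = build_region_layout(self._se_event(), self._genome())
        sizes = [len(s.sequence) for s in lay.subregions]
        assert sizes == [50, 250, 250, 50, 50, 250, 250, 50]
        collapses = [s.collapse for s in lay.subregions]
        assert collapses == ["Upstream"] * 3 + ["Exon"] * 2 + ["Downstream"] * 3

    def test_short_exon_truncated_without_double_counting(self):
        lay = build_region_layout(self._se_event(exon=40), self._genome())
        exon_subs = lay.collapsed("Exon")
        assert sum(len(s.sequence) for s in exon_subs) == 40
        assert all(len(s.sequence) <= s.nominal for s in lay.subregions)

    def test_ri_intron_collapses_to_exon_region(self, small_bundle, small_genome):
        ev = read_rmats_events(small_bundle.paths["rmats_RI"], "RI")[0]
        lay = build_region_layout(ev, small_genome)
        assert [s.collapse for s in lay.subregions] == \
            ["Upstream", "Exon", "Exon", "Downstream"]

    def test_all_classes_produce_layouts(self, small_bundle, small_genome):
        for cls in ("SE", "MXE", "RI", "A3SS", "A5SS"):
            for ev in read_rmats_events(small_bundle.paths[f"rmats_{cls}"], cls):
                lay = build_region_layout(ev, small_genome)
                assert {s.collapse for s in lay.subregions} <= \
                    {"Upstream", "Exon", "Downstream"}
                assert all(len(s.sequence) <= s.nominal for s in lay.subregions)


class TestWilcoxon:
    def test_worked_example_exact(self):
        assert wilcoxon_window_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert wilcoxon_window_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_small_sample_minimum(self):
        with pytest.raises(ValueError):
            wilcoxon_window_test([1, 2], [1, 2, 3])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n, m = rng.integers(3, 9, size=2)
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=m).astype(float)
            assert wilcoxon_window_test(x, y) == pytest.approx(
                oracle_ranksum_p(x, y))

    def test_exact_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(20):
            perm = rng.permutation(100).astype(float)
            x, y = perm[:6], perm[6:13]
            ours = wilcoxon_window_test(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref))

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        diffs = []
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(0.5, size=8)
            exact = wilcoxon_window_test(x, y)
            approx = float(mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue)
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.05 and np.mean(diffs) < 0.01


def make_layout(event_id, dpsi, sequence, event_class="SE",
                collapse="Upstream", nominal=250):
    return RegionLayout(event_id, event_class, dpsi, [
        SubRegion("R1", collapse, nominal, "5p", sequence)])


def random_layouts(rng, n, dpsi, occurrences=0, nominal=250):
    out = []
    for k in range(n):
        seq = list("".join(rng.choice(list("ACGU"), size=nominal)))
        for _ in range(occurrences):
            pos = int(rng.integers(0, nominal - 6))
            seq[pos:pos + 6] = "UGCAUG"
        out.append(make_layout(f"e{k}_{dpsi}", dpsi, "".join(seq)))
    return out


class TestDensityProfile:
    def test_single_occurrence_density(self):
        seq = "UGCAUG" + "A" * 44
        lay = make_layout("e1", 0.5, seq, nominal=50)
        prof = density_profile({"up": [lay], "background": [lay]},
                               UGCAUG, window=50)
        assert prof.regions["R1"]["mean"]["up"][0] == pytest.approx(6 / 50)

    def test_motif_free_profile_is_zero(self, rng):
        lays = random_layouts(rng, 5, 0.5, occurrences=0)
        prof = density_profile({"up": lays}, Motif("X", ("ACGUACGUAC",)))
        vals = prof.regions["R1"]["mean"]["up"]
        assert np.nanmax(vals) == 0.0

    def test_mean_density_near_analytic_expectation(self, rng):
        # iid bases: P(match at a position) = (1/4)^6; expected window
        # coverage ~ p * motif_len (non-overlap approximation)
        lays = random_layouts(rng, 2000, 0.5)
        prof = density_profile({"up": lays}, UGCAUG)
        observed = float(np.nanmean(prof.regions["R1"]["mean"]["up"]))
        p_match = 0.25 ** 6
        expected = p_match * 6
        se = np.sqrt(expected / (2000 * 50))  # generous scale for the mean
        assert abs(observed - expected) < 3 * max(se, 1e-5)

    def test_truncated_events_skip_partial_windows(self):
        full = make_layout("e1", 0.5, "A" * 250)
        short = make_layout("e2", 0.5, "A" * 60)
        prof = density_profile({"up": [full, short]}, UGCAUG)
        mat_nan = np.isnan(prof.regions["R1"]["mean"]["up"])
        assert not mat_nan.any()  # full event covers the grid


class TestSummaryAndCoherence:
    def _summary(self, rng, up_occ, alpha=0.05):
        up = random_layouts(rng, 40, -0.4, occurrences=up_occ)
        bg = random_layouts(rng, 60, 0.0, occurrences=0)
        prof = density_profile({"down": up, "background": bg}, UGCAUG)
        return summarize_enrichment([prof], alpha)

    def test_planted_enrichment_flagged(self, rng):
        assert ("RBFOX1", "SE", "down", "Upstream") in self._summary(rng, 3)

    def test_alpha_zero_empty(self, rng):
        assert self._summary(rng, 3, alpha=0.0) == set()

    def test_occurrence_kept_only_with_matching_summary(self):
        lay = make_layout("e1", -0.2, "UGCAUG" + "A" * 244)
        summary = {("RBFOX1", "SE", "down", "Upstream")}
        occ = coherent_occurrences([lay], [UGCAUG], summary)
        assert len(occ) == 1 and occ[0].positions == [0]
        assert coherent_occurrences([lay], [UGCAUG], set()) == []

    def test_zero_dpsi_excluded(self):
        lay = make_layout("e1", 0.0, "UGCAUG" + "A" * 244)
        summary = {("RBFOX1", "SE", "down", "Upstream"),
                   ("RBFOX1", "SE", "up", "Upstream")}
        assert coherent_occurrences([lay], [UGCAUG], summary) == []


class TestNetworkReduction:
    def test_chain_kept_isolated_dropped(self):
        net = RBPNetwork({"A": "down", "B": "none", "C": "none", "D": "none"},
                         [("A", "B"), ("B", "C")])
        red = reduce_rbp_network(net)
        assert set(red.nodes) == {"A", "B", "C"}

    def test_no_degs_drops_all_nondeg(self):
        net = RBPNetwork({"A": "none", "B": "none"}, [("A", "B")])
        assert reduce_rbp_network(net).nodes == {}

    def test_idempotent(self):
        net = RBPNetwork({"A": "up", "B": "none", "C": "none"},
                         [("A", "B")])
        once = reduce_rbp_network(net)
        twice = reduce_rbp_network(once)
        assert once.nodes == twice.nodes and once.edges == twice.edges

    def test_study_style_fixture_retains_13_rbps(self):
        srsf = [f"SRSF{k}" for k in (1, 2, 3, 6, 7, 9)]
        fxr = ["FXR1", "FXR2", "FMR1"]
        singles = ["ANKHD1", "HNRNPK", "PABPC4", "RBFOX1"]
        decoys = ["PTBP1", "U2AF2"]
        nodes = {n: "none" for n in srsf + fxr + decoys}
        nodes.update({"SRSF7": "down", "FXR1": "down"})
        nodes.update({n: "down" for n in singles[1:]})
        nodes["ANKHD1"] = "up"
        edges = [(a, b) for grp in (srsf, fxr)
                 for i, a in enumerate(grp) for b in grp[i + 1:]]
        edges.append(tuple(decoys))
        red = reduce_rbp_network(RBPNetwork(nodes, edges))
        assert len(red.nodes) == 13
        assert set(decoys) & set(red.nodes) == set()
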