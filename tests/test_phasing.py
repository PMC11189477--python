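"""Reference-sperm phasing: relative genotyping, breakpoints, correction,
bin maps and marker emission."""

import numpy as np
import pandas as pd
import pytest

from gametophase.gametematrix import MISSING
from gametophase.phasing import (
    BinMap,
    CrossoverEvent,
    RelativeTracks,
    build_bin_map,
    correct_false_recombination,
    count_crossovers,
    detect_breakpoints,
    detect_all_breakpoints,
    emit_haplotype_markers,
    filter_suspicious,
    genotype_against_reference,
    phase_pipeline,
)
from gametophase.simdata import marker_accuracy

from conftest import TOY_EVENT_SPACING_BP, make_matrix


def states_from(text: str) -> np.ndarray:
    """'SSDD.S' -> [0, 0, 1, 1, -1, 0]."""
    return np.array({"S": 0, "D": 1, ".": -1}[c] for c in text) if False else np.array(
        [{"S": 0, "D": 1, ".": -1}[c] for c in text], dtype=np.int8
    )


class TestRelativeGenotyping:
    def test_identical_sperm_is_all_same(self):
        m = make_matrix(np.array([[0, 0], [1, 1], [0, 0]]))
        tracks = genotype_against_reference(m, "s001")
        np.testing.assert_array_equal(tracks.states[:, 1], [0, 0, 0])

    def test_reference_own_track_is_all_same(self):
        m = make_matrix(np.array([[0, 1], [1, 0], [MISSING, 1]]))
        tracks = genotype_against_reference(m, "s001")
        np.testing.assert_array_equal(tracks.states[:, 0], [0, 0, MISSING])

    def test_missing_in_either_cell_is_missing_state(self):
        m = make_matrix(np.array([[0, MISSING], [MISSING, 1], [1, 0]]))
        tracks = genotype_against_reference(m, "s001")
        np.testing.assert_array_equal(tracks.states[:, 1], [MISSING, MISSING, 1])

    def test_unknown_reference_rejected(self):
        m = make_matrix(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            genotype_against_reference(m, "nope")


class TestDetectBreakpoints:
    def run(self, text, window=3, min_support=3):
        s = states_from(text)
        pos = np.arange(1, len(s) + 1) * 10_000
        return detect_breakpoints(s, pos, window, min_support, "s", "chr1")

    def test_clean_switch_called_between_flanking_sites(self):
        events = self.run("SSSSSDDDDD")
        assert len(events) == 1
        assert (events[0].left_bp, events[0].right_bp) == (50_000, 60_000)
        assert events[0].support_left >= 3 and events[0].support_right >= 3

    def test_isolated_flip_is_not_a_breakpoint(self):
        assert self.run("SSSDSSSSSS") == []

    def test_short_doublet_lacks_support(self):
        assert self.run("SSSSDDSSSS") == []

    def test_supported_internal_segment_yields_two_events(self):
        events = self.run("SSSSDDDDSSSS")
        assert [(e.left_bp, e.right_bp) for e in events] == [
            (40_000, 50_000),
            (80_000, 90_000),
        ]

    def test_missing_sites_are_skipped_not_split(self):
        # the terminal DD run has only 2 concordant sites: below support
        assert self.run("SSS...SSSDD") == []
        events = self.run("SSSS..DDDD")
        assert len(events) == 1
        assert (events[0].left_bp, events[0].right_bp) == (40_000, 70_000)

    def test_error_adjacent_to_boundary_shifts_call_by_at_most_one_site(self):
        # the flip sits in the ambiguous S/D zone; either flanking site is
        # an acceptable boundary, one site off at most
        events = self.run("SSSSSDSDDDDD", window=4)
        assert len(events) == 1
        assert 50_000 <= events[0].left_bp <= 70_000

    def test_window_validation(self):
        with pytest.raises(ValueError):
            self.run("SSDD", window=0)


class TestFalseRecombinationCorrection:
    @pytest.fixture
    def toy(self):
        """Fig.-1-style toy: 8 noiseless sperm, the reference recombines once.

        30 sites at 10-kb spacing; the reference sperm (s001) switches
        haplotype between sites 15 and 16, each other sperm at its own
        position.
        """
        n_sites, n_sperm = 30, 8
        own = [None, 3, 7, 10, 18, 22, 25, None]  # own crossover after site i
        codes = np.zeros((n_sites, n_sperm), dtype=np.int8)
        for j, cut in enumerate(own):
            if cut is not None:
                codes[cut:, j] = 1
        codes[15:, 0] ^= 1  # the reference sperm's own crossover
        return make_matrix(codes), own

    def test_population_flips_at_reference_crossover_before_correction(self, toy):
        m, _ = toy
        tracks = genotype_against_reference(m, "s001")
        events = detect_all_breakpoints(tracks, window=3, min_support=3)
        for sid in m.sperm_ids[1:]:
            assert any(
                e.left_bp == 150_000 and e.right_bp == 160_000 for e in events[sid]
            ), f"{sid} lacks the shared false recombination"

    def test_correction_removes_shared_breakpoint_and_credits_reference(self, toy):
        m, own = toy
        tracks = genotype_against_reference(m, "s001")
        result = correct_false_recombination(
            tracks, window=3, min_support=3, tolerance_bp=50_000
        )
        assert len(result.reference_positions["chr1"]) == 1
        assert result.reference_positions["chr1"][0] == pytest.approx(155_000, abs=10_000)
        assert len(result.events["s001"]) == 1  # the reference now carries it
        for j, sid in enumerate(m.sperm_ids[1:], start=1):
            mids = [e.mid for e in result.events[sid]]
            if own[j] is None:
                assert mids == []
            else:
                assert len(mids) == 1
                assert abs(mids[0] - (own[j] * 10_000 + 5_000)) <= 10_000

    def test_no_shared_breakpoint_is_identity(self, toy):
        m, _ = toy
        codes = m.calls.copy()
        codes[15:, 0] ^= 1  # undo the reference crossover
        m2 = make_matrix(codes)
        tracks = genotype_against_reference(m2, "s001")
        result = correct_false_recombination(
            tracks, window=3, min_support=3, tolerance_bp=50_000
        )
        assert result.reference_positions == {"chr1": []}
        np.testing.assert_array_equal(result.tracks.states, tracks.states)

    def test_correction_is_idempotent(self, small_sim):
        _, _, matrix = small_sim
        tracks = genotype_against_reference(matrix, matrix.sperm_ids[0])
        once = correct_false_recombination(tracks)
        twice = correct_false_recombination(once.tracks)
        assert all(not v for v in twice.reference_positions.values())
        np.testing.assert_array_equal(once.tracks.states, twice.tracks.states)

    def test_simulated_reference_events_match_truth(self, phased_small):
        truth, ref = phased_small["truth"], phased_small["ref"]
        correction = phased_small["correction"]
        ridx = truth.sperm_ids.index(ref)
        for chrom, declared in correction.reference_positions.items():
            true_xs = truth.crossovers[ridx].get(chrom, [])
            for d in declared:
                assert min((abs(d - x) for x in true_xs), default=np.inf) < 200_000


class TestSuspiciousFilter:
    def test_close_pair_removed_both(self):
        ev = {
            "s1": [
                CrossoverEvent("s1", "chr1", 1_000_000, 1_010_000, 5, 5),
                CrossoverEvent("s1", "chr1", 1_100_000, 1_110_000, 5, 5),
                CrossoverEvent("s1", "chr1", 5_000_000, 5_010_000, 5, 5),
            ]
        }
        kept, removed = filter_suspicious(ev, min_spacing_bp=2_000_000)
        assert removed == 2
        assert [e.mid for e in kept["s1"]] == [5_005_000.0]

    def test_far_events_untouched(self):
        ev = {"s1": [CrossoverEvent("s1", "chr1", 1_000_000, 1_010_000, 5, 5)]}
        kept, removed = filter_suspicious(ev)
        assert removed == 0 and kept == ev


class TestBinMap:
    def tracks(self, states, positions):
        sites = pd.DataFrame({"chrom": "chr1", "pos": positions})
        n_sperm = states.shape[1]
        return RelativeTracks(
            sites=sites,
            sperm_ids=[f"s{i + 1:03d}" for i in range(n_sperm)],
            ref_id="s001",
            states=np.asarray(states, dtype=np.int8),
            corrected=True,
        )

    def test_identical_intervals_merge_into_one_bin(self):
        pos = np.arange(1, 51) * 10_000  # 500 kb, 5 intervals of 100 kb
        states = np.zeros((50, 4), dtype=np.int8)
        bm = build_bin_map(self.tracks(states, pos), events={}, chrom_lengths={"chr1": 500_000})
        assert bm.n_bins == 1
        assert (bm.bins.iloc[0]["start"], bm.bins.iloc[0]["end"]) == (0, 500_000)

    def test_single_sperm_switch_cuts_exactly_one_boundary(self):
        pos = np.arange(1, 51) * 10_000
        states = np.zeros((50, 4), dtype=np.int8)
        states[20:, 2] = 1  # switch between 200 kb and 210 kb
        tr = self.tracks(states, pos)
        events = {"s003": [CrossoverEvent("s003", "chr1", 200_000, 210_000, 5, 5)]}
        bm = build_bin_map(tr, events, chrom_lengths={"chr1": 500_000})
        assert bm.n_bins == 2
        assert list(bm.bins["end"]) == [200_000, 500_000]
        np.testing.assert_array_equal(bm.genotypes[2], [0, 1])
        np.testing.assert_array_equal(bm.genotypes[0], [0, 0])

    def test_sperm_without_sites_in_bin_is_missing(self):
        pos = np.array([10_000, 20_000, 410_000, 420_000])
        states = np.array(
            [[0, 0], [0, 0], [0, MISSING], [0, MISSING]], dtype=np.int8
        )
        events = {"s001": [CrossoverEvent("s001", "chr1", 20_000, 410_000, 2, 2)]}
        # a cut separates the two site clusters; sperm 2 has no calls right
        bm = build_bin_map(self.tracks(states, pos), events, chrom_lengths={"chr1": 500_000})
        assert bm.genotypes[1, -1] == MISSING


class TestCountCrossovers:
    def bin_map(self, geno):
        geno = np.asarray(geno, dtype=np.int8)
        bins = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(geno.shape[1]) * 100_000,
                "end": (np.arange(geno.shape[1]) + 1) * 100_000,
            }
        )
        bins["bin_id"] = [f"chr1:{s}-{e}" for s, e in zip(bins["start"], bins["end"])]
        return BinMap(bins=bins, sperm_ids=["s1"], genotypes=geno)

    def test_single_transition(self):
        counts, mean = count_crossovers(self.bin_map([[0, 0, 1, 1]]))
        assert counts["s1"] == 1 and mean == 1.0

    def test_missing_bins_are_bridged(self):
        counts, _ = count_crossovers(self.bin_map([[0, MISSING, 1]]))
        assert counts["s1"] == 1
        counts, _ = count_crossovers(self.bin_map([[0, MISSING, 0]]))
        assert counts["s1"] == 0


class TestMarkers:
    def test_noiseless_markers_equal_truth_up_to_label_swap(self):
        from gametophase.gametematrix import qc_sperm, select_reference_sperm
        from gametophase.simdata import (
            SimConfig,
            simulate_donor,
            simulate_meiosis,
            simulate_sperm_calls,
        )

        cfg = SimConfig(
            n_chromosomes=2, chrom_length_bp=3_000_000, n_sperm=40,
            dropout_rate=0.0, genotype_error_rate=0.0, seed=31,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        m = simulate_sperm_calls(truth, cfg)
        qc, _ = qc_sperm(m)
        # noiseless data: close crossover pairs are real, keep them
        bin_map, markers, _, report = phase_pipeline(
            m, select_reference_sperm(qc), min_event_spacing_bp=0
        )
        # sites in the sliver between a crossover and its snapped bin edge
        # can fall below the phasing-confidence cutoff; everything that is
        # phased must be exact
        assert report["n_phased"] >= 0.99 * len(truth.sites)
        assert marker_accuracy(markers, truth) == 1.0

    def test_low_confidence_site_dropped(self):
        geno = np.zeros((10, 1), dtype=np.int8)  # one bin, all sperm H0
        bins = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 100_000, "bin_id": "chr1:0-100000"}]
        )
        bm = BinMap(bins=bins, sperm_ids=[f"s{i:03d}" for i in range(10)], genotypes=geno)
        calls = np.array([[0] * 6 + [1] * 4])  # 60/40 allele split among H0 sperm
        m = make_matrix(calls.T.reshape(1, 10), positions=[50_000],
                        sperm_ids=bm.sperm_ids)
        markers, report = emit_haplotype_markers(bm, m, min_marker_confidence=0.9)
        assert markers.empty
        assert report["n_dropped_low_confidence"] == 1

    def test_confident_site_phased_with_allele_letters(self):
        geno = np.array([[0], [1]], dtype=np.int8)  # (2 sperm, 1 bin): H0 and H1
        bins = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 100_000, "bin_id": "chr1:0-100000"}]
        )
        bm = BinMap(bins=bins, sperm_ids=["s001", "s002"], genotypes=geno)
        m = make_matrix(np.array([[0, 1]]), positions=[50_000], sperm_ids=["s001", "s002"])
        markers, _ = emit_haplotype_markers(bm, m)
        assert markers.iloc[0]["hap0"] == "A" and markers.iloc[0]["hap1"] == "C"
        assert markers.iloc[0]["confidence"] == 1.0

    def test_marker_report_partitions_sites(self, phased_small):
        report = phased_small["report"]
        assert (
            report["n_phased"]
            + report["n_unphased_no_info"]
            + report["n_dropped_low_confidence"]
            == report["n_sites"]
        )


def test_detected_counts_match_truth_on_identifiable_tracks(phased_small):
    """Under study-like noise (50% dropout, 1% error) the detector returns
    exactly k events for a track with k crossovers in >=95% of sperm
    chromosomes, counting tracks whose crossovers are identifiable (at
    least min_support informative sites on each side and no pair below
    the suspicious-spacing resolution)."""
    cfg, truth, matrix = (
        phased_small["cfg"], phased_small["truth"], phased_small["matrix"]
    )
    correction = phased_small["correction"]
    events, _ = filter_suspicious(correction.events, TOY_EVENT_SPACING_BP)
    tracks = correction.tracks
    pos_all = tracks.sites["pos"].to_numpy()
    n = exact = 0
    for s, sid in enumerate(truth.sperm_ids):
        for chrom in cfg.chrom_names():
            sl = tracks.chrom_slice(chrom)
            obs = np.flatnonzero(tracks.states[sl][:, s] != MISSING)
            p = pos_all[sl][obs]
            xs = sorted(float(x) for x in truth.crossovers[s].get(chrom, []))
            identifiable = all(
                5 <= np.searchsorted(p, x) <= len(p) - 5 for x in xs
            ) and all(b - a >= TOY_EVENT_SPACING_BP for a, b in zip(xs, xs[1:]))
            if not identifiable:
                continue
            n += 1
            exact += sum(1 for e in events[sid] if e.chrom == chrom) == len(xs)
    assert n > 100
    assert exact / n >= 0.95


def test_label_swap_leaves_crossover_counts_invariant(phased_small):
    bm = phased_small["bin_map"]
    counts, mean = count_crossovers(bm)
    swapped = BinMap(
        bins=bm.bins, sperm_ids=bm.sperm_ids,
        genotypes=np.where(bm.genotypes == MISSING, MISSING, 1 - bm.genotypes).astype(np.int8),
    )
    counts2, mean2 = count_crossovers(swapped)
    pd.testing.assert_series_equal(counts, counts2)
    assert mean == mean2
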