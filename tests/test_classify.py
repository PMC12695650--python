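"""CA classification: decision tree, annotations, breakdowns, size filter."""

import numpy as np
import pandas as pd
import pytest

from strandkaryo.classify import (CACall, annotation_share, annotate_inverted_duplication,
                                  annotate_on_breakpoint, class_breakdown,
                                  classify_cell, detect_isoacentric_signature,
                                  filter_min_size)
from strandkaryo.segmentation import ConsensusKaryotype, SegmentTrack, StrandSegmenter
from strandkaryo.simulate import CAEventSpec


def make_track(grid, cell, chrom_segments):
    """Build a SegmentTrack from {chrom: [(n_bins, c1, c2, w1, w2), ...]}."""
    rows = []
    for chrom, segs in chrom_segments.items():
        sl = grid.chrom_slice(chrom)
        cursor = 0
        for n_bins, c1, c2, w1, w2 in segs:
            s, e = cursor, cursor + n_bins
            rows.append({
                "chrom": chrom,
                "start": int(grid.starts[chrom][s]),
                "end": int(grid.ends[chrom][e - 1]),
                "start_bin": sl.start + s, "end_bin": sl.start + e,
                "c1": c1, "c2": c2, "w1": w1, "w2": w2,
                "cn_total": c1 + c2,
                "strand_label": "", "at_cap": False,
            })
            cursor = e
        assert cursor == sl.stop - sl.start, f"{chrom} not fully covered"
    return SegmentTrack(cell, grid, pd.DataFrame(rows))


def full_track(grid, chrom_segments):
    """Complete partial chrom specs with flat WC disomy on other chromosomes."""
    out = {}
    for chrom in grid.genome.names:
        n = grid.n_bins_of(chrom)
        out[chrom] = chrom_segments.get(chrom, [(n, 1, 1, 1, 0)])
    return out


@pytest.fixture()
def consensus(grid):
    return ConsensusKaryotype.from_genome(grid)


class TestDecisionTree:
    def test_whole_chromosome_loss_and_gain(self, grid, consensus):
        n = grid.n_bins_of("chr2")
        track = make_track(grid, "c", full_track(grid, {
            "chr2": [(n, 0, 1, 0, 1)]}))
        calls = classify_cell(track, consensus)
        assert [c.cls for c in calls] == ["chromosome_loss"]
        assert calls[0].cn_delta == -1
        assert calls[0].start == 0 and calls[0].end == grid.genome.lengths["chr2"]

        track = make_track(grid, "c", full_track(grid, {
            "chr2": [(n, 2, 1, 2, 0)]}))
        calls = classify_cell(track, consensus)
        assert [c.cls for c in calls] == ["chromosome_gain"]

    def test_terminal_versus_interstitial(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        # q-terminal loss on H1
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0), (30, 0, 1, 0, 0)]}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "terminal_loss"
        assert call.end == grid.genome.lengths["chr1"]
        assert call.hap == "H1"
        # internal gain on H2
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(50, 1, 1, 1, 0), (20, 1, 2, 1, 0), (n - 70, 1, 1, 1, 0)]}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "interstitial_gain"
        assert call.hap == "H2"
        assert 0 < call.start and call.end < grid.genome.lengths["chr1"]

    def test_whole_arm_annotation_above_90_percent(self, grid, genome, consensus):
        # chr1 q arm: bins 80..200; an isolated gain covering 92% of it
        n = grid.n_bins_of("chr1")
        q_bins = n - genome.centromeres["chr1"] // grid.bin_size
        seg = int(q_bins * 0.92)
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - seg, 1, 1, 1, 0), (seg, 1, 2, 1, 1)]}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "terminal_gain"
        assert "whole_arm" in call.annotations
        # 80% coverage is not whole-arm
        seg = int(q_bins * 0.80)
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - seg, 1, 1, 1, 0), (seg, 1, 2, 1, 1)]}))
        (call,) = classify_cell(track, consensus)
        assert "whole_arm" not in call.annotations

    def test_terminal_multistep_and_complex(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        # telomere-anchored alternating block -> terminal multi-step
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 40, 1, 1, 1, 0), (20, 2, 1, 2, 0), (20, 0, 1, 0, 0)]}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "terminal_multistep"
        # same block not anchored at a telomere -> complex
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(50, 1, 1, 1, 0), (20, 2, 1, 2, 0), (20, 0, 1, 0, 0),
                     (n - 90, 1, 1, 1, 0)]}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "complex"

    def test_distant_deviations_are_independent_calls(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(20, 2, 1, 2, 0), (100, 1, 1, 1, 0), (30, 0, 1, 0, 0),
                     (n - 150, 1, 1, 1, 0)]}))
        calls = classify_cell(track, consensus)
        assert sorted(c.cls for c in calls) == ["interstitial_loss", "terminal_gain"]

    def test_chromothripsis_needs_min_oscillation(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        # 5 lost segments alternating with retained ones: 8 switches between
        # H1 copy number 0 and 1 -> chromothripsis
        pieces = [(10, 0 if i % 2 == 0 else 1, 1, 0 if i % 2 == 0 else 1, 0)
                  for i in range(9)]
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 90, 1, 1, 1, 0)] + pieces}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "chromothripsis"
        # a contiguous telomere-anchored +1/-1/+1 block oscillates between
        # two states but with too few switches -> terminal multi-step
        pieces = [(10, 2, 1, 2, 0), (10, 0, 1, 0, 0), (10, 2, 1, 2, 0)]
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0)] + pieces}))
        (call,) = classify_cell(track, consensus)
        assert call.cls == "terminal_multistep"

    def test_grid_mismatch_is_error(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        track = make_track(grid, "c", full_track(grid, {}))
        bad = ConsensusKaryotype(consensus.b1[:10], consensus.b2[:10],
                                 consensus.mask[:10])
        with pytest.raises(ValueError):
            classify_cell(track, bad)


class TestStrandAnnotations:
    def test_inverted_duplication_annotated_only_for_opposite_strand(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        # host H1 template W; gained copy on C (opposite) -> inverted dup
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0), (30, 2, 1, 1, 0)]}))
        (call,) = classify_cell(track, consensus)
        annotate_inverted_duplication(call, track)
        assert call.cls == "terminal_gain"
        assert call.strand_config == "opposite"
        assert "inverted_duplication" in call.annotations
        # tandem gain (same strand) -> not annotated
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0), (30, 2, 1, 2, 0)]}))
        (call,) = classify_cell(track, consensus)
        annotate_inverted_duplication(call, track)
        assert call.strand_config == "same"
        assert "inverted_duplication" not in call.annotations

    def test_isoacentric_flag_from_states(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        # +2 balanced on H1 (host W, extra 1 W + 1 C)
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0), (30, 3, 1, 2, 0)]}))
        (call,) = classify_cell(track, consensus)
        calls, tally = detect_isoacentric_signature([call], track)
        assert tally == (1, 1)
        assert "isoacentric_signature" in call.annotations
        # +2 with both extra copies on W -> not flagged
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(n - 30, 1, 1, 1, 0), (30, 3, 1, 3, 0)]}))
        (call,) = classify_cell(track, consensus)
        calls, tally = detect_isoacentric_signature([call], track)
        assert tally == (0, 1)
        assert "isoacentric_signature" not in call.annotations

    def test_cohort_of_injected_balanced_gains_tallies_18_of_18(self, genome, grid, cfg):
        # 18 cells, each one balanced two-copy acentric gain, with read counts
        rng_positions = np.random.default_rng(0)
        from strandkaryo.counts import StrandBinCounts
        from strandkaryo.simulate import baseline_cell, inject_event, render_counts
        counts = StrandBinCounts(grid)
        rng = np.random.default_rng(12)
        specs = {}
        for i in range(18):
            state = baseline_cell(genome, grid, rng, sce_mean=cfg.sce_mean)
            L = genome.lengths["chr2"]
            size = int(rng_positions.integers(10, 40)) * grid.bin_size
            spec = CAEventSpec("isoacentric_gain", "chr2",
                               "H1" if i % 2 else "H2", L - size, L, 2, "balanced")
            inject_event(state, spec)
            cell = f"c{i:02d}"
            specs[cell] = spec
            counts.add_cell(cell, render_counts(state, cfg.depth, rng, cfg))
        consensus = ConsensusKaryotype.from_genome(grid)
        seg = StrandSegmenter(config=cfg, consensus=consensus).fit(counts)
        tracks = seg.transform(counts)
        n_balanced = n_total = 0
        for cell, track in tracks.items():
            calls = classify_cell(track, seg.consensus_, cfg)
            gains = [c for c in calls if c.cn_delta >= 2 and "gain" in c.cls]
            _, (b, t) = detect_isoacentric_signature(
                gains, track, counts.cells[cell], consensus, cfg)
            n_balanced += b
            n_total += t
        assert (n_balanced, n_total) == (18, 18)

    def test_on_breakpoint_annotation_with_tolerance(self, grid, consensus):
        n = grid.n_bins_of("chr1")
        track = make_track(grid, "c", full_track(grid, {
            "chr1": [(100, 1, 1, 1, 0), (n - 100, 0, 1, 0, 0)]}))
        (call,) = classify_cell(track, consensus)
        pos = 100 * grid.bin_size + 50_000
        annotate_on_breakpoint([call], ("chr1", pos), grid, tolerance_bins=1)
        assert any(a.startswith("on_breakpoint") for a in call.annotations)
        far = [CACall("c", "chr1", 0, 10 * grid.bin_size, "H1", -1, "same",
                      "terminal_loss")]
        annotate_on_breakpoint(far, ("chr1", pos), grid, tolerance_bins=1)
        assert not far[0].annotations


class TestBreakdownAndFilter:
    def _fixture_calls(self, counts_by_class):
        calls = []
        i = 0
        for cls, n in counts_by_class.items():
            for _ in range(n):
                calls.append(CACall(f"cell{i}", "chr1", 0, 10**6, "H1",
                                    -1 if "loss" in cls else 1, "same", cls))
                i += 1
        return calls

    def test_whole_chromosome_share_to_one_decimal(self):
        calls = self._fixture_calls({
            "chromosome_loss": 19, "chromosome_gain": 2, "terminal_loss": 24,
            "terminal_gain": 27, "terminal_multistep": 29, "complex": 18,
            "interstitial_gain": 3, "interstitial_loss": 2,
        })
        assert len(calls) == 124
        bd = class_breakdown(calls)
        assert bd.share("chromosome_loss", "chromosome_gain") == 16.9
        assert bd.total == 124
        assert sum(bd.class_counts.values()) == 124
        assert abs(sum(bd.class_pct.values()) - 100.0) < 0.5

    def test_annotation_shares(self):
        calls = self._fixture_calls({"terminal_loss": 37})
        for c in calls[:24]:
            c.annotations.add("on_breakpoint(chrX:134460000)")
        assert annotation_share(calls, "on_breakpoint") == 64.9
        gains = self._fixture_calls({"terminal_gain": 49})
        for c in gains[:42]:
            c.annotations.add("inverted_duplication")
        assert annotation_share(gains, "inverted_duplication",
                                within_class="terminal_gain") == 85.7

    def test_single_call_is_100_percent(self):
        bd = class_breakdown(self._fixture_calls({"terminal_loss": 1}))
        assert bd.class_pct == {"terminal_loss": 100.0}

    def test_empty_breakdown(self):
        bd = class_breakdown([])
        assert bd.total == 0 and bd.class_pct == {}
        assert bd.share("terminal_loss") == 0.0

    @pytest.mark.parametrize("size, kept", [(150_000, False), (250_000, True)])
    def test_min_size_filter(self, size, kept):
        call = CACall("c", "chr1", 10**6, 10**6 + size, "H1", 1, "same",
                      "interstitial_gain")
        assert bool(filter_min_size([call])) is kept

    def test_min_size_zero_is_identity(self):
        calls = [CACall("c", "chr1", 0, 100, "H1", 1, "same", "terminal_gain")]
        assert filter_min_size(calls, 0) == calls


class TestPipelineInvariants:
    def test_positional_definitions_hold_for_all_calls(self, pipeline, genome):
        for call in pipeline["calls"]:
            length = genome.lengths[call.chrom]
            if call.cls in ("chromosome_gain", "chromosome_loss"):
                assert call.start == 0 and call.end == length
            elif call.cls in ("terminal_gain", "terminal_loss", "terminal_multistep"):
                assert call.start == 0 or call.end == length
            elif call.cls in ("interstitial_gain", "interstitial_loss"):
                assert call.start > 0 and call.end < length
            assert call.size >= 200_000 or call.cls == "chromothripsis"

    def test_classification_is_deterministic(self, pipeline, cfg):
        from strandkaryo.classify import classify_population
        calls2 = classify_population(pipeline["tracks"], pipeline["consensus"],
                                     pipeline["counts"], cfg)
        assert [c.to_row() for c in calls2] == [c.to_row() for c in pipeline["calls"]]

    def test_multistep_calls_carry_the_injected_haplotype(self, pipeline):
        truth = pipeline["truth"]
        calls = pipeline["calls"]
        checked = 0
        for cell, evs in truth.events.items():
            for ev in evs:
                if ev.spec.cls != "terminal_multistep":
                    continue
                matches = [c for c in calls
                           if c.cell == cell and c.chrom == ev.spec.chrom
                           and c.cls == "terminal_multistep"]
                for m in matches:
                    assert m.hap == ev.spec.hap
                    checked += 1
        assert checked > 0
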