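"""Synthetic Strand-seq generator: templates, events, sisters, noise."""

import numpy as np
import pytest

from strandkaryo.config import RunConfig
from strandkaryo.genome import GenomeModelError
from strandkaryo.simulate import (CAEventSpec, baseline_cell, expected_counts,
                                  inject_event, simulate_population,
                                  simulate_sister_pair)

CHR = "chr1"


def _clean_cfg(cfg, **over):
    return RunConfig(**{**cfg.to_dict(), **over})


class TestBaselinePopulation:
    def test_zero_event_rate_gives_canonical_states(self, genome, grid, cfg):
        c = _clean_cfg(cfg, sce_mean=0.0)
        counts, truth = simulate_population(
            genome, grid, n_cells=10, event_rate=0.0, seed=1, config=c)
        assert all(len(v) == 0 for v in truth.events.values())
        # per chromosome, W share of reads is near 0, 1/2 or 1 (WW/WC/CC)
        for cell in counts.cell_ids:
            cc = counts.cells[cell]
            for chrom in genome.names:
                sl = grid.chrom_slice(chrom)
                w = cc.total_w()[sl].sum()
                t = w + cc.total_c()[sl].sum()
                frac = w / t
                assert min(abs(frac - x) for x in (0.02, 0.5, 0.98)) < 0.03

    def test_fixed_seed_reproduces_counts_and_truth(self, genome, grid, cfg):
        a = simulate_population(genome, grid, n_cells=6, seed=3, config=cfg,
                                sister_fraction=0.4)
        b = simulate_population(genome, grid, n_cells=6, seed=3, config=cfg,
                                sister_fraction=0.4)
        assert a[0].equals(b[0])
        assert a[1].siblings == b[1].siblings
        assert {c: [e.spec.__dict__ for e in v] for c, v in a[1].events.items()} == \
               {c: [e.spec.__dict__ for e in v] for c, v in b[1].events.items()}

    def test_invalid_parameters(self, genome, grid, cfg):
        with pytest.raises(ValueError):
            simulate_population(genome, grid, n_cells=2, sister_fraction=1.5, config=cfg)
        with pytest.raises(ValueError):
            simulate_population(genome, grid, n_cells=0, config=cfg)
        with pytest.raises(ValueError):
            simulate_population(genome, grid, n_cells=2, depth=-5, config=cfg)


class TestCountModel:
    def test_expected_total_equals_depth_regardless_of_events(self, genome, grid, cfg, rng):
        state = baseline_cell(genome, grid, rng)
        inject_event(state, CAEventSpec("chromosome_gain", CHR, "H1", 0,
                                        genome.lengths[CHR], 1))
        exp = expected_counts(state, cfg.depth, cfg)
        total = sum(v.sum() for v in exp.values())
        assert total == pytest.approx(cfg.depth, rel=1e-9)

    def test_strand_bookkeeping_recovers_copy_profile(self, genome, grid, cfg, rng):
        # before noise, summed expected W+C per bin is proportional to the
        # injected total copy number at every bin
        state = baseline_cell(genome, grid, rng)
        inject_event(state, CAEventSpec("terminal_loss", CHR, "H2",
                                        20_000_000, 40_000_000, -1))
        exp = expected_counts(state, cfg.depth, cfg)
        per_bin = sum(v for v in exp.values()) / (grid.all_widths() / grid.bin_size)
        cn = state.cn("H1") + state.cn("H2")
        ratio = per_bin / cn
        assert ratio.std() / ratio.mean() < 1e-9


class TestInjectEvent:
    def test_terminal_loss_drops_one_haplotype(self, genome, grid, rng):
        state = baseline_cell(genome, grid, rng)
        before_h1 = state.cn("H1").copy()
        before_h2 = state.cn("H2").copy()
        L = genome.lengths[CHR]
        inject_event(state, CAEventSpec("terminal_loss", CHR, "H2", L - 20_000_000, L, -1))
        sl = grid.chrom_slice(CHR)
        lost = slice(sl.stop - 100, sl.stop)
        assert np.array_equal(state.cn("H2")[lost], before_h2[lost] - 1)
        untouched = np.ones(grid.n_bins, dtype=bool)
        untouched[lost] = False
        assert np.array_equal(state.cn("H2")[untouched], before_h2[untouched])
        assert np.array_equal(state.cn("H1"), before_h1)

    def test_isoacentric_gain_increments_watson_and_crick_equally(self, genome, grid, rng):
        state = baseline_cell(genome, grid, rng)
        w0, c0 = state.w["H1"].copy(), state.c["H1"].copy()
        L = genome.lengths[CHR]
        inject_event(state, CAEventSpec("isoacentric_gain", CHR, "H1",
                                        L - 10_000_000, L, 2, "balanced"))
        dw = state.w["H1"] - w0
        dc = state.c["H1"] - c0
        assert np.array_equal(dw, dc)
        assert dw.max() == 1.0

    def test_chromothripsis_oscillates_between_two_states_on_one_haplotype(
            self, genome, grid, rng):
        state = baseline_cell(genome, grid, rng)
        L = genome.lengths[CHR]
        bs = grid.bin_size
        bounds = [L - 12_000_000 + i * 1_000_000 for i in range(13)]
        steps = [(bounds[i], bounds[i + 1], -1) for i in range(0, 12, 2)]
        spec = CAEventSpec("chromothripsis", CHR, "H1", bounds[0], L, -1, steps=steps)
        inject_event(state, spec)
        sl = grid.chrom_slice(CHR)
        span0 = (L - 12_000_000) // bs
        affected = state.cn("H1")[sl][span0:]
        # direct tally: lost segments at 0 copies, retained at 1
        expected = np.ones_like(affected)
        for s, e, _ in steps:
            expected[s // bs - span0:e // bs - span0] = 0
        assert np.array_equal(affected, expected)
        assert set(np.unique(affected)) == {0.0, 1.0}
        # the other haplotype is untouched (one copy everywhere on this chrom)
        assert np.all(state.cn("H2")[sl] == 1)

    def test_off_chromosome_interval_rejected(self, genome, grid, rng):
        state = baseline_cell(genome, grid, rng)
        with pytest.raises(GenomeModelError):
            inject_event(state, CAEventSpec("terminal_loss", CHR, "H1",
                                            0, genome.lengths[CHR] + 1, -1))

    def test_class_invariants_enforced(self, genome):
        L = genome.lengths[CHR]
        with pytest.raises(ValueError, match="telomere"):
            CAEventSpec("terminal_loss", CHR, "H1", 1_000_000, 2_000_000, -1).validate(genome)
        with pytest.raises(ValueError, match="telomere"):
            CAEventSpec("interstitial_gain", CHR, "H1", 0, 2_000_000, 1).validate(genome)
        with pytest.raises(ValueError, match="even"):
            CAEventSpec("isoacentric_gain", CHR, "H1", L - 2_000_000, L, 1,
                        "balanced").validate(genome)
        with pytest.raises(ValueError, match="balanced"):
            CAEventSpec("isoacentric_gain", CHR, "H1", L - 2_000_000, L, 2,
                        "same").validate(genome)


class TestSisterPairs:
    def test_daughters_are_exact_template_complements(self, genome, grid, cfg, rng):
        parent = baseline_cell(genome, grid, rng, sce_mean=0.0)
        a, b, _ = simulate_sister_pair(parent, "none", rng, cfg)
        for key in a.template:
            assert np.array_equal(a.template[key], ~b.template[key])

    def test_parental_sce_appears_mirrored_in_both_daughters(self, genome, grid, cfg):
        rng = np.random.default_rng(42)
        parent = baseline_cell(genome, grid, rng, sce_mean=6.0)
        assert parent.sces, "seed chosen to give at least one parental SCE"
        a, b, _ = simulate_sister_pair(parent, "none", rng, cfg)
        sces_a = {(c, h, p) for c, h, p, _ in a.sces}
        sces_b = {(c, h, p) for c, h, p, _ in b.sces}
        assert sces_a == sces_b
        orient_a = {(c, h, p): o for c, h, p, o in a.sces}
        orient_b = {(c, h, p): o for c, h, p, o in b.sces}
        for key in orient_a:
            assert orient_a[key] != orient_b[key]

    def test_bfb_outcome_is_reciprocal_inverted_duplication_and_loss(
            self, genome, grid, cfg, rng):
        parent = baseline_cell(genome, grid, rng, sce_mean=0.0)
        a, b, (ev_a, ev_b) = simulate_sister_pair(parent, "bfb", rng, cfg)
        assert ev_a[0].cls == "terminal_inverted_duplication"
        assert ev_b[0].cls == "terminal_loss"
        assert (ev_a[0].chrom, ev_a[0].hap) == (ev_b[0].chrom, ev_b[0].hap)
        assert (ev_a[0].start, ev_a[0].end) == (ev_b[0].start, ev_b[0].end)
        # reciprocal copy number: deltas sum to zero over the interval
        total = (a.cn("H1") + a.cn("H2") + b.cn("H1") + b.cn("H2"))
        assert np.all(total == 4)

    def test_sibling_complementarity_outside_sce_intervals(self, genome, grid, cfg):
        counts, truth = simulate_population(
            genome, grid, n_cells=6, sister_fraction=1.0, seed=11, config=cfg,
            pair_outcomes=("none",))
        assert len(truth.siblings) == 3
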