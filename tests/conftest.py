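"""Shared fixtures: a reduced test genome and a simulated population.

The unit-test genome is small (3 chromosomes, 90 Mb, 450 bins at 200 kb)
with depth scaled to keep per-bin coverage comparable to a full-size
library, so noise behavior matches the defaults while tests stay fast.
"""

import numpy as np
import pytest

from strandkaryo.classify import classify_population
from strandkaryo.config import RunConfig
from strandkaryo.genome import GenomeModel, build_bin_grid
from strandkaryo.segmentation import StrandSegmenter
from strandkaryo.simulate import simulate_population


@pytest.fixture(scope="session")
def genome():
    return GenomeModel(
        names=("chr1", "chr2", "chr3"),
        lengths={"chr1": 40_000_000, "chr2": 30_000_000, "chr3": 20_000_000},
        centromeres={"chr1": 16_000_000, "chr2": 12_000_000, "chr3": 8_000_000},
    )


@pytest.fixture(scope="session")
def grid(genome):
    return build_bin_grid(genome, 200_000)


@pytest.fixture(scope="session")
def cfg():
    # ~110 reads per bin, matching the default full-genome coverage; the QC
    # floor scales with the reduced depth
    return RunConfig(depth=50_000, min_fragments=10_000)


@pytest.fixture(scope="session")
def population(genome, grid, cfg):
    counts, truth = simulate_population(
        genome, grid, n_cells=40, sister_fraction=0.2, seed=7, config=cfg,
    )
    return counts, truth


@pytest.fixture(scope="session")
def pipeline(population, cfg):
    counts, truth = population
    segmenter = StrandSegmenter(config=cfg).fit(counts)
    tracks = segmenter.transform(counts)
    calls = classify_population(tracks, segmenter.consensus_, counts, cfg)
    return {
        "counts": counts,
        "truth": truth,
        "segmenter": segmenter,
        "consensus": segmenter.consensus_,
        "tracks": tracks,
        "calls": calls,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
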