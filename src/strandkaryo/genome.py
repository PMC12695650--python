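"""Genome model and bin grid.

A :class:`GenomeModel` holds chromosome lengths, centromere positions (the
p/q arm boundary) and the baseline homologue count per chromosome (2 for a
disomic chromosome, 3 for a modelled trisomy).  A :class:`BinGrid` tiles each
chromosome with fixed-size half-open bins (BED convention, 0-based); the last
bin of a chromosome may be short.  The default bin size of 200 kb matches the
practical detection limit of intermediate-coverage Strand-seq libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 200_000

__all__ = [
    "GenomeModel",
    "BinGrid",
    "build_bin_grid",
    "default_genome",
    "hg38_like_genome",
    "read_genome_table",
    "write_genome_table",
]


class GenomeModelError(ValueError):
    """Raised when a genome model or coordinates referencing it are invalid."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names, lengths, centromeres and baseline homologue counts."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int]
    homologues: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        homs = dict(self.homologues)
        for name in self.names:
            homs.setdefault(name, 2)
        object.__setattr__(self, "homologues", homs)
        for name in self.names:
            if name not in self.lengths or name not in self.centromeres:
                raise GenomeModelError(f"chromosome {name!r} missing length or centromere")
            length = self.lengths[name]
            cen = self.centromeres[name]
            if length <= 0:
                raise GenomeModelError(f"chromosome {name!r} has non-positive length")
            if not (0 < cen < length):
                raise GenomeModelError(
                    f"centromere of {name!r} ({cen}) must be strictly inside (0, {length})"
                )
            if self.homologues[name] < 1:
                raise GenomeModelError(f"chromosome {name!r} has homologue count < 1")

    def check_chrom(self, chrom: str) -> None:
        if chrom not in self.lengths:
            raise GenomeModelError(f"unknown chromosome {chrom!r}")

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        """Return the [start, end) span of the ``'p'`` or ``'q'`` arm."""
        self.check_chrom(chrom)
        cen = self.centromeres[chrom]
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, self.lengths[chrom]
        raise GenomeModelError(f"arm must be 'p' or 'q', got {arm!r}")

    @property
    def total_homologues(self) -> int:
        return sum(self.homologues[c] for c in self.names)

    def with_homologues(self, **counts: int) -> "GenomeModel":
        """Copy of the model with some chromosomes' homologue counts replaced."""
        homs = dict(self.homologues)
        homs.update(counts)
        return GenomeModel(self.names, dict(self.lengths), dict(self.centromeres), homs)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-size tiling of a genome; bins are 0-based half-open intervals.

    Bins carry a single global index (0..n_bins-1) in chromosome order, which
    the count tables and all per-bin arrays use.
    """

    genome: GenomeModel
    bin_size: int
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    offsets: dict[str, int]
    n_bins: int

    def n_bins_of(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins_of(chrom))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base-pair position ``pos``."""
        self.genome.check_chrom(chrom)
        if not (0 <= pos < self.genome.lengths[chrom]):
            raise GenomeModelError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos // self.bin_size

    def widths(self, chrom: str) -> np.ndarray:
        return self.ends[chrom] - self.starts[chrom]

    def all_widths(self) -> np.ndarray:
        return np.concatenate([self.widths(c) for c in self.genome.names])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.names:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": self.starts[chrom],
                        "end": self.ends[chrom],
                        "bin": np.arange(self.n_bins_of(chrom)) + self.offsets[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_bin_grid(genome: GenomeModel, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile every chromosome with half-open bins of ``bin_size`` base pairs.

    The number of bins per chromosome is ``ceil(length / bin_size)``; the last
    bin is truncated at the chromosome end.  Pure function of its arguments.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    off = 0
    for chrom in genome.names:
        length = genome.lengths[chrom]
        n = math.ceil(length / bin_size)
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        starts[chrom] = s
        ends[chrom] = e
        offsets[chrom] = off
        off += n
    return BinGrid(genome, bin_size, starts, ends, offsets, off)


def default_genome() -> GenomeModel:
    """Reduced synthetic 5-chromosome genome (550 Mb) used throughout tests.

    Sizes span 70-150 Mb so that arm-scale events (1 Mb up to a full arm) and
    whole-chromosome aneuploidies are all representable, while the bin count
    (2,750 at 200 kb) keeps full-population simulations fast.
    """
    names = ("chr1", "chr2", "chr3", "chr4", "chr5")
    lengths = {"chr1": 150_000_000, "chr2": 130_000_000, "chr3": 110_000_000,
               "chr4": 90_000_000, "chr5": 70_000_000}
    centromeres = {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 45_000_000,
                   "chr4": 35_000_000, "chr5": 30_000_000}
    return GenomeModel(names, lengths, centromeres)


_HG38_LIKE = [
    # chrom, length, centromere (rounded to 1 Mb; approximate table)
    ("chr1", 248_000_000, 123_000_000), ("chr2", 242_000_000, 93_000_000),
    ("chr3", 198_000_000, 90_000_000), ("chr4", 190_000_000, 50_000_000),
    ("chr5", 181_000_000, 48_000_000), ("chr6", 171_000_000, 60_000_000),
    ("chr7", 159_000_000, 60_000_000), ("chr8", 145_000_000, 45_000_000),
    ("chr9", 138_000_000, 43_000_000), ("chr10", 134_000_000, 40_000_000),
    ("chr11", 135_000_000, 53_000_000), ("chr12", 133_000_000, 36_000_000),
    ("chr13", 114_000_000, 18_000_000), ("chr14", 107_000_000, 17_000_000),
    ("chr15", 102_000_000, 19_000_000), ("chr16", 90_000_000, 37_000_000),
    ("chr17", 83_000_000, 25_000_000), ("chr18", 80_000_000, 18_000_000),
    ("chr19", 59_000_000, 26_000_000), ("chr20", 64_000_000, 28_000_000),
    ("chr21", 47_000_000, 12_000_000), ("chr22", 51_000_000, 15_000_000),
    ("chrX", 156_000_000, 61_000_000),
]


def hg38_like_genome() -> GenomeModel:
    """23-chromosome model with hg38-like sizes (approximate, 1-Mb rounded)."""
    names = tuple(c for c, _, _ in _HG38_LIKE)
    return GenomeModel(
        names,
        {c: l for c, l, _ in _HG38_LIKE},
        {c: cen for c, _, cen in _HG38_LIKE},
    )


def read_genome_table(path) -> GenomeModel:
    """Read a genome model TSV with columns chrom, length, centromere, homologues."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "centromere", "homologues"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeModelError(f"genome table missing columns: {sorted(missing)}")
    names = tuple(df["chrom"].astype(str))
    return GenomeModel(
        names,
        dict(zip(names, df["length"].astype(int))),
        dict(zip(names, df["centromere"].astype(int))),
        dict(zip(names, df["homologues"].astype(int))),
    )


def write_genome_table(genome: GenomeModel, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": genome.names,
            "length": [genome.lengths[c] for c in genome.names],
            "centromere": [genome.centromeres[c] for c in genome.names],
            "homologues": [genome.homologues[c] for c in genome.names],
        }
    )
    df.to_csv(path, sep="\t", index=False)
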