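"""Reading and writing the package's TSV interchange formats.

All formats are plain TSV with a header; gzip is applied transparently when a
path ends in ``.gz`` (pandas handles compression by suffix).  Writers produce
deterministic row order and float formatting so that identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import pandas as pd

from .counts import CountsValidationError, StrandBinCounts
from .genome import BinGrid

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "write_calls_table",
    "read_calls_table",
]

COUNTS_COLUMNS = ["cell", "chrom", "start", "end", "hap", "w", "c"]


def read_counts_table(path, grid: BinGrid) -> StrandBinCounts:
    """Read and validate a counts TSV against ``grid``.

    Any malformed row (missing column, negative count, unknown chromosome,
    interval not aligned to the grid) raises a typed error; no partially
    loaded table is returned.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise CountsValidationError(f"counts table missing columns: {missing}")
    return StrandBinCounts.from_frame(df, grid)


def write_counts_table(counts: StrandBinCounts, path) -> None:
    """Write counts as TSV in deterministic (cell, chrom, bin, tag) order."""
    counts.to_frame().to_csv(path, sep="\t", index=False)


CALL_COLUMNS = [
    "cell", "chrom", "start", "end", "hap", "cn_delta",
    "strand_config", "class", "annotations",
]


def write_calls_table(calls, path) -> None:
    """Write classified CA calls; ``calls`` is an iterable of CACall."""
    rows = [c.to_row() for c in calls]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_calls_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CountsValidationError(f"calls table missing columns: {missing}")
    df["annotations"] = df["annotations"].fillna("")
    return df


SEGMENT_COLUMNS = [
    "cell", "chrom", "start", "end", "start_bin", "end_bin",
    "c1", "c2", "w1", "w2", "cn_total", "strand_label", "at_cap",
]


def write_segments_table(tracks: dict, path) -> None:
    """Write a dict of cell -> SegmentTrack as one TSV."""
    frames = []
    for cell in sorted(tracks):
        df = tracks[cell].segments.copy()
        df.insert(0, "cell", cell)
        frames.append(df)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=SEGMENT_COLUMNS))
    out.to_csv(path, sep="\t", index=False)


def read_segments_table(path, grid: BinGrid) -> dict:
    """Read a segments TSV back into cell -> SegmentTrack."""
    from .segmentation import SegmentTrack

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise CountsValidationError(f"segments table missing columns: {missing}")
    tracks = {}
    for cell, sub in df.groupby("cell", sort=True):
        tracks[str(cell)] = SegmentTrack(
            str(cell), grid, sub.drop(columns=["cell"]).reset_index(drop=True)
        )
    return tracks


def write_consensus_table(consensus, grid: BinGrid, path) -> None:
    df = grid.to_frame()
    df["b1"] = consensus.b1
    df["b2"] = consensus.b2
    df["mask"] = consensus.mask.astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_consensus_table(path, grid: BinGrid):
    from .segmentation import ConsensusKaryotype
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.n_bins:
        raise CountsValidationError("consensus table does not match the bin grid")
    return ConsensusKaryotype(
        df["b1"].to_numpy(np.int64), df["b2"].to_numpy(np.int64),
        df["mask"].to_numpy(bool),
    )
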