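"""Binned strand-resolved count table.

The primary observation table: per (cell, bin, haplotype tag) Watson and
Crick read counts.  Tags are ``H1``/``H2`` for reads whose haplotype is known
(e.g. via phased het-SNPs) and ``untagged`` for the remainder.  Internally
counts are stored as dense per-cell arrays over the global bin index of a
:class:`~strandkaryo.genome.BinGrid`, which keeps whole-population operations
vectorized; the tabular view materializes only non-empty records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinGrid

TAGS = ("H1", "H2", "untagged")

__all__ = ["StrandBinCounts", "CellCounts", "TAGS", "CountsValidationError"]


class CountsValidationError(ValueError):
    pass


@dataclass
class CellCounts:
    """Dense W/C count arrays (length = grid.n_bins) for one cell, per tag."""

    w: dict[str, np.ndarray]
    c: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, n_bins: int) -> "CellCounts":
        return cls(
            {t: np.zeros(n_bins, dtype=np.int64) for t in TAGS},
            {t: np.zeros(n_bins, dtype=np.int64) for t in TAGS},
        )

    def total_w(self) -> np.ndarray:
        return self.w["H1"] + self.w["H2"] + self.w["untagged"]

    def total_c(self) -> np.ndarray:
        return self.c["H1"] + self.c["H2"] + self.c["untagged"]

    def total(self) -> int:
        return int(self.total_w().sum() + self.total_c().sum())


class StrandBinCounts:
    """Population count table over a shared bin grid."""

    def __init__(self, grid: BinGrid, cells: dict[str, CellCounts] | None = None):
        self.grid = grid
        self.cells: dict[str, CellCounts] = cells or {}

    def add_cell(self, cell: str, counts: CellCounts) -> None:
        if cell in self.cells:
            raise CountsValidationError(f"duplicate cell id {cell!r}")
        self.cells[cell] = counts

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.cells)

    def n_records(self) -> int:
        n = 0
        for cc in self.cells.values():
            for t in TAGS:
                n += int(((cc.w[t] > 0) | (cc.c[t] > 0)).sum())
        return n

    def cell_total(self, cell: str) -> int:
        return self.cells[cell].total()

    def qc_pass(self, min_fragments: int) -> list[str]:
        """Cells with at least ``min_fragments`` mapped fragments, sorted."""
        return [c for c in self.cell_ids if self.cell_total(c) >= min_fragments]

    # ---- tabular view -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format records (cell, chrom, start, end, hap, w, c).

        Rows with zero counts on both strands are omitted; row order is
        deterministic: (cell, chrom in genome order, bin, tag in H1/H2/untagged
        order).
        """
        grid = self.grid
        chrom_of = np.empty(grid.n_bins, dtype=object)
        start_of = np.empty(grid.n_bins, dtype=np.int64)
        end_of = np.empty(grid.n_bins, dtype=np.int64)
        for chrom in grid.genome.names:
            sl = grid.chrom_slice(chrom)
            chrom_of[sl] = chrom
            start_of[sl] = grid.starts[chrom]
            end_of[sl] = grid.ends[chrom]
        frames = []
        for cell in self.cell_ids:
            cc = self.cells[cell]
            for t in TAGS:
                mask = (cc.w[t] > 0) | (cc.c[t] > 0)
                if not mask.any():
                    continue
                idx = np.nonzero(mask)[0]
                frames.append(
                    pd.DataFrame(
                        {
                            "cell": cell,
                            "chrom": chrom_of[idx],
                            "start": start_of[idx],
                            "end": end_of[idx],
                            "hap": t,
                            "w": cc.w[t][idx],
                            "c": cc.c[t][idx],
                            "_bin": idx,
                            "_tag_order": TAGS.index(t),
                        }
                    )
                )
        if not frames:
            return pd.DataFrame(columns=["cell", "chrom", "start", "end", "hap", "w", "c"])
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["cell", "_bin", "_tag_order"], kind="mergesort")
        return df.drop(columns=["_bin", "_tag_order"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: BinGrid) -> "StrandBinCounts":
        required = ["cell", "chrom", "start", "end", "hap", "w", "c"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CountsValidationError(f"counts table missing columns: {missing}")
        out = cls(grid)
        if len(df) == 0:
            return out
        w = df["w"].to_numpy()
        c = df["c"].to_numpy()
        for col, arr in (("w", w), ("c", c)):
            bad = np.nonzero(arr < 0)[0]
            if bad.size:
                raise CountsValidationError(
                    f"negative {col!r} count at row {int(bad[0])}"
                )
        bad_hap = ~df["hap"].isin(TAGS)
        if bad_hap.any():
            row = int(np.nonzero(bad_hap.to_numpy())[0][0])
            raise CountsValidationError(f"unknown haplotype tag at row {row}")
        # map coordinates to global bin indices, erroring on off-grid rows
        bins = np.empty(len(df), dtype=np.int64)
        for chrom, sub in df.groupby("chrom", sort=False):
            grid.genome.check_chrom(str(chrom))
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = starts // grid.bin_size
            sl = grid.chrom_slice(str(chrom))
            n_chrom = sl.stop - sl.start
            ok = (
                (starts % grid.bin_size == 0)
                & (idx < n_chrom)
                & (ends == grid.ends[str(chrom)][np.minimum(idx, n_chrom - 1)])
            )
            if not ok.all():
                row = sub.index[np.nonzero(~ok)[0][0]]
                raise CountsValidationError(
                    f"row {row}: interval not on the {grid.bin_size}-bp grid"
                )
            bins[sub.index.to_numpy()] = idx + sl.start
        seen = set()
        cells_arr = df["cell"].astype(str).to_numpy()
        haps = df["hap"].to_numpy()
        for cell in pd.unique(cells_arr):
            out.cells[cell] = CellCounts.zeros(grid.n_bins)
        for i in range(len(df)):
            key = (cells_arr[i], int(bins[i]), haps[i])
            if key in seen:
                raise CountsValidationError(f"duplicate record at row {i}: {key}")
            seen.add(key)
            cc = out.cells[cells_arr[i]]
            cc.w[haps[i]][bins[i]] = w[i]
            cc.c[haps[i]][bins[i]] = c[i]
        return out

    def equals(self, other: "StrandBinCounts") -> bool:
        if self.cell_ids != other.cell_ids:
            return False
        for cell in self.cell_ids:
            a, b = self.cells[cell], other.cells[cell]
            for t in TAGS:
                if not (np.array_equal(a.w[t], b.w[t]) and np.array_equal(a.c[t], b.c[t])):
                    return False
        return True
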