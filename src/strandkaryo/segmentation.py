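"""Joint copy-number / strand-composition segmentation of single cells.

Per cell, five per-bin channels are built from the count table:

* total copy number (width-corrected read count scaled so the cell's modal
  disomic level maps to 2),
* Watson fraction W/(W+C) over all reads,
* haplotype-1 share of tagged reads,
* per-haplotype Watson fractions of tagged reads.

The stacked, per-cell-standardized channels are segmented with penalized
least-squares optimal partitioning (a BIC-style per-breakpoint cost, exact
dynamic program, deterministic and monotone in the penalty).  Each segment
is then assigned the maximum-likelihood integer state (copies per haplotype
and Watson/Crick composition of each copy) from an enumerated state space,
with ties broken toward the population consensus.  The consensus karyotype
is the per-bin modal copy number across QC-passing cells, which is what a
*de novo* abnormality is defined against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .config import RunConfig
from .counts import StrandBinCounts
from .genome import BinGrid

__all__ = [
    "NormalizedCell",
    "ConsensusKaryotype",
    "SegmentTrack",
    "normalize_counts",
    "build_consensus",
    "segment_cell",
    "StrandSegmenter",
    "penalized_breakpoints",
]

CHANNELS = ("tot", "f", "h", "f1", "f2")


class QCError(ValueError):
    pass


class ConsensusError(ValueError):
    pass


@dataclass
class NormalizedCell:
    """Per-bin signals for one cell, in copy-number / fraction units."""

    cell: str
    tot: np.ndarray   # total copy number estimate
    f: np.ndarray     # Watson fraction, all reads
    h: np.ndarray     # haplotype-1 share of tagged reads
    f1: np.ndarray    # Watson fraction of H1-tagged reads
    f2: np.ndarray    # Watson fraction of H2-tagged reads
    rpc: float        # reads per copy per full-width bin
    grid: BinGrid | None = None
    sigma: dict[str, float] = field(default_factory=dict)

    def channel_matrix(self) -> np.ndarray:
        """Stacked variance-stabilized channels.

        Copy number enters as a square root (constant variance across CN
        levels, lighter count-noise tails); fractions as arcsine square
        roots.  State predictions are transformed identically.
        """
        return np.vstack([
            np.sqrt(np.maximum(self.tot, 0.0)),
            _asin_sqrt(self.f), _asin_sqrt(self.h),
            _asin_sqrt(self.f1), _asin_sqrt(self.f2),
        ])


def _robust_sigma(x: np.ndarray) -> float:
    d = np.diff(x)
    mad = np.median(np.abs(d))
    return max(mad / (np.sqrt(2.0) * 0.6745), 1e-4)


def _asin_sqrt(x) -> np.ndarray:
    """Arcsine-square-root transform: stabilizes the variance of binomial
    fractions, whose raw variance p(1-p)/n would otherwise differ ~4-fold
    between WC (p ~ 0.5) and WW/CC (p near 0 or 1) chromosome states."""
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def normalize_counts(counts: StrandBinCounts, config: RunConfig | None = None,
                     cells: list[str] | None = None) -> dict[str, NormalizedCell]:
    """Build normalized per-bin signals for each (QC-passing) cell.

    The copy-number scale maps the cell's modal level on baseline-disomic
    chromosomes to 2.0 (robust median).  Watson fractions carry a +1
    pseudocount on each strand.  Raises :class:`QCError` for a zero-coverage
    cell.
    """
    config = config or RunConfig()
    grid = counts.grid
    genome = grid.genome
    widths = grid.all_widths() / grid.bin_size
    disomic = np.zeros(grid.n_bins, dtype=bool)
    baseline = np.zeros(grid.n_bins)
    for chrom in genome.names:
        sl = grid.chrom_slice(chrom)
        baseline[sl] = genome.homologues[chrom]
        if genome.homologues[chrom] == 2:
            disomic[sl] = True
    out = {}
    for cell in (cells if cells is not None else counts.cell_ids):
        cc = counts.cells[cell]
        w_all = cc.total_w().astype(float)
        c_all = cc.total_c().astype(float)
        tot_reads = w_all + c_all
        if tot_reads.sum() <= 0:
            raise QCError(f"cell {cell!r} has zero coverage")
        corrected = tot_reads / widths
        ref = corrected[disomic] if disomic.any() else corrected / (baseline / 2.0)
        level = np.median(ref)
        if level <= 0:
            raise QCError(f"cell {cell!r} has no usable coverage on baseline chromosomes")
        tot = corrected * (2.0 / level)
        f = (w_all + 1.0) / (tot_reads + 2.0)
        t1 = (cc.w["H1"] + cc.c["H1"]).astype(float)
        t2 = (cc.w["H2"] + cc.c["H2"]).astype(float)
        h = (t1 + 1.0) / (t1 + t2 + 2.0)
        f1 = (cc.w["H1"] + 1.0) / (t1 + 2.0)
        f2 = (cc.w["H2"] + 1.0) / (t2 + 2.0)
        nc = NormalizedCell(cell, tot, f, h, f1, f2, rpc=level / 2.0, grid=grid)
        # sigmas are estimated on the variance-stabilized scale used by the
        # segmentation cost, from robust successive differences
        nc.sigma = {
            ch: _robust_sigma(row) for ch, row in zip(CHANNELS, nc.channel_matrix())
        }
        out[cell] = nc
    return out


@dataclass
class ConsensusKaryotype:
    """Per-bin modal copy number of the population, split by haplotype."""

    b1: np.ndarray
    b2: np.ndarray
    mask: np.ndarray  # blacklisted bins (low population coverage)

    @property
    def btot(self) -> np.ndarray:
        return self.b1 + self.b2

    @classmethod
    def from_genome(cls, grid: BinGrid) -> "ConsensusKaryotype":
        """Consensus equal to the genome model's baseline homologue counts."""
        b1 = np.zeros(grid.n_bins, dtype=np.int64)
        b2 = np.zeros(grid.n_bins, dtype=np.int64)
        for chrom in grid.genome.names:
            sl = grid.chrom_slice(chrom)
            n_hom = grid.genome.homologues[chrom]
            b1[sl] = n_hom - n_hom // 2
            b2[sl] = n_hom // 2
        return cls(b1, b2, np.zeros(grid.n_bins, dtype=bool))


def build_consensus(counts: StrandBinCounts, config: RunConfig | None = None,
                    normalized: dict[str, NormalizedCell] | None = None) -> ConsensusKaryotype:
    """Per-bin modal integer copy number across QC-passing cells.

    The haplotype split of the modal total uses the population-pooled share
    of haplotype-tagged reads per bin, so a modelled trisomy (baseline 2+1)
    is recovered without reference to the genome model.  Bins whose
    population median coverage falls below ``mask_coverage_frac`` of the
    genome-wide median are masked.
    """
    config = config or RunConfig()
    cells = counts.qc_pass(config.min_fragments)
    if len(cells) < 3:
        raise ConsensusError(f"need at least 3 QC-passing cells, have {len(cells)}")
    if normalized is None:
        normalized = normalize_counts(counts, config, cells)
    grid = counts.grid
    n = grid.n_bins
    max_cn = config.max_copies + 2
    votes = np.zeros((max_cn + 1, n), dtype=np.int64)
    cov = np.zeros((len(cells), n))
    t1_pool = np.zeros(n)
    t2_pool = np.zeros(n)
    for i, cell in enumerate(cells):
        nc = normalized[cell]
        rounded = np.clip(np.round(nc.tot).astype(np.int64), 0, max_cn)
        votes[rounded, np.arange(n)] += 1
        cc = counts.cells[cell]
        cov[i] = cc.total_w() + cc.total_c()
        t1_pool += cc.w["H1"] + cc.c["H1"]
        t2_pool += cc.w["H2"] + cc.c["H2"]
    btot = votes.argmax(axis=0)
    share = (t1_pool + 1.0) / (t1_pool + t2_pool + 2.0)
    b1 = np.clip(np.round(btot * share).astype(np.int64), 0, btot)
    # smooth per chromosome: baseline copy number is constant over large
    # blocks, so isolated per-bin mode flips (small populations, overlapping
    # events) are noise by construction
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        btot[sl] = median_filter(btot[sl], size=5, mode="nearest")
        b1[sl] = median_filter(b1[sl], size=5, mode="nearest")
    b1 = np.clip(b1, 0, btot)
    b2 = btot - b1
    med = np.median(cov, axis=0)
    mask = med < config.mask_coverage_frac * np.median(med)
    return ConsensusKaryotype(b1, b2, mask)


# ---------------------------------------------------------------------------
# change-point engine


def penalized_breakpoints(z: np.ndarray, beta: float) -> list[int]:
    """Exact optimal partitioning of a stacked signal under a per-breakpoint cost.

    ``z`` is (channels, n); segment cost is the within-segment sum of squared
    deviations from the segment mean, summed over channels; each additional
    segment costs ``beta``.  Returns internal breakpoints (sorted bin indices
    ``b`` meaning a boundary between bins b-1 and b).
    """
    if beta <= 0:
        raise ValueError(f"penalty must be positive, got {beta}")
    k, n = z.shape
    if n == 0:
        return []
    S = np.zeros((k, n + 1))
    Q = np.zeros((k, n + 1))
    np.cumsum(z, axis=1, out=S[:, 1:])
    np.cumsum(z * z, axis=1, out=Q[:, 1:])
    F = np.empty(n + 1)
    F[0] = -beta
    ptr = np.zeros(n + 1, dtype=np.int64)
    for t in range(1, n + 1):
        seglen = np.arange(t, 0, -1, dtype=float)
        dq = Q[:, t, None] - Q[:, :t]
        ds = S[:, t, None] - S[:, :t]
        cost = (dq - ds * ds / seglen).sum(axis=0)
        vals = F[:t] + cost + beta
        best = int(np.argmin(vals))
        F[t] = vals[best]
        ptr[t] = best
    cuts = []
    t = n
    while t > 0:
        s = int(ptr[t])
        if s > 0:
            cuts.append(s)
        t = s
    return sorted(cuts)


# ---------------------------------------------------------------------------
# state space and assignment

_STATE_CACHE: dict[int, np.ndarray] = {}


def _state_table(max_copies: int) -> np.ndarray:
    """All (c1, c2, w1, w2) with c1+c2 <= max_copies, wk <= ck."""
    if max_copies not in _STATE_CACHE:
        rows = []
        for c1 in range(max_copies + 1):
            for c2 in range(max_copies + 1 - c1):
                for w1 in range(c1 + 1):
                    for w2 in range(c2 + 1):
                        rows.append((c1, c2, w1, w2))
        _STATE_CACHE[max_copies] = np.array(rows, dtype=np.int64)
    return _STATE_CACHE[max_copies]


def _predict_channels(states: np.ndarray, rpc: float, tag_fraction: float,
                      background_flip: float) -> np.ndarray:
    """Expected (tot, f, h, f1, f2) per state, matching the observation model
    (including the +1 pseudocounts used in :func:`normalize_counts`)."""
    c1, c2, w1, w2 = states.T.astype(float)
    b = background_flip
    c = c1 + c2
    w = w1 + w2
    d_tot = rpc          # reads per copy per bin, all reads
    d_tag = rpc * tag_fraction
    w_eff = w * (1 - b) + (c - w) * b
    tot = c
    f = (w_eff * d_tot + 1.0) / (c * d_tot + 2.0)
    h = (c1 * d_tag + 1.0) / (c * d_tag + 2.0)
    w1_eff = w1 * (1 - b) + (c1 - w1) * b
    w2_eff = w2 * (1 - b) + (c2 - w2) * b
    f1 = (w1_eff * d_tag + 1.0) / (c1 * d_tag + 2.0)
    f2 = (w2_eff * d_tag + 1.0) / (c2 * d_tag + 2.0)
    # same variance-stabilized scale as the observations
    return np.vstack([np.sqrt(tot), _asin_sqrt(f), _asin_sqrt(h),
                      _asin_sqrt(f1), _asin_sqrt(f2)]).T  # (n_states, 5)


STRAND_SYMBOLS = {True: "W", False: "C"}


def _strand_label(c1, c2, w1, w2) -> str:
    w = w1 + w2
    c = (c1 + c2) - w
    if c1 + c2 == 0:
        return "-"
    return "W" * int(w) + "C" * int(c)


@dataclass
class SegmentTrack:
    """Per-cell segmentation: copy-number and strand state per segment."""

    cell: str
    grid: BinGrid
    segments: pd.DataFrame  # chrom, start, end, start_bin, end_bin (global),
    #                         c1, c2, w1, w2, cn_total, strand_label, at_cap

    def cn_arrays(self) -> dict[str, np.ndarray]:
        n = self.grid.n_bins
        arrs = {k: np.zeros(n, dtype=np.int64) for k in ("c1", "c2", "w1", "w2")}
        for row in self.segments.itertuples():
            sl = slice(row.start_bin, row.end_bin)
            for k in arrs:
                arrs[k][sl] = getattr(row, k)
        return arrs


def segment_cell(norm: NormalizedCell, consensus: ConsensusKaryotype,
                 config: RunConfig | None = None,
                 penalty: float | None = None) -> SegmentTrack:
    """Segment one cell and assign integer states.

    Breakpoints come from the penalized change-point program on the stacked
    standardized channels; each segment then receives the state minimizing
    the standardized squared prediction error across channels, with an
    infinitesimal preference for the consensus state (minimal-change
    tie-break).  Adjacent segments with identical states are merged.
    """
    config = config or RunConfig()
    beta = config.penalty if penalty is None else penalty
    if beta <= 0:
        raise ValueError(f"penalty must be positive, got {beta}")
    grid = norm.grid
    if grid is None or grid.n_bins != len(norm.tot):
        raise ValueError("normalized signal carries no matching bin grid")
    states = _state_table(config.max_copies)
    preds = _predict_channels(states, norm.rpc, config.tag_fraction, config.background_flip)
    sig = np.array([norm.sigma[ch] for ch in CHANNELS])
    X = norm.channel_matrix()
    rows = []
    # Breakpoints are detected on the two high-signal channels only (total
    # copy number and Watson fraction): every event class moves at least one
    # of them, while the three tagged-read channels are individually weak and
    # would mostly contribute noise to the detection step.  All five channels
    # inform the state assigned to each segment.
    detect = [CHANNELS.index("tot"), CHANNELS.index("f")]
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        keep = ~consensus.mask[sl]
        x = X[:, sl][:, keep]
        nloc = x.shape[1]
        if nloc == 0:
            continue
        zd = x[detect]
        z = (zd - zd.mean(axis=1, keepdims=True)) / sig[detect, None]
        cuts = penalized_breakpoints(z, beta)
        local_idx = np.nonzero(keep)[0]
        bounds = [0] + cuts + [nloc]
        seg_states = []
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            mean = x[:, s:e].mean(axis=1)
            err = ((preds - mean[None, :]) / sig[None, :]) ** 2
            score = err.sum(axis=1) * (e - s)
            # tie-break toward the consensus state of the segment's first bin
            g0 = sl.start + local_idx[s]
            cons_state = (consensus.b1[g0], consensus.b2[g0])
            cons_rows = np.nonzero(
                (states[:, 0] == cons_state[0]) & (states[:, 1] == cons_state[1])
            )[0]
            score[cons_rows] -= 1e-9
            k = int(np.argmin(score))
            at_cap = mean[0] > np.sqrt(config.max_copies + 0.5)
            seg_states.append((s, e, states[k], at_cap))
        # merge adjacent identical states
        merged = []
        for s, e, st, cap in seg_states:
            if merged and np.array_equal(merged[-1][2], st):
                prev = merged.pop()
                merged.append((prev[0], e, st, prev[3] or cap))
            else:
                merged.append((s, e, st, cap))
        for s, e, st, cap in merged:
            g_start = sl.start + local_idx[s]
            g_end = sl.start + local_idx[e - 1] + 1
            c1, c2, w1, w2 = (int(v) for v in st)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(grid.starts[chrom][local_idx[s]]),
                    "end": int(grid.ends[chrom][local_idx[e - 1]]),
                    "start_bin": int(g_start),
                    "end_bin": int(g_end),
                    "c1": c1, "c2": c2, "w1": w1, "w2": w2,
                    "cn_total": c1 + c2,
                    "strand_label": _strand_label(c1, c2, w1, w2),
                    "at_cap": bool(cap),
                }
            )
    seg = pd.DataFrame(rows)
    return SegmentTrack(norm.cell, grid, seg)


class StrandSegmenter(TransformerMixin, BaseEstimator):
    """Population-aware per-cell segmentation as a scikit-learn transformer.

    ``fit`` learns the population consensus karyotype (and bin blacklist)
    from a :class:`StrandBinCounts`; ``transform`` segments each QC-passing
    cell against it and returns a dict of cell id -> :class:`SegmentTrack`.

    Parameters
    ----------
    penalty : per-breakpoint cost in standardized units.  Larger values give
        fewer breakpoints (monotonically).
    config : full :class:`RunConfig`; ``penalty`` overrides its field.
    consensus : optional precomputed consensus (e.g. the genome baseline),
        skipping the population estimate.
    """

    def __init__(self, penalty: float | None = None, config: RunConfig | None = None,
                 consensus: ConsensusKaryotype | None = None):
        self.penalty = penalty
        self.config = config
        self.consensus = consensus

    def _cfg(self) -> RunConfig:
        cfg = self.config or RunConfig()
        if self.penalty is not None:
            cfg = RunConfig(**{**cfg.to_dict(), "penalty": self.penalty})
        return cfg

    def fit(self, X: StrandBinCounts, y=None):
        cfg = self._cfg()
        if self.consensus is not None:
            self.consensus_ = self.consensus
        else:
            self.consensus_ = build_consensus(X, cfg)
        self.n_cells_ = len(X.cells)
        return self

    def transform(self, X: StrandBinCounts) -> dict[str, SegmentTrack]:
        if not hasattr(self, "consensus_"):
            raise ValueError("StrandSegmenter is not fitted")
        cfg = self._cfg()
        cells = X.qc_pass(cfg.min_fragments)
        normalized = normalize_counts(X, cfg, cells)
        tracks = {}
        for cell in cells:
            tracks[cell] = segment_cell(normalized[cell], self.consensus_, cfg)
        return tracks
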