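"""Sister-cell pair identification from template-strand records.

After one labelled division, the two daughters of a cell inherit opposite
template strands on every homologue, and any SCE that occurred in the parent
appears at the same breakpoint in both daughters with mirrored orientation.
These two signals — genome-wide template reciprocity and mirrored SCEs —
uniquely identify sister pairs among unrelated cells, whose per-homologue
template states agree only by a fair coin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .segmentation import ConsensusKaryotype, SegmentTrack

logger = logging.getLogger(__name__)

__all__ = [
    "StrandStateTrack",
    "PairScore",
    "infer_strand_states",
    "score_pair",
    "find_sister_pairs",
    "reciprocal_ca_check",
    "SisterPairFinder",
]

UNKNOWN = -1  # template not confidently assignable (copy number != 1)


@dataclass
class StrandStateTrack:
    """Per-homologue inferred template strands and SCE breakpoints.

    ``template[(chrom, hap)]`` holds one value per bin: 1 = Watson template,
    0 = Crick, -1 = unknown.  ``sces`` lists (chrom, hap, boundary_bin,
    orientation) with orientation 'W->C' or 'C->W' reading left to right.
    """

    cell: str
    grid: object
    template: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    sces: list[tuple[str, str, int, str]] = field(default_factory=list)

    def informative_fraction(self) -> float:
        known = 0
        total = 0
        for arr in self.template.values():
            known += int((arr != UNKNOWN).sum())
            total += len(arr)
        return known / total if total else 0.0


def infer_strand_states(track: SegmentTrack) -> StrandStateTrack:
    """Infer per-homologue template strands from a segment track.

    Bins where a haplotype carries exactly one copy have a well-defined
    template (the strand its reads map to); elsewhere the template is
    unknown.  A template switch between adjacent single-copy segments at
    constant copy number is reported as an SCE; switches coinciding with a
    copy-number change are not (those are CA breakpoints).  Chromosomes at
    copy number zero are skipped with a log message.
    """
    grid = track.grid
    out = StrandStateTrack(track.cell, grid)
    segs = track.segments
    for chrom in grid.genome.names:
        sub = segs[segs["chrom"] == chrom]
        sl = grid.chrom_slice(chrom)
        n = sl.stop - sl.start
        if len(sub) and (sub["cn_total"] == 0).all():
            logger.info("cell %s: %s has copy number 0, skipped", track.cell, chrom)
        for hap, cpk, wpk in (("H1", "c1", "w1"), ("H2", "c2", "w2")):
            tpl = np.full(n, UNKNOWN, dtype=np.int8)
            runs = []  # (start_local, end_local, ck, template)
            for row in sub.itertuples():
                s = row.start_bin - sl.start
                e = row.end_bin - sl.start
                ck = getattr(row, cpk)
                wk = getattr(row, wpk)
                t = UNKNOWN
                if ck == 1:
                    t = 1 if wk == 1 else 0
                    tpl[s:e] = t
                runs.append((s, e, ck, t))
            out.template[(chrom, hap)] = tpl
            for (s0, e0, c0, t0), (s1, e1, c1, t1) in zip(runs, runs[1:]):
                if c0 == 1 and c1 == 1 and t0 != UNKNOWN and t1 != UNKNOWN and t0 != t1:
                    orient = "W->C" if t0 == 1 else "C->W"
                    out.sces.append((chrom, hap, int(s1 + sl.start), orient))
    return out


@dataclass
class PairScore:
    """Reciprocity evidence for one candidate cell pair."""

    cell_a: str
    cell_b: str
    reciprocity: float
    mirrored_sces: int
    informative_fraction: float
    verdict: str  # sisters | unrelated | ambiguous


def _mirrored_sce_count(a: StrandStateTrack, b: StrandStateTrack,
                        tol_bins: int) -> int:
    count = 0
    used = set()
    for chrom, hap, pos, orient in a.sces:
        mirror = "C->W" if orient == "W->C" else "W->C"
        for j, (c2, h2, p2, o2) in enumerate(b.sces):
            if j in used:
                continue
            if c2 == chrom and h2 == hap and o2 == mirror and abs(p2 - pos) <= tol_bins:
                used.add(j)
                count += 1
                break
    return count


def score_pair(a: StrandStateTrack, b: StrandStateTrack,
               config: RunConfig | None = None) -> PairScore:
    """Score one cell pair for sisterhood.

    Reciprocity is the fraction of informative homologue-bins (template
    known in both cells) with opposite template state.  The verdict is
    ``sisters`` iff reciprocity >= 0.95 and either at least one mirrored SCE
    exists or reciprocity is exactly 1.0 over at least 90% of the genome's
    homologue-bins.  Note a cell scored against itself has reciprocity 0 —
    identity is not reciprocity.
    """
    config = config or RunConfig()
    if a.grid is not b.grid and getattr(a.grid, "n_bins", None) != getattr(b.grid, "n_bins", None):
        raise ValueError("pair members are on different bin grids")
    opposite = 0
    informative = 0
    total = 0
    for key, arr_a in a.template.items():
        arr_b = b.template.get(key)
        total += len(arr_a)
        if arr_b is None:
            continue
        both = (arr_a != UNKNOWN) & (arr_b != UNKNOWN)
        informative += int(both.sum())
        opposite += int((arr_a[both] != arr_b[both]).sum())
    reciprocity = opposite / informative if informative else 0.0
    coverage = informative / total if total else 0.0
    mirrored = _mirrored_sce_count(a, b, config.sce_tolerance_bins)
    if reciprocity >= config.reciprocity_threshold and (
        mirrored >= 1
        or (reciprocity == 1.0 and coverage >= config.full_reciprocity_coverage)
    ):
        verdict = "sisters"
    elif reciprocity >= config.reciprocity_threshold:
        verdict = "ambiguous"
    else:
        verdict = "unrelated"
    return PairScore(a.cell, b.cell, reciprocity, mirrored, coverage, verdict)


def find_sister_pairs(tracks, config: RunConfig | None = None,
                      min_informative: float = 0.2) -> list[PairScore]:
    """All-pairs sister search with greedy one-to-one matching.

    ``tracks`` maps cell id to :class:`StrandStateTrack` (or
    :class:`SegmentTrack`, converted on the fly).  Cells whose strand states
    are ambiguous genome-wide (informative fraction below
    ``min_informative``, e.g. doublets) are excluded with a log message.
    Candidate pairs with verdict ``sisters`` are matched greedily by
    descending reciprocity (ties broken by cell id), each cell in at most
    one pair.
    """
    config = config or RunConfig()
    states: dict[str, StrandStateTrack] = {}
    for cell in sorted(tracks):
        t = tracks[cell]
        st = t if isinstance(t, StrandStateTrack) else infer_strand_states(t)
        if st.informative_fraction() < min_informative:
            logger.info("cell %s excluded from pairing: ambiguous strand states", cell)
            continue
        states[cell] = st
    ids = sorted(states)
    candidates = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            score = score_pair(states[a], states[b], config)
            if score.verdict == "sisters":
                candidates.append(score)
    candidates.sort(key=lambda s: (-s.reciprocity, s.cell_a, s.cell_b))
    taken: set[str] = set()
    pairs = []
    for score in candidates:
        if score.cell_a in taken or score.cell_b in taken:
            continue
        taken.update((score.cell_a, score.cell_b))
        pairs.append(score)
    return pairs


def _drop_micro_runs(dev: np.ndarray, min_bins: int = 2) -> np.ndarray:
    """Zero out deviating runs shorter than ``min_bins`` (detection-limit
    noise must not turn a clean reciprocal chromosome into 'independent')."""
    out = dev.copy()
    n = len(out)
    s = 0
    while s < n:
        e = s
        while e < n and out[e] == out[s]:
            e += 1
        if out[s] != 0 and (e - s) < min_bins:
            out[s:e] = 0
        s = e
    return out


def reciprocal_ca_check(track_a: SegmentTrack, track_b: SegmentTrack,
                        consensus: ConsensusKaryotype) -> dict[str, str]:
    """Classify CA segregation within a sister pair, per affected chromosome.

    For each chromosome where either cell deviates from the consensus:
    ``reciprocal`` if the two cells' per-haplotype deltas sum to zero at
    every bin (a +1/-1 split of the same segment), ``shared`` if the deltas
    are identical (the event pre-dates the parent), else ``independent``.
    """
    grid = track_a.grid
    arrs_a = track_a.cn_arrays()
    arrs_b = track_b.cn_arrays()
    out = {}
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        verdicts = []
        for cpk, bkey in (("c1", "b1"), ("c2", "b2")):
            dev_a = _drop_micro_runs(arrs_a[cpk][sl] - getattr(consensus, bkey)[sl])
            dev_b = _drop_micro_runs(arrs_b[cpk][sl] - getattr(consensus, bkey)[sl])
            if not dev_a.any() and not dev_b.any():
                continue
            if np.array_equal(dev_a, -dev_b):
                verdicts.append("reciprocal")
            elif np.array_equal(dev_a, dev_b):
                verdicts.append("shared")
            else:
                verdicts.append("independent")
        if verdicts:
            if all(v == "reciprocal" for v in verdicts):
                out[chrom] = "reciprocal"
            elif all(v == "shared" for v in verdicts):
                out[chrom] = "shared"
            else:
                out[chrom] = "independent"
    return out


class SisterPairFinder:
    """Sister-pair detection with a scikit-learn-style ``fit_predict``."""

    def __init__(self, config: RunConfig | None = None,
                 min_informative: float = 0.2):
        self.config = config
        self.min_informative = min_informative

    def fit_predict(self, X) -> list[PairScore]:
        """``X``: dict of cell id -> SegmentTrack or StrandStateTrack."""
        self.pairs_ = find_sister_pairs(X, self.config, self.min_informative)
        return self.pairs_

    def get_params(self, deep=True):
        return {"config": self.config, "min_informative": self.min_informative}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
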