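"""CA classification: mapping per-cell segment tracks to the abnormality taxonomy.

Deviations of a cell's per-haplotype copy number from the population
consensus are merged into runs per (chromosome, haplotype) and mapped by a
decision tree:

1. a single deviation spanning the whole chromosome -> chromosome gain/loss;
2. many alternating switches between exactly two copy-number states on one
   haplotype -> chromothripsis (complex subclass);
3. more than two breakpoints not resolvable as a telomere-anchored block ->
   complex;
4. a telomere-anchored contiguous block of alternating gains/losses ->
   terminal multi-step;
5. an isolated telomere-anchored segment -> terminal gain/loss;
6. an isolated internal segment -> interstitial gain/loss.

Strand-informative annotations use the Watson/Crick composition of the
assigned states: a terminal gain whose gained copy sits on the strand
opposite to the host homologue's template is an inverted duplication (the
breakage-fusion-bridge signature); a gain with an even copy-number increment
split 1:1 between Watson and Crick is an isoacentric signature; isolated
events covering >90% of an arm are whole-arm; gains of two or more copies
are amplifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .config import RunConfig
from .counts import CellCounts
from .genome import BinGrid
from .segmentation import ConsensusKaryotype, SegmentTrack

__all__ = [
    "CACall",
    "ClassBreakdown",
    "classify_cell",
    "classify_population",
    "annotate_inverted_duplication",
    "detect_isoacentric_signature",
    "class_breakdown",
    "filter_min_size",
    "CAClassifier",
]

CLASS_LABELS = (
    "chromosome_gain", "chromosome_loss", "interstitial_gain", "interstitial_loss",
    "terminal_gain", "terminal_loss", "terminal_multistep", "complex",
    "chromothripsis",
)


@dataclass
class CACall:
    """One classified chromosomal abnormality."""

    cell: str
    chrom: str
    start: int
    end: int
    hap: str                 # H1 | H2 | unassigned
    cn_delta: int            # vs consensus; for multi-segment events, the
    #                          delta of the widest deviating segment
    strand_config: str       # same | opposite | balanced | mixed
    cls: str
    annotations: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return self.end - self.start

    def to_row(self) -> dict:
        return {
            "cell": self.cell, "chrom": self.chrom, "start": self.start,
            "end": self.end, "hap": self.hap, "cn_delta": self.cn_delta,
            "strand_config": self.strand_config, "class": self.cls,
            "annotations": ",".join(sorted(self.annotations)),
        }


def _bridge_gaps(dev: np.ndarray, max_gap: int = 1) -> np.ndarray:
    """Absorb micro-interruptions into their surroundings.

    A zero-deviation run of at most ``max_gap`` bins flanked by equal
    non-zero deviations is set to the flanking value: a single noise bin
    inside a long event must not shatter it into a complex call.
    """
    out = dev.copy()
    for _ in range(3):  # cascades are rare; a few passes reach a fixed point
        runs = _runs(out)
        changed = False
        for i in range(1, len(runs) - 1):
            s, e, v = runs[i]
            left = runs[i - 1][2]
            right = runs[i + 1][2]
            if (e - s) <= max_gap and left == right and left != 0 and v != left:
                out[s:e] = left
                changed = True
        if not changed:
            break
    return out


def _runs(values: np.ndarray):
    """Maximal runs of equal values: list of (start, end, value)."""
    out = []
    s = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[s]:
            out.append((s, i, values[s]))
            s = i
    return out


def _host_template(w_arr, c_arr, lo, hi, run_s, run_e, with_side=False):
    """Template strand of the single-copy host homologue flanking a run.

    Looks left then right of [run_s, run_e) within [lo, hi) for bins where
    the haplotype has exactly one copy; returns 'W', 'C' or None (with the
    side it was found on when ``with_side``).
    """
    cn = w_arr + c_arr
    for side, rng in (("left", range(run_s - 1, lo - 1, -1)),
                      ("right", range(run_e, hi))):
        for j in rng:
            if cn[j] == 1:
                tpl = "W" if w_arr[j] == 1 else "C"
                return (tpl, side) if with_side else tpl
    return (None, "left") if with_side else None


def _gain_strand_config(w_arr, c_arr, base_cn, template, s, e):
    """Strand configuration of gained copies over [s, e)."""
    if template is None:
        return "mixed"
    w = int(np.round(np.mean(w_arr[s:e])))
    c = int(np.round(np.mean(c_arr[s:e])))
    host_w = base_cn if template == "W" else 0
    host_c = base_cn if template == "C" else 0
    extra_w = w - host_w
    extra_c = c - host_c
    if extra_w < 0 or extra_c < 0:
        return "mixed"
    if extra_w == extra_c and extra_w > 0:
        return "balanced"
    same = extra_w if template == "W" else extra_c
    opp = extra_c if template == "W" else extra_w
    if opp == 0 and same > 0:
        return "same"
    if same == 0 and opp > 0:
        return "opposite"
    return "mixed"


def classify_cell(track: SegmentTrack, consensus: ConsensusKaryotype,
                  config: RunConfig | None = None) -> list[CACall]:
    """Map one cell's segment track to CA calls (decision tree above)."""
    config = config or RunConfig()
    grid = track.grid
    if len(consensus.b1) != grid.n_bins:
        raise ValueError("segment track and consensus are on different grids")
    arrs = track.cn_arrays()
    calls: list[CACall] = []
    K = config.chromothripsis_min_switches
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        lo, hi = sl.start, sl.stop
        cen_bin = grid.genome.centromeres[chrom] // grid.bin_size
        starts = grid.starts[chrom]
        ends = grid.ends[chrom]
        for hap, cpk, wpk, bkey in (("H1", "c1", "w1", "b1"), ("H2", "c2", "w2", "b2")):
            cn = arrs[cpk][sl]
            wk = arrs[wpk][sl]
            ck_cons = getattr(consensus, bkey)[sl]
            dev = _bridge_gaps(cn - ck_cons)
            if not dev.any():
                continue
            cn = ck_cons + dev  # bridged copy-number view
            runs = _runs(dev)
            dev_runs = [(s, e, d) for s, e, d in runs if d != 0]
            n = len(dev)

            def make_call(cls, s, e, delta, strand_config="mixed"):
                return CACall(
                    track.cell, chrom, int(starts[s]), int(ends[e - 1]),
                    hap, int(delta), strand_config, cls,
                )

            # (1) whole-chromosome deviation
            if len(runs) == 1 and runs[0][2] != 0:
                calls.append(make_call(
                    "chromosome_gain" if runs[0][2] > 0 else "chromosome_loss",
                    0, n, runs[0][2]))
                continue

            # (2) chromothripsis: sustained oscillation between two dominant
            # copy-number states across the affected span of this haplotype
            # (robust to isolated off-state bins, checked before grouping
            # because the retained segments between losses can be wide)
            full_s, full_e = dev_runs[0][0], dev_runs[-1][1]
            span_cn = cn[full_s:full_e]
            vals, vcounts = np.unique(span_cn, return_counts=True)
            if len(vals) >= 2:
                top2 = vals[np.argsort(vcounts)[-2:]]
                covered = span_cn[np.isin(span_cn, top2)]
                coverage = len(covered) / len(span_cn)
                n_switches = len(_runs(covered)) - 1
                if coverage >= 0.9 and n_switches >= K:
                    main = max(dev_runs, key=lambda r: r[1] - r[0])
                    calls.append(make_call(
                        "chromothripsis", full_s, full_e, main[2]))
                    continue

            # group deviating runs separated by at most ``gap`` unaffected
            # bins into one event; distant deviations are independent calls
            gap = config.event_group_gap_bins
            groups: list[list] = [[dev_runs[0]]]
            for r in dev_runs[1:]:
                if r[0] - groups[-1][-1][1] <= gap:
                    groups[-1].append(r)
                else:
                    groups.append([r])

            for grp in groups:
                span_s, span_e = grp[0][0], grp[-1][1]
                main = max(grp, key=lambda r: r[1] - r[0])
                main_delta = main[2]

                if len(grp) == 1:
                    s, e, d = grp[0]
                    template = _host_template(wk, cn - wk, 0, n, s, e) if d > 0 else None
                    strand = (
                        _gain_strand_config(wk, cn - wk, ck_cons[s], template, s, e)
                        if d > 0 else "same"
                    )
                    if s == 0 or e == n:
                        cls = "terminal_gain" if d > 0 else "terminal_loss"
                    else:
                        cls = "interstitial_gain" if d > 0 else "interstitial_loss"
                    call = make_call(cls, s, e, d, strand)
                    for a0, a1 in ((0, cen_bin), (cen_bin, n)):  # p and q arm
                        overlap = max(0, min(e, a1) - max(s, a0))
                        if a1 > a0 and overlap > config.whole_arm_frac * (a1 - a0):
                            call.annotations.add("whole_arm")
                    if d >= 2:
                        call.annotations.add("amplification")
                    calls.append(call)
                    continue

                # multiple deviating runs in one event group
                contiguous = bool(dev[span_s:span_e].all())
                telomeric = span_s == 0 or span_e == n
                if contiguous and telomeric:
                    calls.append(make_call(
                        "terminal_multistep", span_s, span_e, main_delta))
                else:
                    calls.append(make_call("complex", span_s, span_e, main_delta))
    return calls


def annotate_inverted_duplication(call: CACall, track: SegmentTrack) -> CACall:
    """Annotate a terminal gain whose gained copy is on the opposite strand."""
    if call.cls == "terminal_gain" and call.strand_config == "opposite":
        call.annotations.add("inverted_duplication")
    return call


def detect_isoacentric_signature(
    calls: list[CACall],
    track: SegmentTrack,
    counts: CellCounts | None = None,
    consensus: ConsensusKaryotype | None = None,
    config: RunConfig | None = None,
) -> tuple[list[CACall], tuple[int, int]]:
    """Flag balanced even-increment gains; return the (balanced, total) tally.

    A gain with copy-number increment >= 2 is tested for a 1:1 Watson/Crick
    split of the *gained* reads: observed W/C read counts in the interval are
    corrected for the expected contribution of baseline copies, and the
    excess is tested against 0.5 with a two-sided exact binomial test at
    ``isoacentric_alpha``.  An even increment that passes receives the
    ``isoacentric_signature`` annotation.  Without read counts the assigned
    integer strand states decide (balanced configuration == equal W and C
    extra copies).
    """
    config = config or RunConfig()
    grid = track.grid
    arrs = track.cn_arrays()
    n_total = 0
    n_balanced = 0
    for call in calls:
        if call.cn_delta < 2 or "gain" not in call.cls:
            continue
        n_total += 1
        balanced = False
        if counts is not None:
            sl = grid.chrom_slice(call.chrom)
            b0 = sl.start + call.start // grid.bin_size
            b1 = min(sl.start + -(-call.end // grid.bin_size), sl.stop)
            hk = "1" if call.hap == "H1" else "2"
            ok = "2" if call.hap == "H1" else "1"
            wk_full = arrs[f"w{hk}"][sl]
            ck_full = arrs[f"c{hk}"][sl]
            template, side = _host_template(
                wk_full, ck_full - wk_full, 0, sl.stop - sl.start,
                b0 - sl.start, b1 - sl.start, with_side=True)
            # the flanking template is only valid up to the first strand-state
            # change inside the interval (an SCE on the host homologue flips
            # it): test on the state-constant run adjacent to that flank
            key = wk_full[b0 - sl.start:b1 - sl.start] * 8 \
                + ck_full[b0 - sl.start:b1 - sl.start]
            bounds = [0] + [j for j in range(1, len(key)) if key[j] != key[j - 1]] \
                + [len(key)]
            if side == "left":
                r0, r1 = b0 + bounds[0], b0 + bounds[1]
            else:
                r0, r1 = b0 + bounds[-2], b0 + bounds[-1]
            b0, b1 = r0, r1
            w_obs = float((counts.total_w()[b0:b1]).sum())
            c_obs = float((counts.total_c()[b0:b1]).sum())
            ctot = (arrs["c1"] + arrs["c2"])[b0:b1].astype(float)
            copies = ctot.sum()
            if copies > 0 and w_obs + c_obs > 0:
                lam = (w_obs + c_obs) / copies  # reads per copy-bin
                base_k = getattr(consensus, f"b{hk}")[b0:b1] if consensus is not None \
                    else np.ones(b1 - b0, dtype=np.int64)
                gained = np.maximum(arrs[f"c{hk}"][b0:b1] - base_k, 0).astype(float)
                # host (non-gained) W copies: the other haplotype's state is
                # intact; the affected haplotype's template comes from the
                # flank
                host_w_k = base_k.astype(float) if template == "W" else 0.0
                host_w = arrs[f"w{ok}"][b0:b1].astype(float) + host_w_k
                bflip = config.background_flip
                host_c = (ctot - gained) - host_w
                exp_base_w = lam * (host_w * (1 - bflip) + host_c * bflip).sum()
                exp_base_c = lam * (ctot - gained).sum() - exp_base_w
                dw = max(w_obs - exp_base_w, 0.0)
                dc = max(c_obs - exp_base_c, 0.0)
                if dw + dc > 0:
                    # under a balanced gain E[dw - dc] = 0 with variance
                    # phi * (total reads): counts are overdispersed (NB
                    # variance = dispersion * mean) and the baseline
                    # subtraction contributes its own count noise
                    phi = max(config.nb_dispersion, 1.0)
                    z = (dw - dc) / np.sqrt(phi * (w_obs + c_obs))
                    p = 2.0 * stats.norm.sf(abs(z))
                    balanced = p >= config.isoacentric_alpha
        else:
            balanced = call.strand_config == "balanced"
        if balanced and call.cn_delta % 2 == 0:
            call.annotations.add("isoacentric_signature")
            n_balanced += 1
    return calls, (n_balanced, n_total)


def annotate_on_breakpoint(calls: list[CACall], locus: tuple[str, int],
                           grid: BinGrid, tolerance_bins: int = 1) -> list[CACall]:
    """Annotate calls having a breakpoint within +-tolerance of a locus."""
    chrom, pos = locus
    locus_bin = pos // grid.bin_size
    for call in calls:
        if call.chrom != chrom:
            continue
        length = grid.genome.lengths[chrom]
        bnds = [b for b in (call.start, call.end) if 0 < b < length]
        for b in bnds:
            if abs(b // grid.bin_size - locus_bin) <= tolerance_bins:
                call.annotations.add(f"on_breakpoint({chrom}:{pos})")
                break
    return calls


def filter_min_size(calls: list[CACall], min_size: int = 200_000) -> list[CACall]:
    """Drop calls smaller than the detection minimum (default 200 kb).

    Multi-segment classes (chromothripsis, complex, multi-step) are judged by
    their total affected span, which is what their interval stores.
    """
    return [c for c in calls if c.size >= min_size]


@dataclass
class ClassBreakdown:
    """Per-class counts and percentages, plus per-chromosome counts."""

    class_counts: dict[str, int]
    class_pct: dict[str, float]
    chrom_counts: dict[str, int]
    total: int

    def share(self, *classes: str) -> float:
        """Combined percentage of the given classes, to 1 decimal."""
        if self.total == 0:
            return 0.0
        n = sum(self.class_counts.get(c, 0) for c in classes)
        return round(100.0 * n / self.total, 1)


def class_breakdown(calls: list[CACall]) -> ClassBreakdown:
    """Count calls per class and per chromosome; percentages to 1 decimal."""
    class_counts: dict[str, int] = {}
    chrom_counts: dict[str, int] = {}
    for c in calls:
        class_counts[c.cls] = class_counts.get(c.cls, 0) + 1
        chrom_counts[c.chrom] = chrom_counts.get(c.chrom, 0) + 1
    total = len(calls)
    pct = {
        k: round(100.0 * v / total, 1) for k, v in class_counts.items()
    } if total else {}
    return ClassBreakdown(class_counts, pct, chrom_counts, total)


def annotation_share(calls: list[CACall], annotation: str,
                     within_class: str | None = None) -> float:
    """Percentage of calls carrying an annotation, to 1 decimal.

    ``annotation`` matches by prefix so positional annotations like
    ``on_breakpoint(chrX:133...)`` can be tallied as ``on_breakpoint``.
    """
    pool = [c for c in calls if within_class is None or c.cls == within_class]
    if not pool:
        return 0.0
    n = sum(1 for c in pool if any(a.startswith(annotation) for a in c.annotations))
    return round(100.0 * n / len(pool), 1)


def classify_population(
    tracks: dict[str, SegmentTrack],
    consensus: ConsensusKaryotype,
    counts=None,
    config: RunConfig | None = None,
    locus: tuple[str, int] | None = None,
) -> list[CACall]:
    """Classify every cell, applying all annotations and the size filter."""
    config = config or RunConfig()
    all_calls: list[CACall] = []
    for cell in sorted(tracks):
        track = tracks[cell]
        calls = classify_cell(track, consensus, config)
        for call in calls:
            annotate_inverted_duplication(call, track)
        cc = counts.cells.get(cell) if counts is not None else None
        calls, _ = detect_isoacentric_signature(calls, track, cc, consensus, config)
        if locus is not None:
            annotate_on_breakpoint(calls, locus, track.grid, config.locus_tolerance_bins)
        all_calls.extend(filter_min_size(calls, config.min_event_size))
    return all_calls


class CAClassifier(TransformerMixin, BaseEstimator):
    """Segment-track -> CA-call transformer (scikit-learn style).

    ``fit`` records the consensus karyotype; ``transform`` maps a dict of
    cell id -> :class:`SegmentTrack` to a list of :class:`CACall`.
    """

    def __init__(self, consensus: ConsensusKaryotype | None = None,
                 config: RunConfig | None = None,
                 locus: tuple[str, int] | None = None):
        self.consensus = consensus
        self.config = config
        self.locus = locus

    def fit(self, X=None, y=None, consensus: ConsensusKaryotype | None = None):
        self.consensus_ = consensus if consensus is not None else self.consensus
        if self.consensus_ is None:
            raise ValueError("CAClassifier needs a consensus karyotype")
        return self

    def transform(self, X: dict[str, SegmentTrack], counts=None) -> list[CACall]:
        if not hasattr(self, "consensus_"):
            self.fit()
        return classify_population(X, self.consensus_, counts,
                                   self.config, self.locus)
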