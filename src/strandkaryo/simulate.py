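"""Synthetic Strand-seq population generator.

Simulates binned, strand-resolved single-cell count tables with known ground
truth: per-homologue template-strand states with sister-chromatid exchanges
(SCEs), sister-cell pairs with reciprocal template inheritance, and injected
chromosomal-abnormality (CA) events drawn from the full taxonomy handled by
the classifier (whole-chromosome gains/losses, terminal and interstitial
segmental events, inverted duplications, terminal multi-step patterns,
chromothripsis, amplifications and balanced isoacentric gains).

The model: each haplotype of each chromosome carries an integer number of
copies per bin, and each copy emits reads on the Watson or Crick strand
according to its template.  A cell's sequencing depth is apportioned across
bins proportionally to local copy number (depth is a property of the library,
not of the genome), with negative-binomial noise, a small fraction of
strand-flipped reads (mapping noise) and a configurable fraction of reads
carrying their true haplotype tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .counts import CellCounts, StrandBinCounts
from .genome import BinGrid, GenomeModel, GenomeModelError

HAPS = ("H1", "H2")

EVENT_CLASSES = (
    "chromosome_gain", "chromosome_loss", "interstitial_gain", "interstitial_loss",
    "terminal_gain", "terminal_loss", "terminal_inverted_duplication",
    "terminal_multistep", "chromothripsis", "whole_arm", "amplification",
    "isoacentric_gain",
)

#: Default class mix for injected events.  Chosen to mirror the observed
#: spectrum in spontaneously micronucleated near-diploid cells: terminal
#: events dominate, ~86% of terminal gains are inverted duplications, losses
#: outnumber gains among whole-chromosome events, and complex classes
#: (multi-step, chromothripsis) form a substantial minority.
DEFAULT_CLASS_MIX = {
    "terminal_loss": 0.19,
    "terminal_gain": 0.03,
    "terminal_inverted_duplication": 0.19,
    "chromosome_loss": 0.15,
    "chromosome_gain": 0.015,
    "interstitial_gain": 0.02,
    "interstitial_loss": 0.02,
    "terminal_multistep": 0.23,
    "chromothripsis": 0.045,
    "whole_arm": 0.03,
    "amplification": 0.04,
    "isoacentric_gain": 0.03,
}


@dataclass
class CAEventSpec:
    """One injected abnormality.

    ``start``/``end`` are base-pair coordinates (0-based, half-open) of the
    affected interval; for ``terminal_multistep`` and ``chromothripsis`` the
    detailed geometry is in ``steps`` (list of (start, end, delta) tuples).
    ``strand_rule`` controls the template of gained copies relative to the
    host homologue: ``same``, ``opposite`` or ``balanced`` (half W, half C).
    """

    cls: str
    chrom: str
    hap: str
    start: int
    end: int
    delta: int
    strand_rule: str = "same"
    steps: list = field(default_factory=list)

    def validate(self, genome: GenomeModel) -> None:
        if self.cls not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.cls!r}")
        genome.check_chrom(self.chrom)
        length = genome.lengths[self.chrom]
        if not (0 <= self.start < self.end <= length):
            raise GenomeModelError(
                f"event interval [{self.start}, {self.end}) off {self.chrom}"
            )
        terminal = self.start == 0 or self.end == length
        if self.cls.startswith("terminal") and not terminal:
            raise ValueError(f"{self.cls} must extend to a telomere")
        if self.cls.startswith("interstitial") and terminal:
            raise ValueError(f"{self.cls} must touch neither telomere")
        if self.cls == "isoacentric_gain":
            if self.delta % 2 != 0:
                raise ValueError("isoacentric_gain requires an even copy-number delta")
            if self.strand_rule != "balanced":
                raise ValueError("isoacentric_gain requires the balanced strand rule")


def expected_call_for(spec: CAEventSpec, genome: GenomeModel) -> tuple[str, frozenset]:
    """Map an injected event to the (class, annotations) the classifier should emit."""
    cen = genome.centromeres[spec.chrom]
    length = genome.lengths[spec.chrom]
    arm_len = cen if spec.end <= cen else (length - cen if spec.start >= cen else None)
    covers_arm = arm_len is not None and (spec.end - spec.start) > 0.9 * arm_len
    ann = set()
    if spec.cls == "chromosome_gain":
        return "chromosome_gain", frozenset()
    if spec.cls == "chromosome_loss":
        return "chromosome_loss", frozenset()
    if spec.cls == "chromothripsis":
        return "chromothripsis", frozenset()
    if spec.cls == "terminal_multistep":
        return "terminal_multistep", frozenset()
    if spec.cls in ("interstitial_gain", "interstitial_loss"):
        if spec.delta >= 2:
            ann.add("amplification")
        return spec.cls, frozenset(ann)
    # remaining classes resolve to terminal gain/loss plus annotations
    if spec.cls == "whole_arm":
        base = "terminal_gain" if spec.delta > 0 else "terminal_loss"
        ann.add("whole_arm")
    elif spec.cls == "terminal_inverted_duplication":
        base = "terminal_gain"
        ann.add("inverted_duplication")
    elif spec.cls == "isoacentric_gain":
        base = "terminal_gain"
        ann.add("isoacentric_signature")
    elif spec.cls == "amplification":
        base = "terminal_gain" if spec.start == 0 or spec.end == length else "interstitial_gain"
    else:
        base = spec.cls
    if spec.delta >= 2:
        ann.add("amplification")
    if covers_arm and base in ("terminal_gain", "terminal_loss"):
        ann.add("whole_arm")
    return base, frozenset(ann)


@dataclass
class TruthEvent:
    spec: CAEventSpec
    expected_class: str
    expected_annotations: frozenset


@dataclass
class TruthTable:
    """Generator-side ledger: injected events, sibling structure, SCEs."""

    events: dict[str, list[TruthEvent]] = field(default_factory=dict)
    siblings: list[tuple[str, str]] = field(default_factory=list)
    sces: dict[str, list[tuple[str, str, int, str]]] = field(default_factory=dict)
    cn: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def validate(self, genome: GenomeModel) -> None:
        cells = set(self.events)
        for a, b in self.siblings:
            if a not in cells or b not in cells:
                raise ValueError(f"sibling pair ({a}, {b}) references unknown cell")
        for evs in self.events.values():
            for ev in evs:
                ev.spec.validate(genome)


class CellState:
    """Expected per-bin copy composition of one cell.

    ``w[hap]``/``c[hap]`` give expected copies emitting Watson/Crick reads
    per global bin; ``template[(chrom, hap)]`` is the boolean template array
    of the host homologue (True = Watson) with its SCE breakpoints.
    """

    def __init__(self, grid: BinGrid):
        self.grid = grid
        n = grid.n_bins
        self.w = {h: np.zeros(n) for h in HAPS}
        self.c = {h: np.zeros(n) for h in HAPS}
        self.template: dict[tuple[str, str], np.ndarray] = {}
        self.sces: list[tuple[str, str, int, str]] = []

    def copy(self) -> "CellState":
        out = CellState(self.grid)
        out.w = {h: self.w[h].copy() for h in HAPS}
        out.c = {h: self.c[h].copy() for h in HAPS}
        out.template = {k: v.copy() for k, v in self.template.items()}
        out.sces = list(self.sces)
        return out

    def cn(self, hap: str) -> np.ndarray:
        return self.w[hap] + self.c[hap]

    def cn_profile(self) -> dict[str, np.ndarray]:
        return {
            "c1": self.cn("H1").copy(), "c2": self.cn("H2").copy(),
            "w1": self.w["H1"].copy(), "w2": self.w["H2"].copy(),
        }


def make_template(grid: BinGrid, chrom: str, hap: str, rng,
                  sce_mean_per_homologue: float):
    """Random template array with Poisson-placed SCE switches at bin boundaries."""
    n = grid.n_bins_of(chrom)
    base = bool(rng.integers(2))
    k = rng.poisson(sce_mean_per_homologue) if sce_mean_per_homologue > 0 else 0
    k = min(k, n - 1)
    cuts = sorted(rng.choice(np.arange(1, n), size=k, replace=False)) if k else []
    tpl = np.empty(n, dtype=bool)
    state = base
    prev = 0
    for cut in list(cuts) + [n]:
        tpl[prev:cut] = state
        state = not state
        prev = cut
    sces = []
    state = base
    for cut in cuts:
        orient = "W->C" if state else "C->W"
        sces.append((chrom, hap, int(cut), orient))
        state = not state
    return tpl, sces


def baseline_cell(genome: GenomeModel, grid: BinGrid, rng,
                  sce_mean: float = 6.0) -> CellState:
    """Cell with baseline karyotype and random template states."""
    state = CellState(grid)
    total_len = sum(genome.lengths.values())
    for chrom in genome.names:
        sl = grid.chrom_slice(chrom)
        n_hom = genome.homologues[chrom]
        per_hap = {"H1": n_hom - n_hom // 2, "H2": n_hom // 2}
        rate = sce_mean * genome.lengths[chrom] / (2.0 * total_len)
        for hap in HAPS:
            tpl, sces = make_template(grid, chrom, hap, rng, rate)
            state.template[(chrom, hap)] = tpl
            state.sces.extend(sces)
            k = per_hap[hap]
            if k:
                state.w[hap][sl] += k * tpl
                state.c[hap][sl] += k * (~tpl)
    return state


def inject_event(state: CellState, spec: CAEventSpec, rng=None) -> CellState:
    """Apply an event to a cell state (in place) and return it."""
    grid = state.grid
    genome = grid.genome
    spec.validate(genome)
    sl = grid.chrom_slice(spec.chrom)
    tpl = state.template[(spec.chrom, spec.hap)]

    def bins_of(start, end):
        b0 = start // grid.bin_size
        b1 = min(-(-end // grid.bin_size), grid.n_bins_of(spec.chrom))
        return np.arange(sl.start + b0, sl.start + b1), np.arange(b0, b1)

    def apply_gain(start, end, d, rule):
        g, loc = bins_of(start, end)
        t = tpl[loc]
        if rule == "same":
            state.w[spec.hap][g] += d * t
            state.c[spec.hap][g] += d * (~t)
        elif rule == "opposite":
            state.w[spec.hap][g] += d * (~t)
            state.c[spec.hap][g] += d * t
        elif rule == "balanced":
            state.w[spec.hap][g] += d / 2.0
            state.c[spec.hap][g] += d / 2.0
        else:
            raise ValueError(f"unknown strand rule {rule!r}")

    def apply_loss(start, end, d=1):
        g, loc = bins_of(start, end)
        t = tpl[loc]
        state.w[spec.hap][g] = np.maximum(state.w[spec.hap][g] - d * t, 0)
        state.c[spec.hap][g] = np.maximum(state.c[spec.hap][g] - d * (~t), 0)

    if spec.cls in ("chromosome_gain", "terminal_gain", "interstitial_gain",
                    "amplification", "isoacentric_gain"):
        apply_gain(spec.start, spec.end, spec.delta, spec.strand_rule)
    elif spec.cls == "terminal_inverted_duplication":
        apply_gain(spec.start, spec.end, spec.delta, "opposite")
    elif spec.cls in ("chromosome_loss", "terminal_loss", "interstitial_loss"):
        apply_loss(spec.start, spec.end, abs(spec.delta))
    elif spec.cls == "whole_arm":
        if spec.delta > 0:
            apply_gain(spec.start, spec.end, spec.delta, spec.strand_rule)
        else:
            apply_loss(spec.start, spec.end, abs(spec.delta))
    elif spec.cls in ("terminal_multistep", "chromothripsis"):
        for s, e, d in spec.steps:
            if d > 0:
                apply_gain(s, e, d, spec.strand_rule)
            elif d < 0:
                apply_loss(s, e, abs(d))
    else:  # pragma: no cover
        raise ValueError(spec.cls)
    return state


# ---------------------------------------------------------------------------
# event geometry sampling


def _snap(grid: BinGrid, pos: float) -> int:
    return int(round(pos / grid.bin_size)) * grid.bin_size


def _log_uniform(rng, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_event(genome: GenomeModel, grid: BinGrid, cls: str, chrom: str,
                 hap: str, rng, config: RunConfig) -> CAEventSpec:
    """Draw the geometry of one event of class ``cls`` on (chrom, hap).

    Sizes are log-uniform between 1 Mb and the arm length (terminal multi-step
    and chromothripsis use larger minimum spans so their sub-segments stay
    resolvable); positions are uniform over allowed placements; everything is
    snapped to bin boundaries with a minimum size of ``min_event_bins`` bins.
    """
    length = genome.lengths[chrom]
    cen = genome.centromeres[chrom]
    bs = grid.bin_size
    min_size = config.min_event_bins * bs

    def arm_interval(arm):
        return (0, cen) if arm == "p" else (cen, length)

    if cls in ("chromosome_gain", "chromosome_loss"):
        delta = 1 if cls.endswith("gain") else -1
        return CAEventSpec(cls, chrom, hap, 0, length, delta)

    arm = "p" if rng.integers(2) == 0 else "q"
    a0, a1 = arm_interval(arm)
    arm_len = a1 - a0

    if cls == "whole_arm":
        delta = 1 if rng.integers(2) == 0 else -1
        return CAEventSpec(cls, chrom, hap, a0 if arm == "p" else a0,
                           cen if arm == "p" else length, delta)

    if cls in ("terminal_gain", "terminal_loss", "terminal_inverted_duplication",
               "isoacentric_gain") or cls == "amplification":
        size = _snap(grid, _log_uniform(rng, max(1e6, min_size), arm_len))
        size = max(min_size, min(size, arm_len))
        if cls == "amplification" and rng.integers(2) == 0:
            # interstitial amplification
            lo = a0 + bs if a0 == 0 else a0
            hi = a1 - bs if a1 == length else a1
            size = min(size, max(hi - lo - 2 * bs, min_size))
            start = _snap(grid, rng.uniform(lo, hi - size))
            start = min(max(start, lo), hi - size)
            spec_delta = int(rng.integers(2, 4))
            return CAEventSpec(cls, chrom, hap, start, start + size, spec_delta)
        start, end = (0, size) if arm == "p" else (length - size, length)
        if cls == "terminal_gain":
            return CAEventSpec(cls, chrom, hap, start, end, 1, "same")
        if cls == "terminal_loss":
            return CAEventSpec(cls, chrom, hap, start, end, -1)
        if cls == "terminal_inverted_duplication":
            return CAEventSpec(cls, chrom, hap, start, end, 1, "opposite")
        if cls == "isoacentric_gain":
            return CAEventSpec(cls, chrom, hap, start, end, 2, "balanced")
        return CAEventSpec(cls, chrom, hap, start, end, int(rng.integers(2, 4)), "same")

    if cls in ("interstitial_gain", "interstitial_loss"):
        lo = a0 + (bs if a0 == 0 else 0)
        hi = a1 - (bs if a1 == length else 0)
        size = _snap(grid, _log_uniform(rng, max(1e6, min_size), max((hi - lo) / 2, min_size + bs)))
        size = max(min_size, min(size, hi - lo - bs))
        start = _snap(grid, rng.uniform(lo, hi - size))
        start = min(max(start, lo), hi - size)
        delta = 1 if cls.endswith("gain") else -1
        return CAEventSpec(cls, chrom, hap, start, start + size, delta)

    if cls == "terminal_multistep":
        min_step = 10 * bs  # keep each step comfortably above the detection limit
        n_steps = int(rng.integers(2, 4))
        span = _snap(grid, _log_uniform(rng, n_steps * min_step * 1.5, arm_len))
        span = max(n_steps * min_step, min(span, arm_len))
        cuts = np.sort(rng.uniform(0, 1, n_steps - 1))
        widths = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * span
        widths = np.maximum(widths, min_step)
        widths = widths / widths.sum() * span
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        sign = 1 if rng.integers(2) == 0 else -1
        steps = []
        if arm == "q":
            base = length - span
            bounds = [_snap(grid, base + e) for e in edges]
            bounds[0], bounds[-1] = base, length
            order = range(n_steps - 1, -1, -1)  # outermost (telomeric) first
        else:
            bounds = [_snap(grid, e) for e in edges]
            bounds[0], bounds[-1] = 0, span
            order = range(n_steps)
        for i in range(1, n_steps):  # keep boundaries strictly increasing
            bounds[i] = min(max(bounds[i], bounds[i - 1] + bs), bounds[-1] - (n_steps - i) * bs)
        for j, i in enumerate(order):
            s, e = bounds[i], bounds[i + 1]
            steps.append((int(s), int(e), sign * (1 if j % 2 == 0 else -1) * 1))
        start = min(s for s, _, _ in steps)
        end = max(e for _, e, _ in steps)
        return CAEventSpec(cls, chrom, hap, start, end,
                           steps[0][2], "same", steps=steps)

    if cls == "chromothripsis":
        span = _snap(grid, _log_uniform(rng, max(30e6, arm_len * 0.5), arm_len))
        span = min(span, arm_len)
        start, end = (0, span) if arm == "p" else (length - span, length)
        n_bkp = int(rng.integers(10, 15))
        n_seg = n_bkp + 1
        inner = np.sort(rng.choice(
            np.arange(start // bs + 2, end // bs - 1), size=n_bkp, replace=False)) * bs
        bounds = np.concatenate([[start], inner, [end]]).astype(int)
        lose_first = bool(rng.integers(2))
        steps = []
        for i in range(n_seg):
            lost = (i % 2 == 0) == lose_first
            if lost:
                steps.append((int(bounds[i]), int(bounds[i + 1]), -1))
        return CAEventSpec(cls, chrom, hap, start, end, -1, "same", steps=steps)

    raise ValueError(f"cannot sample class {cls!r}")


# ---------------------------------------------------------------------------
# count rendering


def expected_counts(state: CellState, depth: float, config: RunConfig):
    """Expected read counts per (tag, strand, bin), before noise.

    Returns a dict with keys (hap, 'W'|'C') for tagged reads and
    ('untagged', 'W'|'C'), each a float array over global bins.  Total
    expectation sums to ``depth`` regardless of injected events.
    """
    widths = state.grid.all_widths().astype(float)
    b = config.background_flip
    tau = config.tag_fraction
    mass = {}
    total = 0.0
    for hap in HAPS:
        w_eff = state.w[hap] * (1 - b) + state.c[hap] * b
        c_eff = state.c[hap] * (1 - b) + state.w[hap] * b
        mass[(hap, "W")] = w_eff * widths
        mass[(hap, "C")] = c_eff * widths
        total += mass[(hap, "W")].sum() + mass[(hap, "C")].sum()
    if total <= 0:
        raise ValueError("cell has no genomic material")
    scale = depth / total
    out = {}
    for hap in HAPS:
        out[(hap, "W")] = mass[(hap, "W")] * scale * tau
        out[(hap, "C")] = mass[(hap, "C")] * scale * tau
    out[("untagged", "W")] = sum(mass[(h, "W")] for h in HAPS) * scale * (1 - tau)
    out[("untagged", "C")] = sum(mass[(h, "C")] for h in HAPS) * scale * (1 - tau)
    return out


def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draw with variance = phi * mean (phi > 1)."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if phi <= 1.0 + 1e-9:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = mean[pos] / (phi - 1.0)
    p = 1.0 / phi
    out[pos] = rng.negative_binomial(r, p)
    return out


def render_counts(state: CellState, depth: float, rng, config: RunConfig,
                  noise: str = "nb") -> CellCounts:
    exp = expected_counts(state, depth, config)
    cc = CellCounts.zeros(state.grid.n_bins)
    for (tag, strand), mean in sorted(exp.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if noise == "nb":
            vals = _nb_draw(rng, mean, config.nb_dispersion)
        elif noise == "none":
            vals = np.round(mean).astype(np.int64)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        if strand == "W":
            cc.w[tag] += vals
        else:
            cc.c[tag] += vals
    return cc


# ---------------------------------------------------------------------------
# population-level simulation


def simulate_sister_pair(parent: CellState, outcome: str, rng,
                         config: RunConfig | None = None):
    """Divide ``parent`` into two daughters with reciprocal template states.

    Every homologue's template in daughter B is the complement of daughter A,
    so parental SCEs appear at identical breakpoints with mirrored
    orientation.  ``outcome`` adds a reciprocal CA: ``'bfb'`` (dicentric
    bridge breakage: inverted duplication in A, terminal loss in B at the
    same breakpoint) or ``'acentric'`` (the acentric fragment segregates into
    A: +1 in A, -1 in B); ``'none'`` adds nothing.
    """
    config = config or RunConfig()
    grid = parent.grid
    genome = grid.genome
    a = parent.copy()
    b = CellState(grid)
    for (chrom, hap), tpl in a.template.items():
        sl = grid.chrom_slice(chrom)
        comp = ~tpl
        b.template[(chrom, hap)] = comp
        # daughter B has the same copy structure, complemented templates
        tot = a.w[hap][sl] + a.c[hap][sl]
        b.w[hap][sl] = np.where(comp, tot, 0.0)
        b.c[hap][sl] = np.where(comp, 0.0, tot)
    for chrom, hap, pos, orient in a.sces:
        mirrored = "C->W" if orient == "W->C" else "W->C"
        b.sces.append((chrom, hap, pos, mirrored))

    events_a: list[CAEventSpec] = []
    events_b: list[CAEventSpec] = []
    if outcome != "none":
        chrom = genome.names[int(rng.integers(len(genome.names)))]
        hap = HAPS[int(rng.integers(2))]
        length = genome.lengths[chrom]
        cen = genome.centromeres[chrom]
        arm = "p" if rng.integers(2) == 0 else "q"
        arm_len = cen if arm == "p" else length - cen
        size = _snap(grid, _log_uniform(rng, max(2e6, 2 * grid.bin_size), arm_len))
        size = max(2 * grid.bin_size, min(size, arm_len))
        start, end = (0, size) if arm == "p" else (length - size, length)
        gain_cls = "terminal_inverted_duplication" if outcome == "bfb" else "terminal_gain"
        gain = CAEventSpec(gain_cls, chrom, hap, start, end, 1,
                           "opposite" if outcome == "bfb" else "same")
        loss = CAEventSpec("terminal_loss", chrom, hap, start, end, -1)
        inject_event(a, gain)
        inject_event(b, loss)
        events_a.append(gain)
        events_b.append(loss)
    return a, b, (events_a, events_b)


def _draw_events(genome, grid, rng, config, class_mix):
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n_events = rng.poisson(config.event_rate)
    occupied = set()
    specs = []
    for _ in range(n_events):
        for _attempt in range(20):
            chrom = genome.names[int(rng.integers(len(genome.names)))]
            hap = HAPS[int(rng.integers(2))]
            if (chrom, hap) not in occupied:
                break
        else:
            continue
        occupied.add((chrom, hap))
        cls = classes[int(rng.choice(len(classes), p=probs))]
        specs.append(sample_event(genome, grid, cls, chrom, hap, rng, config))
    return specs


def simulate_population(
    genome: GenomeModel,
    grid: BinGrid,
    n_cells: int,
    depth: float | None = None,
    event_rate: float | None = None,
    sister_fraction: float = 0.0,
    seed: int = 0,
    config: RunConfig | None = None,
    class_mix: dict | None = None,
    noise: str = "nb",
    pair_outcomes: tuple = ("none", "bfb", "acentric"),
) -> tuple[StrandBinCounts, TruthTable]:
    """Simulate a Strand-seq population with ground truth.

    ``sister_fraction`` of the cells are generated as sister pairs sharing a
    parent (reciprocal templates, mirrored SCEs, and optionally a reciprocal
    CA drawn from ``pair_outcomes``); the remainder are singletons.  Injected
    events follow ``class_mix`` at ``event_rate`` events per cell (Poisson),
    at most one event per (chromosome, haplotype).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= sister_fraction <= 1.0):
        raise ValueError(f"sister_fraction must be in [0, 1], got {sister_fraction}")
    config = config or RunConfig()
    depth = config.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    rate = config.event_rate if event_rate is None else event_rate
    cfg = RunConfig(**{**config.to_dict(), "event_rate": rate})
    class_mix = class_mix or DEFAULT_CLASS_MIX
    rng = np.random.default_rng(seed)

    n_pairs = int(n_cells * sister_fraction) // 2
    n_single = n_cells - 2 * n_pairs
    counts = StrandBinCounts(grid)
    truth = TruthTable()

    def register(cell_id, state, specs):
        truth.events[cell_id] = [
            TruthEvent(s, *expected_call_for(s, genome)) for s in specs
        ]
        truth.sces[cell_id] = list(state.sces)
        truth.cn[cell_id] = state.cn_profile()
        counts.add_cell(cell_id, render_counts(state, depth, rng, cfg, noise))

    for i in range(n_pairs):
        parent = baseline_cell(genome, grid, rng, cfg.sce_mean)
        outcome = pair_outcomes[int(rng.integers(len(pair_outcomes)))]
        a, b, (ev_a, ev_b) = simulate_sister_pair(parent, outcome, rng, cfg)
        for st in (a, b):
            for spec in _draw_events(genome, grid, rng, cfg, class_mix):
                occupied = {(e.chrom, e.hap) for e in (ev_a + ev_b)}
                if (spec.chrom, spec.hap) in occupied:
                    continue
                inject_event(st, spec)
                (ev_a if st is a else ev_b).append(spec)
        id_a, id_b = f"p{i:04d}a", f"p{i:04d}b"
        register(id_a, a, ev_a)
        register(id_b, b, ev_b)
        truth.siblings.append((id_a, id_b))

    for i in range(n_single):
        state = baseline_cell(genome, grid, rng, cfg.sce_mean)
        specs = _draw_events(genome, grid, rng, cfg, class_mix)
        for spec in specs:
            inject_event(state, spec)
        register(f"s{i:04d}", state, specs)

    truth.validate(genome)
    return counts, truth
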