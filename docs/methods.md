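# Methods

This note documents the models and numerical choices behind `strandkaryo`:
what the synthetic generator emulates, how segmentation and classification
work, how sister pairs are scored, how the agent-based rate model is
specified and fitted, and what the defaults mean. It also states what the
synthetic tests do and do not establish about real data.

## Observation model

The unit of observation is a binned, strand-resolved single-cell count
table: for every (cell, 200-kb bin, haplotype tag ∈ {H1, H2, untagged})
pair, the number of reads mapping to the Watson and Crick strands.
Coordinates are 0-based half-open (BED convention) on a genome model of
chromosome lengths, centromere positions and baseline homologue counts
(2 for disomic chromosomes, 3 for a modelled trisomy, split 2+1 across
haplotypes).

In Strand-seq, each chromatid's reads map to the strand of its retained
template, so a homologue in template state W emits Watson reads; a disomic
chromosome is in state WW, WC or CC depending on which templates the two
homologues retained. A fraction of reads can be assigned to a haplotype
(in real data via phased heterozygous SNPs); this is modelled as a
per-read tag with an informative fraction (default 15%) rather than
explicit SNP positions — bin-level tagged counts carry the same signal.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream component is validated.

* **Depth.** Each cell receives an expected total of 285,000 mapped
  fragments (the typical yield of an intermediate-coverage Strand-seq
  library), apportioned across bins proportionally to local copy number ×
  bin width and normalized so that the expected total equals the depth
  regardless of injected events — sequencing depth is a property of the
  library, not of the genome. Per-cell QC flags cells below 50,000
  fragments.
* **Count noise.** Per (bin, haplotype, strand, tag) counts are negative
  binomial with variance = 2 × mean (dispersion configurable). No
  quantitative noise model for Strand-seq counts is established in the
  literature; this dispersion is a deliberately conservative choice and is
  a free knob in the config.
* **Strand noise.** 2% of a bin's reads are assigned to the wrong strand
  (mapping noise), so template states must be inferred, never read off.
* **Templates and SCEs.** Each homologue draws a random initial template;
  SCE counts are Poisson with mean 6 per cell genome-wide, positions
  uniform on bin boundaries. The rate only needs to make sister pairing
  informative; no empirical per-cell SCE rate is assumed.
* **Sister pairs.** A parent's two daughters receive complementary
  templates on every homologue, so each parental SCE appears at the same
  breakpoint in both daughters with mirrored orientation. Daughter-private
  SCEs default to 0 (`daughter_sce_mean`); with the labelled-division
  readout, parental SCEs dominate the record and private SCEs would only
  blur reciprocity. Optionally a reciprocal CA is segregated into the
  daughters: a BFB bridge breakage (inverted duplication in one daughter,
  terminal loss of the same interval and haplotype in the other) or an
  asymmetrically segregating acentric fragment (+1/−1).
* **Events.** Injected CA classes cover the full taxonomy: whole-chromosome
  gain/loss, terminal gain/loss, terminal inverted duplication (gain in
  opposite strand orientation), interstitial gain/loss, whole-arm events,
  amplifications (Δ ≥ +2), balanced isoacentric gains (even Δ split 1:1
  between W and C), terminal multi-step patterns (2–3 alternating
  telomere-anchored steps of ≥ 2 Mb each) and chromothripsis (10–14
  breakpoints on one haplotype oscillating between two copy-number
  states). Sizes are log-uniform between 1 Mb and the arm length; at most
  one event per (chromosome, haplotype); the default class mix mirrors the
  observed spontaneous spectrum in near-diploid micronucleated cells
  (terminal events dominant, ~86% of terminal gains inverted, losses more
  frequent than gains among whole-chromosome events).

The generator reproduces binned counts only: it does not model GC or
replication-timing bias, mappability holes, library-specific background
or read-level artifacts. Consequently, passing recovery tests demonstrate
the correctness and calibration of the algorithms under the stated noise
model, not performance on real libraries, where bin blacklisting and
library QC carry more weight.

## Segmentation

Per cell, five per-bin channels are derived: total copy number (read count
corrected for bin width, scaled so the cell's modal level on
baseline-disomic chromosomes maps to 2.0), the Watson fraction of all
reads, the haplotype-1 share of tagged reads, and the per-haplotype Watson
fractions of tagged reads (all fractions with +1 pseudocounts).

Channels are variance-stabilized — square root for copy number, arcsine
square root for fractions — because raw fraction noise differs ~4-fold
between WC (p ≈ 0.5) and WW/CC (p near 0/1) chromosome states and raw
count noise grows with copy number; a single per-channel robust sigma
(median absolute successive difference / (√2 · 0.6745)) is then valid
genome-wide.

Breakpoints are found by exact penalized least-squares optimal
partitioning on the stacked (copy number, Watson fraction) channels; the
three tagged-read channels are individually weak and would contribute
mostly noise to detection, but all five channels inform the state
assigned to each segment. The per-breakpoint penalty (default β = 10 in
standardized units) is deterministic and monotone: more penalty, fewer
breakpoints. Each segment receives the maximum-likelihood state from the
enumerated space of (copies per haplotype, Watson-template copies per
haplotype) with total copy number capped at 6 (`at_cap` flags saturation),
ties broken toward the population consensus (minimal-change principle).
Bins whose population median coverage falls below 25% of the genome
median are blacklisted (a proxy for unmappable regions).

**Detection operating point.** β = 10 places the 50% detection point at a
single bin for one-copy events at default depth (measured: ~65% at 200 kb,
~93% at 400 kb, ≥ 99% at 1 Mb), at the cost of roughly one to two false
breakpoint clusters per cell, almost all spanning ≤ 3 bins with |Δ| = 1.
This floor is intrinsic to the counting noise: a 2–3-bin one-copy change
and a coincident count/strand fluctuation are statistically
indistinguishable at ~100 reads per bin. Raising β (or filtering calls
with `filter_min_size`) trades sensitivity at the limit for specificity;
both knobs are exposed.

## Consensus karyotype

De novo means "deviating from the population". The consensus is the
per-bin modal integer copy number across QC-passing cells (≥ 3 required,
≥ 20 recommended), split across haplotypes by the population-pooled share
of haplotype-tagged reads, then median-filtered (width 5) per chromosome:
baseline copy number is constant over large blocks, so isolated per-bin
mode flips — which otherwise turn into calls in *every* cell — are noise
by construction. A trisomic chromosome is recovered as baseline 3 (2+1)
without reference to the genome model. The mode is robust to shared
subclonal events at the few-percent level.

## Classification

Per (chromosome, haplotype), the deviation of assigned copy number from
the consensus is processed as follows:

1. single-bin interruptions inside a deviating run are bridged (noise must
   not shatter one event into "complex");
2. a single run covering the whole chromosome → chromosome gain/loss;
3. chromothripsis: over the affected span, ≥ 5 switches (configurable)
   between the two dominant copy-number states covering ≥ 90% of the span
   — checked before any grouping because the retained segments between
   losses can be wide;
4. remaining deviating runs are grouped into events across gaps of at most
   2 bins; distant deviations are independent calls;
5. per group: a single telomere-anchored run → terminal gain/loss; a
   single internal run → interstitial gain/loss; multiple contiguous runs
   anchored at a telomere → terminal multi-step; anything else → complex.

Annotations: `whole_arm` for isolated events covering > 90% of an arm;
`amplification` for Δ ≥ +2; `inverted_duplication` for terminal gains
whose gained copy sits on the strand opposite to the host homologue's
template (the host template is read from the nearest flanking single-copy
segment); `on_breakpoint(chrom:pos)` for calls with a breakpoint within
±1 bin of a user-supplied locus (targeted-DSB experiments);
`isoacentric_signature` for gains with an even increment whose gained
reads split 1:1 between Watson and Crick.

The isoacentric balance test subtracts the expected read contribution of
the non-gained copies (using the flanking host template, restricted to
the state-constant run adjacent to that flank, since an SCE inside the
gained interval flips the host template) and tests the Watson−Crick
difference of the excess at variance φ × (total reads) — counts are
overdispersed and the baseline subtraction contributes its own noise, so
a raw exact binomial would be anti-conservative. The per-event α is 0.01:
truly unbalanced gains sit many standard deviations away (p ≈ 0), so the
α only sets the false-*negative* rate on true balanced gains, and 1% keeps
cohort tallies like 18-of-18 achievable.

Calls below 200 kb (the practical detection limit; multi-segment classes
judged by total span) are filtered by default.

## Sister-pair identification

Per-homologue template states are read from segments where the haplotype
carries exactly one copy (elsewhere the template is undefined); a template
switch between adjacent single-copy segments at constant copy number is an
SCE with an orientation; switches coinciding with copy-number changes are
CA breakpoints, not SCEs.

A pair is scored by reciprocity — the fraction of informative
homologue-bins (template known in both cells) with opposite states — and
by mirrored SCEs (same chromosome and haplotype, positions within ±1 bin,
opposite orientations). Verdict `sisters` requires reciprocity ≥ 0.95 and
either ≥ 1 mirrored SCE or perfect reciprocity over ≥ 90% of homologue-
bins. Under the null, unrelated cells agree per homologue with probability
1/2, so reciprocity concentrates near 0.5 and the joint requirement makes
false sisters vanishingly rare; a cell scored against itself has
reciprocity 0. Matching is greedy by descending reciprocity with
deterministic tie-breaks; cells with ambiguous genome-wide strand states
(informative fraction < 0.2, e.g. doublets) are excluded with a logged
reason. Within a verified pair, per-chromosome CA segregation is
`reciprocal` when the two cells' per-haplotype deltas cancel bin-wise,
`shared` when identical, else `independent`; deviating runs under 2 bins
are ignored there so detection-limit noise cannot mask a clean reciprocal
chromosome.

## Agent-based CA-rate model

Cells occupy two interphase states (normal, micronucleated) and carry a
fixed-duration cell-cycle clock (the measured median; default 16 h — only
the time axis depends on it), a micronucleus status and a heritable CA
status. At clock expiry a cell arrests (and is removed) or divides via a
normal, laggard (lagging-chromosome) or bridge (chromatin-bridge) mitosis
with state-conditional probabilities. A division creates two daughters;
with a mitosis-type-dependent probability one daughter (uniform choice)
is micronucleated — parents that are themselves micronucleated are 9.5×
as likely to produce one (capped at 1) — and with probability R(mitosis
type) one daughter (uniform choice) acquires a de novo CA. Runs start at
50 cells and stop at 50,000, by which point the micronucleus frequency
has plateaued; identical clocks collapse the event queue into
division waves, which the implementation vectorizes.

Default wild-type transition values use the measured main quantities
(laggards 6.2% and bridges 5.1% of mitoses; daughter micronucleation
32.3%/17.2% for laggard/bridge; the 9.5× propagation factor). The arrest
probabilities (2% normal, 30% micronucleated), the micronucleated-cell
mitosis mix (error rates doubled) and the normal-mitosis micronucleation
baseline (4%) are package choices where no published value exists; the
defaults are therefore approximate, and the *stability* of the simulated
equilibrium — not its exact level — is the tested property.

**Rate estimation.** Given observed de novo CA frequencies by compartment,
the rates R are estimated by bound-constrained Nelder–Mead minimization of
the simulated sum of squared errors, averaging a fixed set of replicate
seeds per evaluation (common random numbers make each start's objective
deterministic; distinct starts use distinct replicate seeds so that the
final residual-weighted average cancels rather than shares simulation
noise), with a polish restart from each optimum. The reported estimate is
the average of per-start optima weighted by inverse residual error.

Which compartments define the fit is configurable. The two-compartment
choice matching what sequencing directly observes (CA frequency in
micronucleated vs normal-nucleus cells) leaves the three rates only
jointly constrained — two observables
cannot pin three parameters, which is visible as per-start spread. The
simulation therefore also reports CA frequencies of daughters stratified
by the parent's mitosis type; fitting those three compartments identifies
all three rates, and the recovery checks use them. Because CA status is
heritable and cumulative, targets must be generated at the same stop
population as the fitting simulations.

The basal rate is the deterministic weighted average Σ f_t R_t of the
per-type rates with the mitosis-type frequencies (frequencies must sum
to 1 within 1e-9).

## Exact and resampling statistics

Fisher's exact test (two-sided, point-probability construction) and the
exact two-sided binomial test (sum of outcome probabilities not exceeding
the observed one) are delegated to scipy, and are verified against
brute-force enumeration oracles for every configuration with ≤ 12
observations in the test suite. Per-chromosome CA enrichment tests each
chromosome's call count against the total with a one-sided binomial null
proportional to its homologue count (each homologue equally likely to
acquire a CA; the homologue weighting, which matters for trisomies, can
be switched off), with Benjamini–Hochberg adjustment by default
(Bonferroni selectable) and flags at adjusted p < 0.05. The loss/gain
bias test flips each event's direction with probability 1/2 (optionally
within strata) and reports the fraction of permutations reaching the
observed |losses − gains| plus its Monte-Carlo error; its closed form is
the two-sided binomial tail, which the permutation p converges to.

## Problem sizes used in validation

The behavioral checks run at: 500 cells (4 × 125 seeds) for per-class
classification recovery (≥ 90% per class); 20 seeded populations of 100
cells with 10 planted pairs for sister-pair precision (1.0) and recall
(≥ 0.9); 60 replicates per size for the detection-limit sweep; stop
population 5,000 with 5 optimization starts for rate recovery (±0.05 per
component); and the full 50 → 50,000 run for plateau stability (CV of the
final 10 samples < 0.1, sampled every 4 h). Unit tests use a reduced
3-chromosome genome (90 Mb, 450 bins) with depth 50,000, preserving
per-bin coverage.

## Known limitations

* Breakpoints are reported at bin resolution; no sub-bin refinement and
  no junction (read-pair) evidence.
* The generator's noise model is parametric; real-library artifacts
  (mappability, GC, variable BrdU incorporation) are out of scope, and
  the blacklist mechanism is exercised only lightly by synthetic data.
* Sensitivity and specificity cross over near the 200-kb single-bin
  limit; single-bin calls should be treated as candidates.
* Complex-event subclassification beyond chromothripsis (e.g. separating
  focal bridge-breakage oscillations from other clustered patterns) uses
  the arm-contiguity and oscillation rules only.
* The ABM ignores spatial structure, explicit chromosome identity and
  fitness differences between karyotypes; arrest is absorbing.
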