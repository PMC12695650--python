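"""Exact and resampling statistics for CA analyses.

Fisher's exact test (two-sided, point-probability construction), the
two-sided exact binomial test (sum of outcome probabilities not exceeding
that of the observed count), per-chromosome CA enrichment under the
equal-probability-per-homologue null with multiple-testing control, and a
sign-flip permutation test for the chromosome loss/gain bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel

__all__ = [
    "fisher_exact_2x2",
    "binom_exact_two_sided",
    "chromosome_enrichment",
    "loss_gain_bias_test",
    "EnrichmentResult",
    "BiasTestResult",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    ``table`` is ((a, b), (c, d)) of non-negative integers with at least one
    non-zero margin.  The two-sided p sums the hypergeometric probabilities
    of all tables (with the observed margins) whose point probability does
    not exceed the observed one.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("test undefined for an all-zero table")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def binom_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood construction)."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


@dataclass
class EnrichmentResult:
    unit: str
    observed: int
    expected_prop: float
    p_raw: float
    p_adj: float
    enriched: bool


def chromosome_enrichment(
    calls,
    genome: GenomeModel,
    method: str = "bh",
    weight_by_consensus: bool = True,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-chromosome CA enrichment under an equal-probability-per-homologue null.

    Each chromosome's call count is tested (one-sided binomial, greater)
    against the total call count with null proportion equal to its share of
    homologues — weighted by the modelled homologue count (so a trisomy
    contributes 3/total) when ``weight_by_consensus``, else 1/n_chromosomes.
    Adjustment: Benjamini-Hochberg (``"bh"``) or ``"bonferroni"``.
    """
    call_list = list(calls)
    if not call_list:
        raise ValueError("need at least one call")
    chrom_of = [c.chrom if hasattr(c, "chrom") else c for c in call_list]
    n_total = len(chrom_of)
    counts = {c: 0 for c in genome.names}
    for chrom in chrom_of:
        genome.check_chrom(chrom)
        counts[chrom] += 1
    if weight_by_consensus:
        total_w = genome.total_homologues
        null_prop = {c: genome.homologues[c] / total_w for c in genome.names}
    else:
        null_prop = {c: 1.0 / len(genome.names) for c in genome.names}
    raw = [
        sps.binomtest(counts[c], n_total, null_prop[c], alternative="greater").pvalue
        for c in genome.names
    ]
    how = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if how is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(raw, alpha=alpha, method=how)
    return [
        EnrichmentResult(c, counts[c], null_prop[c], float(p), float(q), bool(q < alpha))
        for c, p, q in zip(genome.names, raw, adj)
    ]


@dataclass
class BiasTestResult:
    p_value: float
    mc_error: float
    observed_imbalance: int
    n_perm: int


def loss_gain_bias_test(
    losses: int,
    gains: int,
    n_perm: int = 100_000,
    stratification=None,
    seed: int = 0,
) -> BiasTestResult:
    """Permutation test for a loss/gain direction bias.

    The null flips each event's direction with probability 1/2 (within
    strata if ``stratification`` labels are given, which leaves the flip
    distribution unchanged but documents the exchangeability unit); the
    p-value is the fraction of permutations whose absolute loss-gain
    imbalance reaches the observed one.  The closed-form equivalent is the
    two-sided binomial tail of ``losses`` out of ``losses+gains`` at 0.5.
    """
    if losses < 0 or gains < 0 or losses + gains < 1:
        raise ValueError("need non-negative counts with at least one event")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; the p-value is unstable")
    n = losses + gains
    observed = abs(losses - gains)
    rng = np.random.default_rng(seed)
    if stratification is not None:
        labels = np.asarray(stratification)
        if len(labels) != n:
            raise ValueError("stratification labels must cover every event")
        flips = np.zeros(n_perm, dtype=np.int64)
        for lab in np.unique(labels):
            k = int((labels == lab).sum())
            flips += rng.binomial(k, 0.5, size=n_perm)
    else:
        flips = rng.binomial(n, 0.5, size=n_perm)
    imbalance = np.abs(2 * flips - n)
    p = float((imbalance >= observed).mean())
    mc = float(np.sqrt(max(p * (1 - p), 1.0 / n_perm) / n_perm))
    return BiasTestResult(p, mc, observed, n_perm)
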