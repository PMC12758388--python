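"""Cohort-level statistics for coordinated-splicing analyses.

Includes the permutation test for per-gene enrichment of splicing events,
the within-gene paired delta-PSI correlation with its random-pairing
control, the relative block-event enrichment across RBP knockdowns, and
set-overlap bookkeeping.  All stochastic operations take an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .block_caller import ExonPair
from .io_formats import RBPEventTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "EnrichmentResult",
    "permutation_gene_enrichment",
    "paired_dpsi_correlation",
    "random_pairing_control",
    "rbp_block_enrichment",
    "overlap_report",
]


@dataclass
class PermutationResult:
    observed_multi_gene_count: int
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    k: int


@dataclass
class EnrichmentResult:
    rbp: str
    cell_type: str
    fraction_block: float
    relative_enrichment: Optional[float]  # None for zero-block RBPs
    excluded: bool = False


def permutation_gene_enrichment(
    n_events: int,
    gene_ids: Sequence[str],
    observed_multi_gene_count: Optional[int] = None,
    k: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for enrichment of genes carrying >= k events.

    Each permutation drops ``n_events`` events uniformly at random (with
    replacement across events, i.e. multinomially) onto the quantified
    genes; the statistic is the number of genes receiving >= k events.
    The one-sided p-value is (1 + #{null >= observed}) / (1 + n_perm).
    When ``observed_multi_gene_count`` is None it is derived from
    ``gene_ids`` interpreted as the per-event gene assignment list.
    """
    if n_events < 1:
        raise ValueError("need >= 1 event")
    unique_genes = sorted(set(gene_ids))
    n_genes = len(unique_genes)
    if n_genes < 2:
        raise ValueError("need >= 2 genes")
    if observed_multi_gene_count is None:
        _, counts = np.unique(np.asarray(gene_ids), return_counts=True)
        observed_multi_gene_count = int((counts >= k).sum())
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_genes, size=(n_perm, n_events))
    hits = np.zeros((n_perm, n_genes), dtype=np.int32)
    np.add.at(hits, (np.repeat(np.arange(n_perm), n_events), draws.ravel()), 1)
    null = (hits >= k).sum(axis=1)
    p = (1 + int((null >= observed_multi_gene_count).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_multi_gene_count=observed_multi_gene_count,
        null_distribution=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        k=k,
    )


def paired_dpsi_correlation(pairs: Sequence[ExonPair]) -> float:
    """Pearson r of delta-PSI over within-gene exon pairs.

    Each unordered pair contributes once, oriented lower ladder index
    first.  Raises when either margin has zero variance (r undefined).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs")
    a = np.array([p.dpsi_a for p in pairs])
    b = np.array([p.dpsi_b for p in pairs])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _ = sps.pearsonr(a, b)
    return float(r)


def random_pairing_control(
    dpsi_pool: Sequence[float], n_pairs: int, seed: int = 0
) -> float:
    """Pearson r over randomly paired delta-PSI values (genes ignored).

    Pairs are drawn uniformly from the whole pool, without replacement
    within a pair (with replacement across pairs).  Raises for a
    zero-variance draw.
    """
    pool = np.asarray(dpsi_pool, dtype=float)
    if pool.size < 2:
        raise ValueError("pool must hold >= 2 values")
    rng = np.random.default_rng(seed)
    a_idx = rng.integers(0, pool.size, size=n_pairs)
    b_idx = rng.integers(0, pool.size - 1, size=n_pairs)
    b_idx = b_idx + (b_idx >= a_idx)  # never pair a value with itself
    a, b = pool[a_idx], pool[b_idx]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in random pairing; r undefined")
    r, _ = sps.pearsonr(a, b)
    return float(r)


def rbp_block_enrichment(
    tables: Sequence[RBPEventTable],
) -> list[EnrichmentResult]:
    """Relative enrichment of block events per RBP knockdown.

    fraction = block events / all events for each RBP; relative
    enrichment = fraction / median fraction over *qualifying* RBPs (those
    with at least one regulated block exon).  Zero-total RBPs are
    excluded and logged; zero-block RBPs are reported but flagged and
    excluded from the median.
    """
    results: list[EnrichmentResult] = []
    fractions: list[float] = []
    for t in tables:
        total = t.n_total_events
        if total == 0:
            logger.warning("RBP %s (%s): zero total events; excluded", t.rbp, t.cell_type)
            continue
        frac = t.n_block_events / total
        qualifies = t.n_block_events >= 1
        if qualifies:
            fractions.append(frac)
        results.append(
            EnrichmentResult(
                rbp=t.rbp,
                cell_type=t.cell_type,
                fraction_block=frac,
                relative_enrichment=None,
                excluded=not qualifies,
            )
        )
    if not fractions:
        raise ValueError("no RBP with >= 1 block event")
    med = float(np.median(fractions))
    for r in results:
        if not r.excluded:
            r.relative_enrichment = r.fraction_block / med
    return results


def overlap_report(set_a: Sequence, set_b: Sequence) -> dict[str, float]:
    """Exact intersection counts between two id sets."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(inter),
        "fraction_of_a": len(inter) / len(a) if a else float("nan"),
    }
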