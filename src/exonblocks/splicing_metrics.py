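"""Per-intron splicing efficiency (SPI) and intron-removal order (F_UPFI).

SPI for an intron is spliced / (spliced + unspliced), where *spliced*
reads carry a gap exactly matching the intron and *unspliced* reads cross
an exon-intron boundary contiguously with at least ``min_overhang``
(default 3) nt on both sides of the boundary.  Both junctions of the
intron are pooled.  The statistic targets nascent (chromatin-associated)
RNA, where partially spliced molecules are abundant.

F_UPFI for an internal exon is the fraction of order-informative reads in
which the exon's transcriptionally upstream flanking intron was removed
while the downstream one was still present.  A read is informative when it
reports an unambiguous spliced/unspliced status for *both* flanking
introns and the two statuses differ.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .block_caller import ExonBlock
from .core_model import GeneModel, GenomicInterval
from .read_ops import AlignedRead

logger = logging.getLogger(__name__)

__all__ = [
    "SPIRecord",
    "DiffSPIRecord",
    "FUPFIRecord",
    "IntronCategory",
    "compute_spi",
    "differential_spi",
    "categorize_introns",
    "spi_histograms",
    "compute_fupfi",
]

DEFAULT_MIN_COV = 10
DEFAULT_MIN_OVERHANG = 3
DEFAULT_MIN_INFORMATIVE = 5

SPI_P_THRESHOLD = 0.01
SPI_DELTA_THRESHOLD = 0.10


@dataclass
class SPIRecord:
    """Splicing-per-intron measurement for one intron in one sample."""

    intron: GenomicInterval
    spliced_reads: int
    unspliced_reads: int
    spi: Optional[float]
    low_coverage: bool
    condition: str = ""
    replicate: str = ""

    @property
    def total(self) -> int:
        return self.spliced_reads + self.unspliced_reads


@dataclass
class DiffSPIRecord:
    intron: GenomicInterval
    spi_ctrl: float
    spi_treat: float
    delta_spi: float
    p_value: float
    significant: bool


@dataclass
class FUPFIRecord:
    """Pairwise intron-order statistic around one exon."""

    exon_index: int
    n_up_first: int
    n_down_first: int
    f_upfi: Optional[float]


class IntronCategory:
    BLOCK_INTERNAL = "block_internal"
    BLOCK_FLANKING = "block_flanking"
    OTHER = "other"


# ---------------------------------------------------------------------------


def _read_intron_status(
    read: AlignedRead,
    intron: GenomicInterval,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> Optional[str]:
    """'spliced', 'unspliced', or None (ambiguous) for one read and intron.

    Spliced: a gap exactly matching the intron.  Unspliced: contiguous
    aligned coverage across the 5' or 3' exon-intron boundary with
    ``min_overhang`` nt on both sides.
    """
    if read.chrom != intron.chrom:
        return None
    if read.has_gap(intron.start, intron.end, tolerance=0):
        return "spliced"
    for boundary in (intron.start, intron.end):
        if read.covers_contiguously(boundary - min_overhang, boundary + min_overhang):
            return "unspliced"
    return None


def compute_spi(
    intron: GenomicInterval,
    reads: Sequence[AlignedRead],
    min_cov: int = DEFAULT_MIN_COV,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    condition: str = "",
    replicate: str = "",
) -> SPIRecord:
    """Splicing efficiency of one intron from boundary and junction reads."""
    spliced = unspliced = 0
    for read in reads:
        status = _read_intron_status(read, intron, min_overhang)
        if status == "spliced":
            spliced += 1
        elif status == "unspliced":
            unspliced += 1
    total = spliced + unspliced
    low = total < min_cov
    return SPIRecord(
        intron=intron,
        spliced_reads=spliced,
        unspliced_reads=unspliced,
        spi=None if low else spliced / total,
        low_coverage=low,
        condition=condition,
        replicate=replicate,
    )


def differential_spi(
    ctrl: Sequence[SPIRecord],
    treat: Sequence[SPIRecord],
    p_threshold: float = SPI_P_THRESHOLD,
    delta_threshold: float = SPI_DELTA_THRESHOLD,
) -> Optional[DiffSPIRecord]:
    """Differential splicing efficiency of one intron between conditions.

    ``ctrl``/``treat`` are replicate-level records for the same intron.
    delta_spi is mean(treat) - mean(ctrl) over replicate SPI values; the
    p-value comes from a two-sided test on the pooled 2x2 spliced/unspliced
    count table (chi-square with continuity correction, or Fisher's exact
    test when any cell is below 5).  Returns None (logged) when the intron
    is low-coverage in either condition.
    """
    if not ctrl or not treat:
        raise ValueError("need >= 1 replicate per condition")
    intron = ctrl[0].intron
    for r in list(ctrl) + list(treat):
        if (r.intron.chrom, r.intron.start, r.intron.end) != (
            intron.chrom, intron.start, intron.end,
        ):
            raise ValueError("records mix introns")
    if any(r.low_coverage for r in ctrl) or any(r.low_coverage for r in treat):
        logger.info(
            "intron %s:%d-%d low-coverage; excluded from differential SPI",
            intron.chrom, intron.start, intron.end,
        )
        return None
    table = np.array(
        [
            [sum(r.spliced_reads for r in ctrl), sum(r.unspliced_reads for r in ctrl)],
            [sum(r.spliced_reads for r in treat), sum(r.unspliced_reads for r in treat)],
        ]
    )
    if (table < 5).any():
        _, p = sps.fisher_exact(table, alternative="two-sided")
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=True)
    delta = statistics.fmean(r.spi for r in treat) - statistics.fmean(
        r.spi for r in ctrl
    )
    return DiffSPIRecord(
        intron=intron,
        spi_ctrl=statistics.fmean(r.spi for r in ctrl),
        spi_treat=statistics.fmean(r.spi for r in treat),
        delta_spi=delta,
        p_value=float(p),
        significant=p <= p_threshold and abs(delta) >= delta_threshold,
    )


def categorize_introns(
    blocks: Sequence[ExonBlock],
    models: Mapping[str, GeneModel],
) -> dict[tuple[str, int], str]:
    """Label every intron of every gene relative to called blocks.

    Keys are (gene_id, intron_index) with intron i lying between ladder
    exons i and i+1.  Internal introns lie between block members; flanking
    introns are a block's immediate upstream/downstream neighbors; all
    others are 'other'.  An intron internal to one block and flanking an
    adjacent one stays internal (logged).
    """
    labels: dict[tuple[str, int], str] = {}
    for gene_id, model in models.items():
        for i in range(len(model.introns)):
            labels[(gene_id, i)] = IntronCategory.OTHER
    flanking: set[tuple[str, int]] = set()
    internal: set[tuple[str, int]] = set()
    for block in blocks:
        model = models[block.gene_id]
        first, last = block.member_indices[0], block.member_indices[-1]
        for i in range(first, last):
            internal.add((block.gene_id, i))
        if first - 1 >= 0:
            flanking.add((block.gene_id, first - 1))
        if last < len(model.introns):
            flanking.add((block.gene_id, last))
    for key in flanking:
        labels[key] = IntronCategory.BLOCK_FLANKING
    for key in internal:
        if key in flanking:
            logger.info(
                "intron %s:%d internal to one block and flanking another; "
                "labelled internal", *key,
            )
        labels[key] = IntronCategory.BLOCK_INTERNAL
    return labels


def spi_histograms(
    records: Sequence[SPIRecord],
    categories: Mapping[tuple[str, int], str],
    intron_keys: Mapping[tuple[str, int, int], tuple[str, int]],
    bin_width: float = 0.05,
) -> dict[str, np.ndarray]:
    """Normalized SPI frequency histogram per intron category.

    ``intron_keys`` maps (chrom, start, end) of an intron to its
    (gene_id, intron_index) key in ``categories``.  Each non-empty
    category's histogram sums to 1; empty categories yield all zeros.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values: dict[str, list[float]] = {
        IntronCategory.BLOCK_INTERNAL: [],
        IntronCategory.BLOCK_FLANKING: [],
        IntronCategory.OTHER: [],
    }
    for rec in records:
        if rec.spi is None:
            continue
        key = intron_keys.get((rec.intron.chrom, rec.intron.start, rec.intron.end))
        if key is None:
            continue
        values[categories.get(key, IntronCategory.OTHER)].append(rec.spi)
    out: dict[str, np.ndarray] = {}
    for cat, vals in values.items():
        hist, _ = np.histogram(vals, bins=edges)
        total = hist.sum()
        out[cat] = hist / total if total else hist.astype(float)
    return out


def compute_fupfi(
    exon_index: int,
    reads: Sequence[AlignedRead],
    model: GeneModel,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> FUPFIRecord:
    """Fraction of reads in which the upstream flanking intron spliced first.

    Raises for first/last ladder exons, which lack a flanking intron pair.
    Reads with both introns spliced or both unspliced carry no order
    information and are dropped; ``f_upfi`` is None below
    ``min_informative`` informative reads.
    """
    up = model.upstream_intron(exon_index)
    down = model.downstream_intron(exon_index)
    if up is None or down is None:
        raise ValueError(
            f"exon {exon_index} of {model.gene_id} has no flanking intron pair"
        )
    n_up_first = n_down_first = 0
    for read in reads:
        s_up = _read_intron_status(read, up, min_overhang)
        s_down = _read_intron_status(read, down, min_overhang)
        if s_up == "spliced" and s_down == "unspliced":
            n_up_first += 1
        elif s_up == "unspliced" and s_down == "spliced":
            n_down_first += 1
    total = n_up_first + n_down_first
    return FUPFIRecord(
        exon_index=exon_index,
        n_up_first=n_up_first,
        n_down_first=n_down_first,
        f_upfi=n_up_first / total if total >= min_informative else None,
    )
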