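"""Coordinated exon-block calling from differential exon-inclusion tables.

An *exon block* is a maximal run of >= 2 consecutive ladder exons that all
changed significantly and coordinately: every consecutive pair shares the
sign of its delta-PSI and differs by at most ``pair_tolerance`` (the
chain-wise rule; an all-pairs variant is available by flag).  The
*block-skipping junction* is the exon-exon junction formed when the exons
immediately upstream of and downstream from the block are spliced directly
together, excising the whole block; it is the genomic interval of the
excised region and is absent for blocks touching a gene terminus.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core_model import GeneModel, GenomicInterval
from .io_formats import DiffExonRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceThresholds",
    "ExonPair",
    "ExonBlock",
    "BlockSummary",
    "filter_significant",
    "pair_exons",
    "adjacency_summary",
    "call_blocks",
    "call_blocks_all_genes",
    "derive_skip_junction",
    "frame_preserving",
    "summarize_blocks",
]


@dataclass(frozen=True)
class SignificanceThresholds:
    """Thresholds for calling an exon significantly changed and for chaining.

    Defaults: probability >= 0.9 and |delta PSI| >= 0.10 for significance
    (boundaries inclusive); neighboring exons chain into a block when their
    delta-PSI values differ by at most 0.02.
    """

    min_probability: float = 0.9
    min_abs_delta_psi: float = 0.10
    pair_tolerance: float = 0.02

    def __post_init__(self) -> None:
        for name in ("min_probability", "min_abs_delta_psi", "pair_tolerance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ExonPair:
    """An unordered pair of significant exons within one gene."""

    gene_id: str
    exon_a: int
    exon_b: int
    dpsi_a: float
    dpsi_b: float
    adjacent: bool
    similar: bool

    def __post_init__(self) -> None:
        if not self.exon_a < self.exon_b:
            raise ValueError("exon_a must be the lower ladder index")


@dataclass
class ExonBlock:
    """A maximal run of >= 2 coordinately changing adjacent exons."""

    gene_id: str
    member_indices: tuple[int, ...]
    internal_introns: list[Optional[GenomicInterval]]
    flank_up_intron: Optional[GenomicInterval]
    flank_down_intron: Optional[GenomicInterval]
    skip_junction: Optional[GenomicInterval]
    mean_delta_psi: float
    frame_preserving: bool
    all_constitutive_fraction: float

    def __post_init__(self) -> None:
        if len(self.member_indices) < 2:
            raise ValueError("a block needs >= 2 member exons")
        for a, b in zip(self.member_indices, self.member_indices[1:]):
            if b != a + 1:
                raise ValueError("member indices must be consecutive")
        if len(self.internal_introns) != len(self.member_indices) - 1:
            raise ValueError("internal introns must number members - 1")

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class BlockSummary:
    n_blocks: int = 0
    n_genes: int = 0
    n_member_exons: int = 0
    fraction_two_exon: float = float("nan")
    median_size_larger: float = float("nan")
    mean_size_larger: float = float("nan")
    mean_abs_delta_psi: float = float("nan")
    fraction_frame_preserving: float = float("nan")
    constitutive_fraction_block: float = float("nan")
    constitutive_fraction_single: float = float("nan")


# ---------------------------------------------------------------------------


def filter_significant(
    records: Sequence[DiffExonRecord],
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> list[DiffExonRecord]:
    """Keep exons with probability and |delta PSI| at or above threshold.

    delta_psi is the replicate-mean treatment - control value; a negative
    value means the exon is more skipped upon treatment.
    """
    kept = [
        r
        for r in records
        if r.probability >= thresholds.min_probability
        and abs(r.delta_psi) >= thresholds.min_abs_delta_psi
    ]
    n_skipped = sum(1 for r in kept if r.delta_psi < 0)
    logger.info(
        "significant exons: %d of %d (%d more skipped upon treatment)",
        len(kept), len(records), n_skipped,
    )
    return kept


def pair_exons(
    significant: Sequence[DiffExonRecord],
    model: GeneModel,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> list[ExonPair]:
    """Emit all unordered pairs of significant exons within one gene.

    ``adjacent`` means consecutive collapsed-ladder indices; ``similar``
    means the two delta-PSI values differ by at most ``pair_tolerance``.
    """
    recs = sorted(
        (r for r in significant if r.gene_id == model.gene_id),
        key=lambda r: r.exon_index,
    )
    pairs: list[ExonPair] = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            pairs.append(
                ExonPair(
                    gene_id=model.gene_id,
                    exon_a=a.exon_index,
                    exon_b=b.exon_index,
                    dpsi_a=a.delta_psi,
                    dpsi_b=b.delta_psi,
                    adjacent=b.exon_index == a.exon_index + 1,
                    similar=abs(a.delta_psi - b.delta_psi)
                    <= thresholds.pair_tolerance,
                )
            )
    return pairs


def adjacency_summary(pairs: Sequence[ExonPair]) -> dict[str, float]:
    """Fraction of similarly affected pairs that are ladder-adjacent."""
    similar = [p for p in pairs if p.similar]
    n_adj = sum(1 for p in similar if p.adjacent)
    return {
        "n_pairs": len(pairs),
        "n_similar": len(similar),
        "n_adjacent_similar": n_adj,
        "fraction_adjacent_among_similar": (
            n_adj / len(similar) if similar else float("nan")
        ),
    }


def _chain_ok(
    prev: DiffExonRecord,
    nxt: DiffExonRecord,
    thresholds: SignificanceThresholds,
    require_same_sign: bool,
) -> bool:
    if abs(prev.delta_psi - nxt.delta_psi) > thresholds.pair_tolerance:
        return False
    if require_same_sign and (prev.delta_psi > 0) != (nxt.delta_psi > 0):
        return False
    return True


def call_blocks(
    significant: Sequence[DiffExonRecord],
    model: GeneModel,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
    require_same_sign: bool = True,
    all_pairs: bool = False,
) -> tuple[list[ExonBlock], list[DiffExonRecord]]:
    """Call maximal coordinated exon blocks in one gene.

    Returns ``(blocks, singles)`` where singles are significant exons left
    in no block.  A run extends across consecutive significant ladder
    indices while each new member stays within ``pair_tolerance`` of the
    previous member (chain-wise rule) — or of every member already in the
    run when ``all_pairs`` — and, by default, shares the delta-PSI sign.
    Runs are broken at missing introns (overlapping exon-variant ladder
    entries), since a block may not span two variants of the same region.
    """
    by_index = {
        r.exon_index: r
        for r in significant
        if r.gene_id == model.gene_id
    }
    blocks: list[ExonBlock] = []
    singles: list[DiffExonRecord] = []
    run: list[DiffExonRecord] = []

    def flush() -> None:
        if len(run) >= 2:
            blocks.append(_make_block(run, model))
        elif run:
            singles.append(run[0])
        run.clear()

    for idx in sorted(by_index):
        rec = by_index[idx]
        if run:
            prev = run[-1]
            contiguous = idx == prev.exon_index + 1
            bridged = contiguous and model.introns[prev.exon_index] is not None
            if all_pairs:
                compat = all(
                    _chain_ok(m, rec, thresholds, require_same_sign) for m in run
                )
            else:
                compat = _chain_ok(prev, rec, thresholds, require_same_sign)
            if not (bridged and compat):
                flush()
        run.append(rec)
    flush()
    return blocks, singles


def call_blocks_all_genes(
    significant: Sequence[DiffExonRecord],
    models: Mapping[str, GeneModel],
    thresholds: SignificanceThresholds = SignificanceThresholds(),
    **kwargs,
) -> tuple[list[ExonBlock], list[DiffExonRecord]]:
    """Run :func:`call_blocks` over every gene with significant exons."""
    blocks: list[ExonBlock] = []
    singles: list[DiffExonRecord] = []
    by_gene: dict[str, list[DiffExonRecord]] = {}
    for r in significant:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gene_id, recs in sorted(by_gene.items()):
        if gene_id not in models:
            logger.warning("gene %s absent from annotation; skipped", gene_id)
            continue
        b, s = call_blocks(recs, models[gene_id], thresholds, **kwargs)
        blocks.extend(b)
        singles.extend(s)
    logger.info(
        "called %d blocks (%d member exons) and %d single regulated exons",
        len(blocks), sum(b.size for b in blocks), len(singles),
    )
    return blocks, singles


def _make_block(run: Sequence[DiffExonRecord], model: GeneModel) -> ExonBlock:
    indices = tuple(r.exon_index for r in run)
    first, last = indices[0], indices[-1]
    internal = [model.introns[i] for i in range(first, last)]
    flank_up = model.upstream_intron(first)
    flank_down = model.downstream_intron(last)
    block = ExonBlock(
        gene_id=model.gene_id,
        member_indices=indices,
        internal_introns=internal,
        flank_up_intron=flank_up,
        flank_down_intron=flank_down,
        skip_junction=None,
        mean_delta_psi=statistics.fmean(r.delta_psi for r in run),
        frame_preserving=frame_preserving_indices(indices, model),
        all_constitutive_fraction=statistics.fmean(
            1.0 if model.constitutive[i] else 0.0 for i in indices
        ),
    )
    block.skip_junction = derive_skip_junction(block, model)
    return block


def derive_skip_junction(
    block: ExonBlock, model: GeneModel
) -> Optional[GenomicInterval]:
    """Genomic interval excised when the block's flanking exons splice together.

    Spans from the 3' end of the nearest upstream non-block exon to the 5'
    start of the nearest downstream non-block exon (transcriptional
    orientation), returned as a genomic half-open interval.  Absent when
    the block touches the first or last ladder exon.
    """
    first, last = block.member_indices[0], block.member_indices[-1]
    if first == 0 or last == model.n_exons - 1:
        return None
    up_exon = model.exons[first - 1]
    down_exon = model.exons[last + 1]
    if model.strand == "+":
        start, end = up_exon.end, down_exon.start
    else:
        start, end = down_exon.end, up_exon.start
    if start >= end:
        return None  # overlapping exon variants leave no excisable gap
    return GenomicInterval(model.chrom, start, end, model.strand)


def frame_preserving_indices(indices: Sequence[int], model: GeneModel) -> bool:
    total = sum(len(model.exons[i]) for i in indices)
    return total % 3 == 0


def frame_preserving(block: ExonBlock, model: GeneModel) -> bool:
    """True iff skipping the whole block preserves reading frame
    (member exon lengths sum to a multiple of 3)."""
    return frame_preserving_indices(block.member_indices, model)


def summarize_blocks(
    blocks: Sequence[ExonBlock],
    singles: Sequence[DiffExonRecord] = (),
    models: Optional[Mapping[str, GeneModel]] = None,
) -> BlockSummary:
    """Deterministic cohort summary of called blocks.

    Reports block counts, the fraction of 2-exon blocks, the median and
    mean size of larger blocks, the mean |delta PSI| over member exons,
    the frame-preserving fraction, and constitutive fractions among block
    members versus single regulated exons.
    """
    if not blocks:
        return BlockSummary()
    sizes = [b.size for b in blocks]
    larger = [s for s in sizes if s > 2]
    summary = BlockSummary(
        n_blocks=len(blocks),
        n_genes=len({b.gene_id for b in blocks}),
        n_member_exons=sum(sizes),
        fraction_two_exon=sum(1 for s in sizes if s == 2) / len(sizes),
        median_size_larger=statistics.median(larger) if larger else float("nan"),
        mean_size_larger=statistics.fmean(larger) if larger else float("nan"),
        mean_abs_delta_psi=statistics.fmean(abs(b.mean_delta_psi) for b in blocks),
        fraction_frame_preserving=statistics.fmean(
            1.0 if b.frame_preserving else 0.0 for b in blocks
        ),
        constitutive_fraction_block=_weighted_constitutive(blocks),
    )
    if singles:
        summary.constitutive_fraction_single = statistics.fmean(
            1.0 if r.constitutive else 0.0 for r in singles
        )
    return summary


def _weighted_constitutive(blocks: Sequence[ExonBlock]) -> float:
    total = sum(b.size for b in blocks)
    const = sum(b.all_constitutive_fraction * b.size for b in blocks)
    return const / total if total else float("nan")


def write_blocks_tsv(blocks: Sequence[ExonBlock], path) -> None:
    """Per-block TSV: members, mean delta-PSI, frame flag, skip junction."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tmember_indices\tmean_delta_psi\tframe_preserving\t"
            "constitutive_fraction\tskip_chrom\tskip_start\tskip_end\n"
        )
        for b in blocks:
            if b.skip_junction is not None:
                j = (b.skip_junction.chrom, str(b.skip_junction.start),
                     str(b.skip_junction.end))
            else:
                j = (".", ".", ".")
            fh.write(
                "\t".join(
                    [
                        b.gene_id,
                        ",".join(str(i) for i in b.member_indices),
                        f"{b.mean_delta_psi:.6g}",
                        "1" if b.frame_preserving else "0",
                        f"{b.all_constitutive_fraction:.6g}",
                        *j,
                    ]
                )
                + "\n"
            )
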