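"""Strand-aware gene / exon / intron data model.

All genomic coordinates in this package are 0-based, half-open, genomic
(left < right regardless of strand).  *Transcriptional* order — the order
in which exons appear in the mature RNA — is ascending genomic start for
plus-strand genes and descending genomic start for minus-strand genes.
"Upstream" and "downstream" always refer to transcriptional direction.

The :class:`GeneModel` is a collapsed meta-gene: the union of all distinct
exon intervals over a gene's annotated transcripts, ordered
transcriptionally, with the inter-exon gaps as introns.  Adjacency of two
exons (the basis for coordinated-block calling) means consecutive indices
in this collapsed ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "ExonCategory",
    "build_gene_model",
    "classify_constitutive",
    "categorize_exons",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """An annotated isoform: an ordered chain of exon intervals.

    Exons are stored in genomic order (ascending start); they must be
    non-overlapping and all on the same chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        ordered = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        object.__setattr__(self, "exons", tuple(ordered))

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass
class GeneModel:
    """Collapsed exon/intron ladder for one gene.

    ``exons`` are in transcriptional order (index 0 = 5'-most exon of the
    gene).  ``introns[i]`` is the genomic gap between exons i and i+1; it is
    ``None`` when two overlapping-but-unequal exon variants leave no gap.
    ``constitutive[i]`` flags exons present (by exact coordinates) in every
    annotated transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[Optional[GenomicInterval]]
    constitutive: list[bool]
    n_transcripts: int

    def __post_init__(self) -> None:
        if len(self.introns) != max(len(self.exons) - 1, 0):
            raise ValueError("introns must number exons - 1")
        if len(self.constitutive) != len(self.exons):
            raise ValueError("one constitutive flag per exon")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_index(self, interval: GenomicInterval) -> int:
        return self.exons.index(interval)

    def upstream_intron(self, exon_index: int) -> Optional[GenomicInterval]:
        """Transcriptionally upstream flanking intron of an exon (None at index 0)."""
        if exon_index == 0:
            return None
        return self.introns[exon_index - 1]

    def downstream_intron(self, exon_index: int) -> Optional[GenomicInterval]:
        if exon_index >= len(self.exons) - 1:
            return None
        return self.introns[exon_index]


class ExonCategory(str, Enum):
    """Position-based category of an analyzed exon.

    Block members are split by position within their block; significant
    exons outside any block are ``single_regulated``; everything else is
    ``non_regulated`` (the reference category for strength/length
    comparisons).
    """

    FIRST_BLOCK = "first_block"
    INTERNAL_BLOCK = "internal_block"
    LAST_BLOCK = "last_block"
    SINGLE_REGULATED = "single_regulated"
    NON_REGULATED = "non_regulated"


def _transcriptional_sort(
    exons: Iterable[GenomicInterval], strand: str
) -> list[GenomicInterval]:
    genomic = sorted(set(exons), key=lambda e: (e.start, e.end))
    return genomic if strand == "+" else genomic[::-1]


def build_gene_model(transcripts: Sequence[Transcript]) -> GeneModel:
    """Collapse a gene's transcripts into a meta-exon ladder.

    Exons are de-duplicated by exact coordinates; overlapping-but-unequal
    variants are both retained as separate ladder entries.  Introns are the
    genomic gaps between transcriptionally consecutive ladder exons.

    Raises ``ValueError`` for an empty transcript list or for transcripts
    on mixed genes, chromosomes, or strands.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"mixed gene_ids: {sorted(gene_ids)}")
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("transcripts of one gene must share chrom and strand")
    gene_id = next(iter(gene_ids))
    chrom = next(iter(chroms))
    strand = next(iter(strands))

    exons = _transcriptional_sort(
        (e for t in transcripts for e in t.exons), strand
    )
    introns: list[Optional[GenomicInterval]] = []
    for a, b in zip(exons, exons[1:]):
        left, right = (a, b) if strand == "+" else (b, a)
        if left.end < right.start:
            introns.append(
                GenomicInterval(chrom, left.end, right.start, strand)
            )
        else:
            # overlapping exon variants leave no genomic gap
            introns.append(None)

    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        introns=introns,
        constitutive=[False] * len(exons),
        n_transcripts=len(transcripts),
    )
    return classify_constitutive(model, transcripts)


def classify_constitutive(
    model: GeneModel, transcripts: Sequence[Transcript]
) -> GeneModel:
    """Flag ladder exons present at exact coordinates in every transcript."""
    exon_sets = [
        {(e.start, e.end) for e in t.exons} for t in transcripts
    ]
    model.constitutive = [
        all((e.start, e.end) in s for s in exon_sets) for e in model.exons
    ]
    return model


def categorize_exons(
    blocks: Sequence["ExonBlock"],  # noqa: F821 - defined in block_caller
    significant: Sequence["DiffExonRecord"],  # noqa: F821
    model: GeneModel,
) -> dict[int, ExonCategory]:
    """Map every ladder exon index of one gene to its category.

    Block members get first/internal/last labels by position within their
    block (a 2-exon block has a first and a last member, no internal).
    Significant exons outside blocks are single_regulated; all remaining
    ladder exons are non_regulated.  Blocks must be disjoint.
    """
    labels: dict[int, ExonCategory] = {
        i: ExonCategory.NON_REGULATED for i in range(model.n_exons)
    }
    seen: set[int] = set()
    for block in blocks:
        if block.gene_id != model.gene_id:
            continue
        members = list(block.member_indices)
        if seen.intersection(members):
            raise ValueError(
                f"exon assigned to two blocks in gene {model.gene_id}"
            )
        seen.update(members)
        labels[members[0]] = ExonCategory.FIRST_BLOCK
        labels[members[-1]] = ExonCategory.LAST_BLOCK
        for idx in members[1:-1]:
            labels[idx] = ExonCategory.INTERNAL_BLOCK
    for rec in significant:
        if rec.gene_id == model.gene_id and rec.exon_index not in seen:
            labels[rec.exon_index] = ExonCategory.SINGLE_REGULATED
    return labels
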