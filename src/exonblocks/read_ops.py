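"""CIGAR geometry reconstruction and block-skipping read detection.

Reference-consuming CIGAR operations (M, =, X for aligned; D and N for
gaps) are accumulated left to right from the 0-based mapping position.
Both D and N count as candidate splice gaps — long-read aligners emit
either for a skipped exon block — but gaps shorter than ``min_gap``
(default 20 nt, below the smallest human introns) are reclassified as
aligned-internal indels, not splice gaps.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .block_caller import ExonBlock
from .core_model import GeneModel, GenomicInterval
from .io_formats import JunctionCountRecord, RawAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "BlockSkipCall",
    "parse_cigar",
    "reconstruct_geometry",
    "call_block_skip",
    "count_junction_reads",
    "rpm",
    "detection_summary",
]

DEFAULT_MIN_GAP = 20
DEFAULT_TOLERANCE_NT = 8

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_REF_CONSUMING = set("MDN=X")
_ALIGNED = set("M=X")
_GAP = set("DN")


@dataclass
class AlignedRead:
    """Reference-space geometry of one alignment.

    ``aligned_blocks`` and ``gaps`` alternate (block, gap, block, ...) and
    tile ``[start, ref_end)`` exactly.
    """

    read_id: str
    chrom: str
    aligned_blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.aligned_blocks[0][0]

    @property
    def ref_end(self) -> int:
        return self.aligned_blocks[-1][1]

    def has_gap(self, start: int, end: int, tolerance: int = 0) -> bool:
        return any(
            abs(g0 - start) <= tolerance and abs(g1 - end) <= tolerance
            for g0, g1 in self.gaps
        )

    def covers_contiguously(self, left: int, right: int) -> bool:
        """True iff one aligned block spans [left, right] without a gap."""
        return any(b0 <= left and right <= b1 for b0, b1 in self.aligned_blocks)

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return self.chrom == iv.chrom and any(
            b0 < iv.end and iv.start < b1 for b0, b1 in self.aligned_blocks
        )


@dataclass
class BlockSkipCall:
    """Per-block tally of skip versus inclusion reads."""

    block_id: str
    n_skip_reads: int
    n_inclusion_reads: int

    @property
    def percent_skip(self) -> float:
        denom = self.n_skip_reads + self.n_inclusion_reads
        return self.n_skip_reads / denom if denom else float("nan")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; reject unknown ops."""
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def reconstruct_geometry(
    record: RawAlignment, min_gap: int = DEFAULT_MIN_GAP
) -> AlignedRead:
    """Reconstruct aligned blocks and splice gaps from a raw SAM record.

    Adjacent N/D runs are merged into one gap; gaps shorter than
    ``min_gap`` are absorbed into the surrounding aligned block.
    """
    segments: list[tuple[str, int, int]] = []  # (kind, start, end)
    pos = record.pos
    for length, op in parse_cigar(record.cigar):
        if op not in _REF_CONSUMING:
            continue
        kind = "aligned" if op in _ALIGNED else "gap"
        if segments and segments[-1][0] == kind:
            segments[-1] = (kind, segments[-1][1], pos + length)
        else:
            segments.append((kind, pos, pos + length))
        pos += length
    if not segments or segments[0][0] != "aligned" or segments[-1][0] != "aligned":
        raise ValueError(
            f"read {record.qname}: CIGAR does not start/end with aligned ops"
        )
    # reclassify short gaps as aligned-internal, then re-merge
    merged: list[tuple[str, int, int]] = []
    for kind, s, e in segments:
        if kind == "gap" and e - s < min_gap:
            kind = "aligned"
        if merged and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1], e)
        else:
            merged.append((kind, s, e))
    return AlignedRead(
        read_id=record.qname,
        chrom=record.rname,
        aligned_blocks=[(s, e) for k, s, e in merged if k == "aligned"],
        gaps=[(s, e) for k, s, e in merged if k == "gap"],
    )


def call_block_skip(
    reads: Iterable[AlignedRead],
    block: ExonBlock,
    model: GeneModel,
    tolerance_nt: int = DEFAULT_TOLERANCE_NT,
) -> BlockSkipCall:
    """Classify reads over a block as SKIP, INCLUSION, or uninformative.

    SKIP: the read has a gap matching the block-skipping junction within
    ``tolerance_nt`` at both ends.  INCLUSION: aligned blocks overlap both
    flanking exons and at least one member exon.  Uninformative reads are
    excluded from the denominator.  Raises for terminal blocks, which have
    no skip junction.
    """
    junction = block.skip_junction
    if junction is None:
        raise ValueError(
            f"terminal block {block.gene_id}:{block.member_indices} has no "
            "skip junction"
        )
    first, last = block.member_indices[0], block.member_indices[-1]
    up_exon = model.exons[first - 1]
    down_exon = model.exons[last + 1]
    members = [model.exons[i] for i in block.member_indices]

    n_skip = n_incl = 0
    for read in reads:
        if read.chrom != model.chrom:
            continue
        if read.has_gap(junction.start, junction.end, tolerance_nt):
            n_skip += 1
        elif (
            read.overlaps_interval(up_exon)
            and read.overlaps_interval(down_exon)
            and any(read.overlaps_interval(m) for m in members)
        ):
            n_incl += 1
    block_id = f"{block.gene_id}:{first}-{last}"
    return BlockSkipCall(block_id=block_id, n_skip_reads=n_skip,
                         n_inclusion_reads=n_incl)


def count_junction_reads(
    junctions: Sequence[GenomicInterval],
    source: Union[Sequence[JunctionCountRecord], Sequence[AlignedRead]],
    sample: str = "sample",
    tolerance_nt: int = 0,
) -> list[JunctionCountRecord]:
    """Count split-read support per junction.

    From SJ-tab records an exact coordinate match is required (short reads
    are splice-aware aligned); from reads, gaps matching within
    ``tolerance_nt`` count.
    """
    src = list(source)
    sj_mode = bool(src) and isinstance(src[0], JunctionCountRecord)
    out: list[JunctionCountRecord] = []
    if sj_mode:
        table = {
            (r.interval.chrom, r.interval.start, r.interval.end): sum(
                r.counts.values()
            )
            for r in src
        }
        for j in junctions:
            count = table.get((j.chrom, j.start, j.end), 0)
            out.append(JunctionCountRecord(interval=j, counts={sample: count}))
    else:
        for j in junctions:
            count = sum(
                1
                for read in src
                if read.chrom == j.chrom
                and read.has_gap(j.start, j.end, tolerance_nt)
            )
            out.append(JunctionCountRecord(interval=j, counts={sample: count}))
    return out


def rpm(count: int, total_mapped: int) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1_000_000 / total_mapped


def detection_summary(
    junction_counts: Mapping[str, Sequence[JunctionCountRecord]],
    total_mapped: Optional[Mapping[str, int]] = None,
    min_reads: int = 1,
) -> dict[str, dict[str, float]]:
    """Per-condition junction-detection summary.

    ``junction_counts`` maps a condition name to one record per junction
    (counts per sample inside each record).  A junction is *detected* in a
    condition when any sample reaches ``min_reads``.  When ``total_mapped``
    is given (per sample), mean RPM over samples is reported per junction.
    """
    summary: dict[str, dict[str, float]] = {}
    for condition, records in junction_counts.items():
        if not records:
            raise ValueError(f"condition {condition}: no junctions")
        detected = [
            any(c >= min_reads for c in rec.counts.values()) for rec in records
        ]
        entry: dict[str, float] = {
            "n_junctions": float(len(records)),
            "fraction_detected": sum(detected) / len(records),
        }
        if total_mapped:
            rpms = [
                statistics.fmean(
                    rpm(c, total_mapped[s]) for s, c in rec.counts.items()
                )
                for rec in records
            ]
            entry["mean_rpm"] = statistics.fmean(rpms)
        summary[condition] = entry
    return summary


def write_block_skip_tsv(calls: Sequence[BlockSkipCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tn_skip\tn_inclusion\tpercent_skip\n")
        for c in calls:
            fh.write(
                f"{c.block_id}\t{c.n_skip_reads}\t{c.n_inclusion_reads}\t"
                f"{c.percent_skip:.6g}\n"
            )
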