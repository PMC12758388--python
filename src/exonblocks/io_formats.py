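"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions per format (see ``core_model`` for the internal
convention, which is 0-based half-open everywhere):

* GTF: 1-based, inclusive.
* BED6 / BED12: 0-based, half-open.
* STAR ``SJ.out.tab``: 1-based inclusive coordinates of the first and last
  intronic base; strand coded 0 (undefined) / 1 (+) / 2 (−); column 7 is
  the unique-mapping read count.
* SAM: text only; POS is 1-based and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import gffutils

from .core_model import GeneModel, GenomicInterval, Transcript, build_gene_model

logger = logging.getLogger(__name__)

__all__ = [
    "DiffExonRecord",
    "JunctionCountRecord",
    "RBPEventTable",
    "RawAlignment",
    "read_diff_table",
    "write_diff_table",
    "read_sj_tab",
    "write_sj_tab",
    "read_alignments",
    "read_gtf",
    "write_gtf",
    "write_exon_ladder_bed6",
    "write_blocks_bed12",
    "read_rbp_tables",
]

_CIGAR_OPS = set("MIDNSHP=X")


# ---------------------------------------------------------------------------
# records


@dataclass
class DiffExonRecord:
    """One exon's differential-inclusion measurement.

    PSI values are fractions in [0, 1], one per replicate; ``delta_psi`` is
    the replicate-mean difference treatment − control (negative = more
    skipped upon treatment).  ``probability`` is the upstream quantifier's
    confidence that the exon changed.
    """

    gene_id: str
    exon_index: int
    interval: GenomicInterval
    psi_ctrl: tuple[float, ...]
    psi_treat: tuple[float, ...]
    delta_psi: float
    probability: float
    constitutive: bool = False

    def __post_init__(self) -> None:
        for name, vals in (("psi_ctrl", self.psi_ctrl), ("psi_treat", self.psi_treat)):
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} value {v} outside [0, 1]")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"delta_psi {self.delta_psi} outside [-1, 1]")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass
class JunctionCountRecord:
    """Split-read support for one intron/gap interval, per sample."""

    interval: GenomicInterval
    counts: dict[str, int]
    total_mapped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for sample {s}")
        for s, t in self.total_mapped.items():
            if t <= 0:
                raise ValueError(f"non-positive total_mapped for sample {s}")


@dataclass
class RBPEventTable:
    """Alternative-splicing event counts for one RBP knockdown experiment."""

    rbp: str
    cell_type: str
    n_block_events: int
    n_events_by_type: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_block_events > sum(self.n_events_by_type.values()):
            raise ValueError(
                f"{self.rbp}: block events exceed total events"
            )

    @property
    def n_total_events(self) -> int:
        return sum(self.n_events_by_type.values())


@dataclass(frozen=True)
class RawAlignment:
    """A minimally parsed SAM record (POS already converted to 0-based)."""

    qname: str
    flag: int
    rname: str
    pos: int
    cigar: str


# ---------------------------------------------------------------------------
# differential-PSI tables

_NATIVE_COLUMNS = [
    "gene_id",
    "exon_index",
    "chrom",
    "start",
    "end",
    "strand",
    "psi_ctrl",
    "psi_treat",
    "delta_psi",
    "probability",
    "constitutive",
]

_WHIPPET_REQUIRED = ["Gene", "Node", "Coord", "Strand", "Psi_A", "Psi_B", "DeltaPsi", "Probability"]


def _parse_psi_list(text: str) -> tuple[float, ...]:
    return tuple(float(x) for x in text.split(",") if x != "")


def read_diff_table(
    path: Union[str, Path], dialect: str = "native"
) -> list[DiffExonRecord]:
    """Read a differential exon-inclusion TSV.

    ``dialect='native'`` is this package's own schema (fractions
    throughout, replicate PSI comma-separated).  ``dialect='whippet_diff'``
    reads a Whippet-like per-node table where Psi_A is the treatment group,
    Psi_B the control group, and the DeltaPsi column is expressed in
    percent (a trailing ``%`` is tolerated); units are fixed by dialect,
    never guessed from magnitudes.
    """
    if dialect not in ("native", "whippet_diff"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[DiffExonRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = _NATIVE_COLUMNS[:-1] if dialect == "native" else _WHIPPET_REQUIRED
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if dialect == "native":
                    rec = _parse_native_row(parts, col)
                else:
                    rec = _parse_whippet_row(parts, col)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} row {lineno}: {exc}") from exc
            records.append(rec)
    logger.info("read %d diff-exon records from %s", len(records), path)
    return records


def _parse_native_row(parts: Sequence[str], col: Mapping[str, int]) -> DiffExonRecord:
    interval = GenomicInterval(
        parts[col["chrom"]],
        int(parts[col["start"]]),
        int(parts[col["end"]]),
        parts[col["strand"]],
    )
    constitutive = False
    if "constitutive" in col and col["constitutive"] < len(parts):
        constitutive = parts[col["constitutive"]].strip().lower() in ("1", "true", "yes")
    return DiffExonRecord(
        gene_id=parts[col["gene_id"]],
        exon_index=int(parts[col["exon_index"]]),
        interval=interval,
        psi_ctrl=_parse_psi_list(parts[col["psi_ctrl"]]),
        psi_treat=_parse_psi_list(parts[col["psi_treat"]]),
        delta_psi=float(parts[col["delta_psi"]]),
        probability=float(parts[col["probability"]]),
        constitutive=constitutive,
    )


def _parse_whippet_row(parts: Sequence[str], col: Mapping[str, int]) -> DiffExonRecord:
    chrom, span = parts[col["Coord"]].split(":")
    start1, end1 = span.split("-")
    interval = GenomicInterval(
        chrom, int(start1) - 1, int(end1), parts[col["Strand"]]
    )
    dpsi_text = parts[col["DeltaPsi"]].rstrip("%")
    return DiffExonRecord(
        gene_id=parts[col["Gene"]],
        exon_index=int(parts[col["Node"]]) - 1,
        interval=interval,
        psi_treat=_parse_psi_list(parts[col["Psi_A"]]),
        psi_ctrl=_parse_psi_list(parts[col["Psi_B"]]),
        delta_psi=float(dpsi_text) / 100.0,
        probability=float(parts[col["Probability"]]),
    )


def write_diff_table(records: Iterable[DiffExonRecord], path: Union[str, Path]) -> None:
    """Write records in the native TSV schema (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_NATIVE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        str(r.exon_index),
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.interval.strand,
                        ",".join(f"{v:.6g}" for v in r.psi_ctrl),
                        ",".join(f"{v:.6g}" for v in r.psi_treat),
                        f"{r.delta_psi:.6g}",
                        f"{r.probability:.6g}",
                        "1" if r.constitutive else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

_SJ_STRAND = {0: "+", 1: "+", 2: "-"}  # 0 = undefined; kept as "+" placeholder


def read_sj_tab(path: Union[str, Path], sample: str = "sample") -> list[JunctionCountRecord]:
    """Read a STAR ``SJ.out.tab``-dialect junction table for one sample.

    Coordinates are converted from 1-based inclusive intronic bases to the
    0-based half-open gap interval.  Duplicate junction lines (merged
    lanes) have their counts summed, with a warning.
    """
    path = Path(path)
    merged: dict[tuple[str, int, int, str], int] = {}
    n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path} line {lineno}: need >= 7 columns")
            try:
                start1, end1 = int(parts[1]), int(parts[2])
                strand_code = int(parts[3])
                n_unique = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            key = (parts[0], start1 - 1, end1, _SJ_STRAND.get(strand_code, "+"))
            if key in merged:
                n_dups += 1
            merged[key] = merged.get(key, 0) + n_unique
    if n_dups:
        logger.warning("%s: %d duplicate junction lines summed", path, n_dups)
    return [
        JunctionCountRecord(
            interval=GenomicInterval(chrom, start, end, strand),
            counts={sample: count},
        )
        for (chrom, start, end, strand), count in merged.items()
    ]


def write_sj_tab(records: Iterable[JunctionCountRecord], path: Union[str, Path],
                 sample: Optional[str] = None) -> None:
    """Write junction records in SJ.out.tab dialect (columns 5/6/8/9 zeroed)."""
    rows = []
    for r in records:
        if sample is None:
            (count,) = r.counts.values()
        else:
            count = r.counts.get(sample, 0)
        strand_code = 1 if r.interval.strand == "+" else 2
        rows.append(
            (r.interval.chrom, r.interval.start + 1, r.interval.end,
             strand_code, 0, 0, count, 0, 0)
        )
    rows.sort()
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# SAM text


def read_alignments(
    path: Union[str, Path],
    include_secondary: bool = False,
) -> Iterator[RawAlignment]:
    """Stream mapped records from a SAM text file (headerful or headerless).

    Unmapped records (FLAG 0x4) are skipped; secondary (0x100) and
    supplementary (0x800) alignments are excluded unless requested.
    Records with unknown CIGAR operation letters are rejected and logged.
    """
    path = Path(path)
    n_kept = n_bad = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                n_bad += 1
                logger.warning("%s: truncated SAM record skipped", path)
                continue
            flag = int(parts[1])
            if flag & 0x4:
                continue
            if not include_secondary and flag & (0x100 | 0x800):
                continue
            cigar = parts[5]
            if cigar == "*" or any(
                not (c.isdigit() or c in _CIGAR_OPS) for c in cigar
            ):
                n_bad += 1
                logger.warning(
                    "%s: record %s rejected (bad CIGAR %r)", path, parts[0], cigar
                )
                continue
            n_kept += 1
            yield RawAlignment(
                qname=parts[0],
                flag=flag,
                rname=parts[2],
                pos=int(parts[3]) - 1,
                cigar=cigar,
            )
    logger.info("%s: %d alignments read, %d rejected", path, n_kept, n_bad)


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: Union[str, Path]) -> dict[str, list[Transcript]]:
    """Read exon features from a GTF into transcripts grouped by gene.

    Requires ``gene_id`` and ``transcript_id`` attributes on exon
    features.  GTF's 1-based inclusive coordinates are converted to the
    internal 0-based half-open convention.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_transcript: dict[str, tuple[str, list[GenomicInterval]]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        per_transcript.setdefault(tx_id, (gene_id, []))[1].append(iv)
    genes: dict[str, list[Transcript]] = {}
    for tx_id, (gene_id, exons) in per_transcript.items():
        genes.setdefault(gene_id, []).append(
            Transcript(transcript_id=tx_id, gene_id=gene_id, exons=tuple(exons))
        )
    logger.info("read %d genes / %d transcripts from GTF", len(genes), len(per_transcript))
    return genes


def read_gene_models(path: Union[str, Path]) -> dict[str, GeneModel]:
    """Read a GTF and collapse every gene into a :class:`GeneModel`."""
    return {
        gene_id: build_gene_model(txs) for gene_id, txs in read_gtf(path).items()
    }


def write_gtf(transcripts: Iterable[Transcript], path: Union[str, Path],
              source: str = "exonblocks") -> None:
    """Write exon features (1-based inclusive) for the given transcripts."""
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [e.chrom, source, "exon", str(e.start + 1), str(e.end),
                         ".", e.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED


def write_exon_ladder_bed6(model: GeneModel, path: Union[str, Path],
                           append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for i, e in enumerate(model.exons):
            name = f"{model.gene_id}_exon{i}"
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t0\t{model.strand}\n"
            )


def write_blocks_bed12(blocks: Sequence["ExonBlock"],  # noqa: F821
                       models: Mapping[str, GeneModel],
                       path: Union[str, Path]) -> None:
    """Write blocks as BED12 lines, member exons as sub-blocks."""
    with open(path, "w") as fh:
        for n, block in enumerate(blocks):
            model = models[block.gene_id]
            members = [model.exons[i] for i in block.member_indices]
            members_genomic = sorted(members, key=lambda e: e.start)
            chrom_start = members_genomic[0].start
            chrom_end = members_genomic[-1].end
            sizes = ",".join(str(len(e)) for e in members_genomic)
            starts = ",".join(str(e.start - chrom_start) for e in members_genomic)
            name = f"{block.gene_id}_block{n}"
            fh.write(
                "\t".join(
                    [
                        model.chrom, str(chrom_start), str(chrom_end), name,
                        "0", model.strand, str(chrom_start), str(chrom_end),
                        "0", str(len(members_genomic)), sizes, starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RBP event tables


def read_rbp_tables(path: Union[str, Path]) -> list[RBPEventTable]:
    """Read a per-RBP event-count TSV.

    Expected columns: ``rbp``, ``cell_type``, ``n_block_events``, then one
    column per event type (any further column names are treated as event
    types with integer counts).
    """
    path = Path(path)
    tables: list[RBPEventTable] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for fixed in ("rbp", "cell_type", "n_block_events"):
            if fixed not in header:
                raise ValueError(f"{path}: missing required column {fixed!r}")
        col = {name: i for i, name in enumerate(header)}
        type_cols = [c for c in header if c not in ("rbp", "cell_type", "n_block_events")]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tables.append(
                RBPEventTable(
                    rbp=parts[col["rbp"]],
                    cell_type=parts[col["cell_type"]],
                    n_block_events=int(parts[col["n_block_events"]]),
                    n_events_by_type={c: int(parts[col[c]]) for c in type_cols},
                )
            )
    return tables
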