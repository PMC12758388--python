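"""Synthetic annotation, genome, PSI-table, and read generator with truth.

The generator emulates the statistical structure the block analysis
assumes, so every stage of the pipeline can be exercised against planted
ground truth without any external download:

* multi-exon gene models on both strands, with coordinated blocks planted
  in a subset of genes, flanked by long introns and weakened splice-site
  motifs (block-internal and other sites carry near-consensus motifs);
* two-condition, replicated differential-PSI tables in which block
  members share a common negative delta-PSI (more skipped upon
  treatment) with bounded within-block jitter, surrounded by
  low-probability noise exons and isolated significant decoys;
* long reads drawn from block-inclusion versus block-skipping isoform
  templates with M/N CIGARs and optional boundary wobble;
* nascent-RNA short reads encoding a chosen per-intron splicing
  efficiency (junction-spanning = spliced, boundary-crossing =
  unspliced) and order-informative reads encoding a per-exon probability
  that the upstream flanking intron is removed first.

Every stage derives its random stream from ``SimConfig.seed`` plus a
stage-specific offset, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core_model import GeneModel, GenomicInterval, Transcript, build_gene_model
from .io_formats import DiffExonRecord, write_diff_table, write_gtf, write_sj_tab, JunctionCountRecord
from .splicing_metrics import IntronCategory
from .splice_sites import revcomp

__all__ = [
    "SimConfig",
    "TruthManifest",
    "AnnotationBundle",
    "SimRead",
    "sample_donor_9mer",
    "sample_acceptor_23mer",
    "generate_annotation",
    "generate_diff_table",
    "simulate_long_reads",
    "simulate_nascent_reads",
    "write_fasta",
    "write_sam",
    "write_manifest",
]

DONOR_CONSENSUS = "CAGGTAAGT"          # 3 exonic + GT + 4 intronic
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTCTTTCAGGCT"  # 20 intronic (…AG) + 3 exonic
_DONOR_CORE = (3, 4)    # GT dinucleotide positions (0-based) kept intact
_ACCEPTOR_CORE = (18, 19)  # AG dinucleotide

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults encode the simulated cohort the package is validated on:
    20 genes with 8 planted two-to-three-exon blocks, a planted block
    delta-PSI of -0.198 with replicate noise sd 0.005, block-flanking
    introns drawn longer than others, weakened flanking splice sites,
    treatment long reads skipping blocks at rate 0.125, internal introns
    spliced efficiently (0.9) and flanking introns inefficiently (0.3),
    and a deterministic internal-introns-first removal order.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (6, 10)
    exon_len: tuple[int, int] = (80, 200)
    intron_len_other: tuple[int, int] = (150, 400)
    intron_len_flanking: tuple[int, int] = (600, 1200)
    n_blocks: int = 8
    block_size_range: tuple[int, int] = (2, 3)
    block_spec: Optional[list[tuple[int, int, int]]] = None  # (gene, start, size)
    dpsi_block: float = 0.198
    dpsi_block_sd: float = 0.08      # between-block magnitude spread
    dpsi_block_jitter: float = 0.008  # bound on within-block member spread
    dpsi_noise_sd: float = 0.005
    decoy_single_fraction: float = 0.05
    site_weaken_prob: float = 0.6    # per mutable position, flanking sites
    site_consensus_noise: float = 0.05  # per mutable position, other sites
    skip_fraction_ctrl: float = 0.0
    skip_fraction_treat: float = 0.125
    read_wobble: int = 0
    spi_internal: float = 0.9
    spi_flanking: float = 0.3
    spi_other: float = 0.7
    spi_treat_shift: float = 0.15    # efficiency gain of 'other' introns upon treatment
    order_prob_first_block: float = 0.0
    order_prob_last_block: float = 1.0
    order_prob_other: float = 0.5
    n_long_reads_per_gene: int = 200
    n_spi_reads_per_intron: int = 100
    n_order_reads_per_exon: int = 50
    nascent_skip_reads_treat: int = 8
    nascent_skip_reads_ctrl: int = 0
    replicates: int = 3
    psi_rep_sd: float = 0.002
    alt_isoform_prob: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.exons_per_gene[0] < self.block_size_range[1] + 2:
            raise ValueError(
                "genes must be long enough to host a non-terminal block"
            )
        for name in (
            "dpsi_block", "decoy_single_fraction", "skip_fraction_ctrl",
            "skip_fraction_treat", "spi_internal", "spi_flanking", "spi_other",
            "order_prob_first_block", "order_prob_last_block", "order_prob_other",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class TruthManifest:
    """Planted ground truth for one synthetic dataset."""

    blocks: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    block_dpsi: dict[str, float] = field(default_factory=dict)
    decoy_singles: list[tuple[str, int]] = field(default_factory=list)
    intron_category: dict[tuple[str, int], str] = field(default_factory=dict)
    intron_efficiency: dict[tuple[str, int], float] = field(default_factory=dict)
    order_prob: dict[tuple[str, int], float] = field(default_factory=dict)
    site_strength: dict[tuple[str, int], str] = field(default_factory=dict)
    read_labels: dict[str, str] = field(default_factory=dict)
    skip_junctions: dict[str, tuple[str, int, int]] = field(default_factory=dict)


@dataclass
class AnnotationBundle:
    """In-memory result of annotation generation."""

    config: SimConfig
    transcripts: dict[str, list[Transcript]]
    models: dict[str, GeneModel]
    genome: dict[str, str]
    manifest: TruthManifest


@dataclass(frozen=True)
class SimRead:
    """A pre-aligned simulated read (enough to emit one SAM line)."""

    qname: str
    chrom: str
    pos: int  # 0-based
    cigar: str
    flag: int = 0


# ---------------------------------------------------------------------------
# motif sampling


def _mutate(seq: str, rng: np.random.Generator, prob: float,
            keep: tuple[int, ...]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in keep:
            continue
        if rng.random() < prob:
            out[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


def sample_donor_9mer(rng: np.random.Generator, weak: bool,
                      config: Optional[SimConfig] = None) -> str:
    """Draw a donor motif: consensus-like, or degenerate for weak sites.

    The GT core is always kept so splice junctions stay recognizable.
    """
    cfg = config or SimConfig()
    prob = cfg.site_weaken_prob if weak else cfg.site_consensus_noise
    return _mutate(DONOR_CONSENSUS, rng, prob, _DONOR_CORE)


def sample_acceptor_23mer(rng: np.random.Generator, weak: bool,
                          config: Optional[SimConfig] = None) -> str:
    cfg = config or SimConfig()
    prob = cfg.site_weaken_prob if weak else cfg.site_consensus_noise
    return _mutate(ACCEPTOR_CONSENSUS, rng, prob, _ACCEPTOR_CORE)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# annotation + genome


def _plan_blocks(config: SimConfig, n_exons_per_gene: Sequence[int],
                 rng: np.random.Generator) -> dict[int, tuple[int, int]]:
    """gene index -> (start ladder index, size); auto-placed unless given."""
    if config.block_spec is not None:
        return {g: (s, z) for g, s, z in config.block_spec}
    if config.n_blocks > config.n_genes:
        raise ValueError("cannot plant more blocks than genes")
    genes = rng.choice(config.n_genes, size=config.n_blocks, replace=False)
    plan: dict[int, tuple[int, int]] = {}
    for g in sorted(int(x) for x in genes):
        n_exons = n_exons_per_gene[g]
        size = int(rng.integers(config.block_size_range[0],
                                config.block_size_range[1] + 1))
        start = int(rng.integers(1, n_exons - size))  # flanks stay non-terminal
        plan[g] = (start, size)
    return plan


def generate_annotation(config: SimConfig) -> AnnotationBundle:
    """Generate gene models, genome sequence, and the truth manifest.

    Genes land on two chromosomes and both strands (coordinates redrawn
    on overlap, bounded retries).  Splice-site motifs are written into
    the genome: near-consensus for block-internal and other introns,
    degenerate for block-flanking introns.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_exons_per_gene = [
        int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        for _ in range(config.n_genes)
    ]
    block_plan = _plan_blocks(config, n_exons_per_gene, rng)

    manifest = TruthManifest()
    transcripts: dict[str, list[Transcript]] = {}
    genome_parts: dict[str, list[tuple[int, str]]] = {"chr1": [], "chr2": []}
    placed: dict[str, list[tuple[int, int]]] = {"chr1": [], "chr2": []}
    span = 30_000 * (config.n_genes // 2 + 2)

    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:04d}"
        n_exons = n_exons_per_gene[g]
        block = block_plan.get(g)
        members = (
            set(range(block[0], block[0] + block[1])) if block else set()
        )
        exon_lens = [
            int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            for _ in range(n_exons)
        ]
        intron_cats = []
        for i in range(n_exons - 1):
            if block and block[0] <= i < block[0] + block[1] - 1:
                cat = IntronCategory.BLOCK_INTERNAL
            elif block and (i == block[0] - 1 or i == block[0] + block[1] - 1):
                cat = IntronCategory.BLOCK_FLANKING
            else:
                cat = IntronCategory.OTHER
            intron_cats.append(cat)
        intron_lens = [
            int(
                rng.integers(*config.intron_len_flanking)
                if cat == IntronCategory.BLOCK_FLANKING
                else rng.integers(*config.intron_len_other)
            )
            for cat in intron_cats
        ]

        # transcript-oriented sequence with motifs stamped in
        exon_seqs = [_random_seq(rng, L) for L in exon_lens]
        intron_seqs = [_random_seq(rng, L) for L in intron_lens]
        for i, cat in enumerate(intron_cats):
            weak = cat == IntronCategory.BLOCK_FLANKING
            donor = sample_donor_9mer(rng, weak, config)
            acceptor = sample_acceptor_23mer(rng, weak, config)
            exon_seqs[i] = exon_seqs[i][:-3] + donor[:3]
            intron_seqs[i] = donor[3:] + intron_seqs[i][6:-20] + acceptor[:20]
            exon_seqs[i + 1] = acceptor[20:] + exon_seqs[i + 1][3:]
            manifest.site_strength[(gene_id, i)] = "weak" if weak else "consensus"

        tx_seq_parts: list[str] = []
        offsets: list[int] = []
        pos = 0
        for i in range(n_exons):
            offsets.append(pos)
            tx_seq_parts.append(exon_seqs[i])
            pos += exon_lens[i]
            if i < n_exons - 1:
                tx_seq_parts.append(intron_seqs[i])
                pos += intron_lens[i]
        gene_seq = "".join(tx_seq_parts)
        gene_len = len(gene_seq)

        # placement: random chrom/offset, redrawn on overlap
        strand = "+" if g % 2 == 0 else "-"
        for attempt in range(100):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            gstart = int(rng.integers(1000, span - gene_len - 1000))
            if all(
                gstart + gene_len + 500 <= s or e + 500 <= gstart
                for s, e in placed[chrom]
            ):
                break
        else:
            raise RuntimeError("could not place gene without overlap")
        placed[chrom].append((gstart, gstart + gene_len))
        genome_parts[chrom].append(
            (gstart, gene_seq if strand == "+" else revcomp(gene_seq))
        )

        exon_ivs: list[GenomicInterval] = []
        for i in range(n_exons):
            if strand == "+":
                s = gstart + offsets[i]
                e = s + exon_lens[i]
            else:
                e = gstart + gene_len - offsets[i]
                s = e - exon_lens[i]
            exon_ivs.append(GenomicInterval(chrom, s, e, strand))

        txs = [
            Transcript(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                exons=tuple(exon_ivs),
            )
        ]
        # occasionally a second isoform skipping one ordinary internal exon
        skippable = [
            i for i in range(1, n_exons - 1)
            if i not in members and (i + 1) not in members and (i - 1) not in members
        ]
        if skippable and rng.random() < config.alt_isoform_prob:
            drop = int(rng.choice(skippable))
            txs.append(
                Transcript(
                    transcript_id=f"{gene_id}.t2",
                    gene_id=gene_id,
                    exons=tuple(
                        iv for i, iv in enumerate(exon_ivs) if i != drop
                    ),
                )
            )
        transcripts[gene_id] = txs

        if block:
            manifest.blocks.append(
                (gene_id, tuple(range(block[0], block[0] + block[1])))
            )
        for i, cat in enumerate(intron_cats):
            manifest.intron_category[(gene_id, i)] = cat
            eff = {
                IntronCategory.BLOCK_INTERNAL: config.spi_internal,
                IntronCategory.BLOCK_FLANKING: config.spi_flanking,
                IntronCategory.OTHER: config.spi_other,
            }[cat]
            manifest.intron_efficiency[(gene_id, i)] = eff
        for i in range(1, n_exons - 1):
            if block and i == block[0]:
                p = config.order_prob_first_block
            elif block and i == block[0] + block[1] - 1:
                p = config.order_prob_last_block
            else:
                p = config.order_prob_other
            manifest.order_prob[(gene_id, i)] = p

    # assemble chromosome sequences (random background, genes stamped in)
    genome: dict[str, str] = {}
    bg_rng = np.random.default_rng([config.seed, 2])
    for chrom, parts in genome_parts.items():
        end = max((s + len(seq) for s, seq in parts), default=2000) + 1000
        arr = bg_rng.choice(_BASES, size=end)
        for s, seq in parts:
            arr[s:s + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
        genome[chrom] = arr.tobytes().decode()

    models = {gid: build_gene_model(txs) for gid, txs in transcripts.items()}
    for gene_id, member_tuple in manifest.blocks:
        model = models[gene_id]
        first, last = member_tuple[0], member_tuple[-1]
        up, down = model.exons[first - 1], model.exons[last + 1]
        if model.strand == "+":
            j = (model.chrom, up.end, down.start)
        else:
            j = (model.chrom, down.end, up.start)
        manifest.skip_junctions[gene_id] = j
    return AnnotationBundle(
        config=config,
        transcripts=transcripts,
        models=models,
        genome=genome,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# differential-PSI tables


def generate_diff_table(
    config: SimConfig, bundle: AnnotationBundle
) -> list[DiffExonRecord]:
    """Two-condition replicated PSI table with planted blocks and decoys.

    Block members get delta-PSI ~ -dpsi_block with within-block jitter
    bounded by ``dpsi_block_jitter`` (so consecutive members always chain
    under the 0.02 tolerance) and probability >= 0.9.  Other exons get
    near-zero delta-PSI at low probability, except isolated decoy
    singles.  Replicate PSI values are recentred so their means equal the
    planted values exactly.
    """
    rng = np.random.default_rng([config.seed, 3])
    records: list[DiffExonRecord] = []
    blocks = {gid: set(m) for gid, m in bundle.manifest.blocks}
    bundle.manifest.decoy_singles.clear()
    bundle.manifest.block_dpsi.clear()

    for gene_id in sorted(bundle.models):
        model = bundle.models[gene_id]
        members = blocks.get(gene_id, set())
        n = model.n_exons

        # choose isolated decoy exons: internal, not touching the block,
        # not adjacent to another decoy
        forbidden = set(members)
        for m in members:
            forbidden.update((m - 1, m + 1))
        decoys: set[int] = set()
        candidates = [i for i in range(1, n - 1) if i not in forbidden]
        rng.shuffle(candidates)
        for c in candidates:
            if rng.random() < config.decoy_single_fraction and (
                (c - 1) not in decoys and (c + 1) not in decoys
            ):
                decoys.add(c)
        for d in sorted(decoys):
            bundle.manifest.decoy_singles.append((gene_id, d))

        block_base = -float(
            np.clip(rng.normal(config.dpsi_block, config.dpsi_block_sd),
                    0.12, 0.60)
        )
        if members:
            bundle.manifest.block_dpsi[gene_id] = block_base
        for i in range(n):
            if i in members:
                jitter = float(
                    np.clip(rng.normal(0, config.dpsi_noise_sd),
                            -config.dpsi_block_jitter, config.dpsi_block_jitter)
                )
                dpsi = block_base + jitter
                prob = float(0.9 + 0.1 * rng.random())
            elif i in decoys:
                dpsi = -float(0.15 + 0.25 * rng.random())
                prob = float(0.9 + 0.1 * rng.random())
            else:
                dpsi = float(np.clip(rng.normal(0, config.dpsi_noise_sd), -0.05, 0.05))
                prob = float(0.5 * rng.random())
            psi_ctrl_mean = float(0.85 + 0.1 * rng.random())
            psi_treat_mean = float(np.clip(psi_ctrl_mean + dpsi, 0.0, 1.0))
            dpsi = psi_treat_mean - psi_ctrl_mean
            records.append(
                DiffExonRecord(
                    gene_id=gene_id,
                    exon_index=i,
                    interval=model.exons[i],
                    psi_ctrl=_replicates(rng, psi_ctrl_mean, config),
                    psi_treat=_replicates(rng, psi_treat_mean, config),
                    delta_psi=dpsi,
                    probability=prob,
                    constitutive=model.constitutive[i],
                )
            )
    return records


def _replicates(rng: np.random.Generator, mean: float,
                config: SimConfig) -> tuple[float, ...]:
    vals = rng.normal(mean, config.psi_rep_sd, size=config.replicates)
    vals = vals - vals.mean() + mean  # replicate mean is exact
    return tuple(float(np.clip(v, 0.0, 1.0)) for v in vals)


# ---------------------------------------------------------------------------
# reads


def _cigar_from_segments(segments: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in segments if length > 0)


def _template_read(
    exons: Sequence[GenomicInterval], qname: str, chrom: str,
    wobble: int, rng: np.random.Generator,
) -> SimRead:
    """Full-length read over an exon chain (genomic order), M/N CIGAR."""
    exs = sorted(exons, key=lambda e: e.start)
    bounds = []  # aligned segments
    for e in exs:
        bounds.append([e.start, e.end])
    if wobble > 0:
        for i in range(len(bounds) - 1):
            shift = int(rng.integers(-wobble, wobble + 1))
            bounds[i][1] += shift
            shift2 = int(rng.integers(-wobble, wobble + 1))
            bounds[i + 1][0] += shift2
    segments: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(bounds):
        segments.append(("M", e - s))
        if i < len(bounds) - 1:
            segments.append(("N", bounds[i + 1][0] - e))
    return SimRead(
        qname=qname, chrom=chrom, pos=bounds[0][0],
        cigar=_cigar_from_segments(segments),
    )


def simulate_long_reads(
    config: SimConfig,
    bundle: AnnotationBundle,
    condition: str = "treat",
) -> list[SimRead]:
    """Long reads per gene from inclusion vs block-skipping templates.

    Each read covers the full transcript; in block genes a read is drawn
    from the block-skipping isoform with the condition's skip fraction.
    Truth labels land in the manifest as ``read_labels[qname]``.
    """
    rng = np.random.default_rng(
        [config.seed, 4, 0 if condition == "ctrl" else 1]
    )
    skip_fraction = (
        config.skip_fraction_ctrl if condition == "ctrl"
        else config.skip_fraction_treat
    )
    blocks = dict(bundle.manifest.blocks)
    reads: list[SimRead] = []
    for gene_id in sorted(bundle.models):
        model = bundle.models[gene_id]
        members = set(blocks.get(gene_id, ()))
        incl_exons = model.exons
        skip_exons = [e for i, e in enumerate(model.exons) if i not in members]
        for r in range(config.n_long_reads_per_gene):
            qname = f"{condition}_{gene_id}_lr{r:05d}"
            is_skip = bool(members) and rng.random() < skip_fraction
            exons = skip_exons if is_skip else incl_exons
            read = _template_read(
                exons, qname, model.chrom, config.read_wobble, rng
            )
            bundle.manifest.read_labels[qname] = "skip" if is_skip else "inclusion"
            reads.append(read)
    return reads


def _boundary_read(chrom: str, boundary: int, qname: str,
                   anchor: int = 20) -> SimRead:
    return SimRead(qname=qname, chrom=chrom, pos=boundary - anchor,
                   cigar=f"{2 * anchor}M")


def _junction_read(chrom: str, intron: GenomicInterval, qname: str,
                   anchor: int = 20) -> SimRead:
    return SimRead(
        qname=qname, chrom=chrom, pos=intron.start - anchor,
        cigar=f"{anchor}M{len(intron)}N{anchor}M",
    )


def _order_read(model: GeneModel, exon_index: int, up_first: bool,
                qname: str, anchor: int = 20) -> SimRead:
    """Read spanning both flanking introns: one spliced out, one retained."""
    g_up = model.introns[exon_index - 1]
    g_down = model.introns[exon_index]
    exon = model.exons[exon_index]
    spliced, retained = (g_up, g_down) if up_first else (g_down, g_up)
    # aligned: 20 nt beyond the spliced intron + exon + 20 nt into the
    # retained intron; gap exactly over the spliced intron
    if spliced.start < exon.start:  # spliced intron genomically left
        seg1 = (spliced.start - anchor, spliced.start)
        seg2 = (spliced.end, exon.end + anchor)
    else:
        seg1 = (exon.start - anchor, spliced.start)
        seg2 = (spliced.end, spliced.end + anchor)
    segs = sorted([seg1, seg2])
    cigar = (
        f"{segs[0][1] - segs[0][0]}M"
        f"{segs[1][0] - segs[0][1]}N"
        f"{segs[1][1] - segs[1][0]}M"
    )
    return SimRead(qname=qname, chrom=model.chrom, pos=segs[0][0], cigar=cigar)


def simulate_nascent_reads(
    config: SimConfig,
    bundle: AnnotationBundle,
    condition: str = "ctrl",
    replicate: int = 0,
) -> tuple[list[SimRead], list[SimRead], list[JunctionCountRecord]]:
    """Nascent-RNA short reads for one condition/replicate.

    Returns ``(spi_reads, order_reads, sj_records)``.  Per intron,
    ``n_spi_reads_per_intron`` reads split binomially into
    junction-spanning (spliced) and boundary-crossing (unspliced) reads
    at the planted efficiency (plus ``spi_treat_shift`` for 'other'
    introns under treatment).  Per internal exon, order-informative reads
    are drawn at the planted upstream-first probability.  The SJ table
    aggregates all splice gaps, including block-skipping junction reads
    added at the configured per-condition rate.
    """
    rng = np.random.default_rng(
        [config.seed, 5, 0 if condition == "ctrl" else 1, replicate]
    )
    spi_reads: list[SimRead] = []
    order_reads: list[SimRead] = []
    gap_counts: dict[tuple[str, int, int, str], int] = {}

    def add_gap(chrom: str, start: int, end: int, strand: str, n: int = 1) -> None:
        key = (chrom, start, end, strand)
        gap_counts[key] = gap_counts.get(key, 0) + n

    for gene_id in sorted(bundle.models):
        model = bundle.models[gene_id]
        for i, intron in enumerate(model.introns):
            if intron is None:
                continue
            eff = bundle.manifest.intron_efficiency[(gene_id, i)]
            if (
                condition == "treat"
                and bundle.manifest.intron_category[(gene_id, i)]
                == IntronCategory.OTHER
            ):
                eff = min(1.0, eff + config.spi_treat_shift)
            n = config.n_spi_reads_per_intron
            n_spliced = int(rng.binomial(n, eff))
            for r in range(n_spliced):
                spi_reads.append(
                    _junction_read(
                        model.chrom, intron,
                        f"{condition}_r{replicate}_{gene_id}_i{i}_s{r:04d}",
                    )
                )
            add_gap(model.chrom, intron.start, intron.end, model.strand, n_spliced)
            for r in range(n - n_spliced):
                boundary = intron.start if r % 2 == 0 else intron.end
                spi_reads.append(
                    _boundary_read(
                        model.chrom, boundary,
                        f"{condition}_r{replicate}_{gene_id}_i{i}_u{r:04d}",
                    )
                )
        for i in range(1, model.n_exons - 1):
            if model.introns[i - 1] is None or model.introns[i] is None:
                continue
            p = bundle.manifest.order_prob[(gene_id, i)]
            for r in range(config.n_order_reads_per_exon):
                up_first = bool(rng.random() < p)
                order_reads.append(
                    _order_read(
                        model, i, up_first,
                        f"{condition}_r{replicate}_{gene_id}_e{i}_o{r:04d}",
                    )
                )

    n_skip = (
        config.nascent_skip_reads_treat if condition == "treat"
        else config.nascent_skip_reads_ctrl
    )
    if n_skip > 0:
        for gene_id, (chrom, s, e) in sorted(
            bundle.manifest.skip_junctions.items()
        ):
            model = bundle.models[gene_id]
            iv = GenomicInterval(chrom, s, e, model.strand)
            for r in range(n_skip):
                spi_reads.append(
                    _junction_read(
                        chrom, iv,
                        f"{condition}_r{replicate}_{gene_id}_skipjx{r:03d}",
                    )
                )
            add_gap(chrom, s, e, model.strand, n_skip)

    sample = f"{condition}_rep{replicate}"
    sj_records = [
        JunctionCountRecord(
            interval=GenomicInterval(chrom, s, e, strand),
            counts={sample: n},
        )
        for (chrom, s, e, strand), n in sorted(gap_counts.items())
    ]
    return spi_reads, order_reads, sj_records


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: dict[str, str], path: Union[str, Path],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(reads: Sequence[SimRead], chrom_lengths: dict[str, int],
              path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
        for r in reads:
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.chrom}\t{r.pos + 1}\t60\t{r.cigar}"
                f"\t*\t0\t0\t*\t*\n"
            )


def write_manifest(manifest: TruthManifest, path: Union[str, Path]) -> None:
    payload = {
        "blocks": [
            {"gene_id": g, "members": list(m)} for g, m in manifest.blocks
        ],
        "block_dpsi": dict(manifest.block_dpsi),
        "decoy_singles": [
            {"gene_id": g, "exon_index": i} for g, i in manifest.decoy_singles
        ],
        "intron_category": {
            f"{g}:{i}": c for (g, i), c in manifest.intron_category.items()
        },
        "intron_efficiency": {
            f"{g}:{i}": e for (g, i), e in manifest.intron_efficiency.items()
        },
        "order_prob": {
            f"{g}:{i}": p for (g, i), p in manifest.order_prob.items()
        },
        "site_strength": {
            f"{g}:{i}": s for (g, i), s in manifest.site_strength.items()
        },
        "skip_junctions": {
            g: list(j) for g, j in manifest.skip_junctions.items()
        },
        "read_labels": manifest.read_labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_annotation(bundle: AnnotationBundle, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write GTF, FASTA, and truth manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf = outdir / "annotation.gtf"
    fasta = outdir / "genome.fa"
    manifest = outdir / "truth.json"
    write_gtf(
        [t for txs in bundle.transcripts.values() for t in txs], gtf
    )
    write_fasta(bundle.genome, fasta)
    write_manifest(bundle.manifest, manifest)
    return {"gtf": gtf, "fasta": fasta, "manifest": manifest}
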