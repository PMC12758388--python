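"""Shared fixtures: tiny hand-built gene models and one default simulation."""

import pytest

from exonblocks.core_model import GenomicInterval, Transcript, build_gene_model
from exonblocks.io_formats import DiffExonRecord, RawAlignment
from exonblocks.read_ops import reconstruct_geometry
from exonblocks.synthetic import SimConfig, generate_annotation, generate_diff_table


def make_model(exon_bounds, strand="+", chrom="chr1", gene_id="g1", n_tx=1,
               drop_from_tx2=None):
    """Gene model from [(start, end), ...] genomic exon bounds."""
    exons = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in sorted(exon_bounds)
    )
    txs = [Transcript(transcript_id=f"{gene_id}.t1", gene_id=gene_id, exons=exons)]
    if n_tx > 1:
        keep = tuple(
            e for i, e in enumerate(exons)
            if drop_from_tx2 is None or i != drop_from_tx2
        )
        txs.append(
            Transcript(transcript_id=f"{gene_id}.t2", gene_id=gene_id, exons=keep)
        )
    return build_gene_model(txs)


def make_record(gene_id, exon_index, dpsi, prob=0.95, interval=None,
                constitutive=False):
    iv = interval or GenomicInterval("chr1", 100 * (exon_index + 1),
                                    100 * (exon_index + 1) + 50)
    psi_ctrl = 0.6
    psi_treat = min(max(0.6 + dpsi, 0.0), 1.0)
    return DiffExonRecord(
        gene_id=gene_id,
        exon_index=exon_index,
        interval=iv,
        psi_ctrl=(psi_ctrl,) * 3,
        psi_treat=(psi_treat,) * 3,
        delta_psi=dpsi,
        probability=prob,
        constitutive=constitutive,
    )


def geometry(sim_reads, min_gap=20):
    """Reconstruct AlignedReads from simulated SimReads."""
    return [
        reconstruct_geometry(
            RawAlignment(r.qname, r.flag, r.chrom, r.pos, r.cigar),
            min_gap=min_gap,
        )
        for r in sim_reads
    ]


@pytest.fixture(scope="session")
def default_bundle():
    """The default simulated cohort: 20 genes, 8 planted blocks, seed 1."""
    return generate_annotation(SimConfig())


@pytest.fixture(scope="session")
def default_diff_table(default_bundle):
    return generate_diff_table(default_bundle.config, default_bundle)
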