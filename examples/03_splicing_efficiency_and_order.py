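"""Splicing-per-intron (SPI) and intron-removal order (F_UPFI) from
nascent-RNA reads.

SPI = spliced / (spliced + unspliced) junction evidence per intron.
F_UPFI is the fraction of order-informative reads where an exon's
upstream flanking intron was removed before the downstream one: 0 for
first block exons and 1 for last block exons means block-internal introns
are spliced before the flanking introns.
"""

from exonblocks.io_formats import RawAlignment
from exonblocks.read_ops import reconstruct_geometry
from exonblocks.splicing_metrics import IntronCategory, compute_fupfi, compute_spi
from exonblocks.synthetic import SimConfig, generate_annotation, simulate_nascent_reads


def geometry(sim_reads):
    return [
        reconstruct_geometry(RawAlignment(r.qname, r.flag, r.chrom, r.pos, r.cigar))
        for r in sim_reads
    ]


cfg = SimConfig(seed=1)
bundle = generate_annotation(cfg)
spi_reads, order_reads, _ = simulate_nascent_reads(cfg, bundle, "ctrl", 0)
spi_geo, order_geo = geometry(spi_reads), geometry(order_reads)

by_cat = {c: [] for c in (IntronCategory.BLOCK_INTERNAL,
                          IntronCategory.BLOCK_FLANKING, IntronCategory.OTHER)}
for gid, model in bundle.models.items():
    reads = [r for r in spi_geo if gid in r.read_id]
    for i, intron in enumerate(model.introns):
        if intron is None:
            continue
        rec = compute_spi(intron, reads)
        if rec.spi is not None:
            by_cat[bundle.manifest.intron_category[(gid, i)]].append(rec.spi)

for cat, vals in by_cat.items():
    print(f"mean SPI {cat:<16} {sum(vals) / len(vals):.3f}  (n={len(vals)})")
# Internal introns (planted efficiency 0.9) splice efficiently, flanking
# introns (0.3) poorly -- the ordering the block model predicts.

for gene_id, members in bundle.manifest.blocks[:4]:
    model = bundle.models[gene_id]
    reads = [r for r in order_geo if gene_id in r.read_id]
    f_first = compute_fupfi(members[0], reads, model).f_upfi
    f_last = compute_fupfi(members[-1], reads, model).f_upfi
    print(f"{gene_id} block {members}: F_UPFI first={f_first:.2f} last={f_last:.2f}")
# first = 0 and last = 1: the internal intron is always removed first.
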