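"""Call coordinated exon blocks from a differential PSI table.

Simulates a 20-gene cohort with 8 planted blocks, filters exons at the
standard significance thresholds (probability >= 0.9, |dPSI| >= 0.10),
and chains adjacent coordinately changing exons (pairwise dPSI difference
<= 0.02, same sign) into maximal blocks.
"""

from exonblocks.block_caller import (
    SignificanceThresholds,
    call_blocks_all_genes,
    filter_significant,
    summarize_blocks,
)
from exonblocks.synthetic import SimConfig, generate_annotation, generate_diff_table

cfg = SimConfig(seed=1)
bundle = generate_annotation(cfg)
table = generate_diff_table(cfg, bundle)

significant = filter_significant(table, SignificanceThresholds())
blocks, singles = call_blocks_all_genes(significant, bundle.models)
summary = summarize_blocks(blocks, singles)

print(f"significant exons: {len(significant)} of {len(table)}")
print(f"blocks called: {summary.n_blocks} over {summary.n_genes} genes "
      f"({summary.n_member_exons} member exons, {len(singles)} single regulated)")
print(f"fraction of 2-exon blocks: {summary.fraction_two_exon:.2f}; "
      f"larger blocks median size {summary.median_size_larger}")
print(f"mean |dPSI| over blocks: {summary.mean_abs_delta_psi:.3f}")
for b in blocks[:3]:
    print(f"  {b.gene_id} members {b.member_indices} "
          f"skip junction {b.skip_junction.chrom}:"
          f"{b.skip_junction.start}-{b.skip_junction.end}")
print("planted blocks:", [(g, m) for g, m in bundle.manifest.blocks[:3]], "...")
# Every called block should match a planted one: the generator's noise
# (sd 0.005) stays below the 0.02 chaining tolerance by construction.
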