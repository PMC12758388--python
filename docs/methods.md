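# Methods

## Coordinate and ordering conventions

All internal coordinates are 0-based half-open genomic intervals.
Formats keep their native conventions at the boundary: GTF is 1-based
inclusive, BED 0-based half-open, STAR-style `SJ.out.tab` junction
tables give the 1-based first and last intronic base (converted to the
half-open gap on read), and SAM POS is converted to 0-based.

A gene is represented as a collapsed *exon ladder*: the union of
distinct exon intervals over all annotated transcripts, ordered
transcriptionally (index 0 is the 5′-most exon; for minus-strand genes
that is the genomically rightmost). "Adjacent" always means consecutive
ladder indices, and "upstream/downstream" are transcriptional.
Overlapping-but-unequal exon variants are kept as separate ladder
entries; the gap between two such entries is undefined, recorded as a
missing intron, and block runs never extend across it. The alternative —
merging overlapping variants into one node — would change adjacency for
a small minority of genes; keeping variants separate is the stricter
choice and is applied uniformly.

An exon is *constitutive* when an exon with exactly its coordinates
occurs in every annotated transcript of its gene. This flag is monotone
under transcript removal, which the test suite checks.

## Block calling

Inputs are per-exon differential-inclusion records: replicate PSI values
per condition, the replicate-mean ΔPSI (treatment − control, signed; a
negative value means more skipping upon treatment), and a probability
that the exon changed. Significance requires probability ≥ 0.9 and
|ΔPSI| ≥ 0.10, both boundaries inclusive.

A block is a maximal run of consecutive significant ladder exons in
which every consecutive pair differs in ΔPSI by at most 0.02 and shares
its sign. The chaining rule is deliberately pairwise (chain-wise): a
long run may drift by more than 0.02 end to end as long as each
neighbor pair stays within tolerance. An all-pairs variant (every member
within tolerance of every other) is available as a flag, as is disabling
the same-sign requirement; both defaults follow from reading coordinated
skipping as a single underlying event per block. Runs of length 1 are
reported separately as single regulated exons.

The block-skipping junction is the genomic interval excised when the
nearest non-block exons upstream and downstream of the block are spliced
directly together: from the upstream flank's 3′ end to the downstream
flank's 5′ start, in transcriptional orientation but reported as a
genomic half-open interval (identical for plus- and minus-strand genes
with the same geometry). Blocks touching the first or last ladder exon
have no skip junction and are excluded from junction-based validation.
A block is frame-preserving when its member exon lengths sum to a
multiple of 3.

## Read-level detection

Alignment geometry is reconstructed from CIGAR strings: M/=/X consume
reference and read (aligned), D and N consume reference only (gap
candidates), I/S consume read only, H/P neither. D and N are treated
alike for splice-gap purposes because long-read aligners emit either for
a skipped block; gaps shorter than `min_gap` = 20 nt (below the smallest
human introns, ≈ 30 nt) are reclassified as alignment-internal indels.
Adjacent gap operations merge.

A long read is a SKIP read for a block when one of its gaps matches the
skip junction within ± `tolerance_nt` = 8 nt at both ends (alignment
wobble at splice boundaries; configurable), an INCLUSION read when its
aligned blocks overlap both flanking exons and at least one member exon,
and uninformative otherwise — uninformative reads are excluded from the
percent-skip denominator, since a read that does not span the locus
cannot vote. Short-read junction tables are matched exactly (splice-
aware aligners report precise junctions). Counts normalize to RPM =
count × 10⁶ / uniquely-mapped total; a junction counts as detected in a
condition when any sample reaches `min_reads` = 1.

## Splicing efficiency and order

SPI for an intron is spliced / (spliced + unspliced), pooling both of
the intron's junctions: spliced reads carry a gap exactly matching the
intron; unspliced reads cover an exon–intron boundary contiguously with
≥ 3 nt on both sides. SPI is reported only at ≥ `min_cov` = 10
informative reads. These defaults are declared choices, not inferred
from any external tool's configuration.

Differential SPI pools replicate counts into a 2×2 spliced/unspliced
table per intron and applies a chi-square test with continuity
correction, switching to Fisher's exact test when any cell is below 5;
ΔSPI is the difference of replicate-mean SPI values. Significance uses
raw p ≤ 0.01 and |ΔSPI| ≥ 0.10; Benjamini–Hochberg correction and a
replicate-level Welch test are available but off by default, matching
the raw-threshold convention of the analysis this package supports.

Introns are categorized relative to blocks: *internal* (between block
members), *flanking* (a block's immediate neighbors), *other*. An intron
internal to one block and flanking an adjacent one is labelled internal
(the stronger association), with a log message.

F_UPFI for an internal exon counts reads that report an unambiguous
status for both flanking introns and disagree between them:
n_up_first / (n_up_first + n_down_first), defined at ≥ 5 informative
reads. Reads with both introns spliced or both retained carry no order
information. Multi-intron order inference beyond this pairwise statistic
is out of scope.

## Splice-site scoring

Donor sites are 9-mers (last 3 exonic + first 6 intronic nt), acceptor
sites 23-mers (last 20 intronic + 3 exonic nt), always read 5′→3′
(minus-strand sequences reverse-complemented). Two scorers share one
interface:

- **MaxEnt tables.** When the published maximum-entropy table files are
  supplied, the donor score is log2 of the GT-core consensus odds times
  a 16384-entry table lookup over the remaining 7 positions, and the
  acceptor score is log2 of the AG-core odds times a nine-submodel
  decomposition over overlapping windows of the remaining 21 positions
  (five numerator models, four denominator corrections). Given the same
  tables, scores reproduce the reference implementation exactly; the
  test suite verifies this against an independent table-lookup oracle on
  synthetic table files.
- **PWM fallback.** Without tables, a position weight matrix is trained
  on the annotation's own splice sites (pseudocount 1, uniform
  background), scoring Σ log2(p_pos(base)/0.25). PWM units are not
  MaxEnt units.

The recursive 5′-splice-site scan reconstructs the donor created at an
exon–exon junction after upstream-intron splicing: the upstream exon's
last 3 nt followed by the candidate exon's first 6 nt. With a MaxEnt
model, the fixed threshold 5.52 applies (the score above which 90% of
human canonical donors fall); with the PWM fallback a percentile of the
annotation's real donor scores (default 90th) is used instead and
labelled as such, since the absolute threshold is meaningless in PWM
units.

The EJC window extractor returns the 10 nt around the canonical EJC
deposition point, 24 nt upstream of an exon's 3′ end in transcript
coordinates (for a 100-nt exon, transcript positions 71–80); exons
shorter than the offset plus half-window yield nothing.

Category comparisons (site scores, exon/intron/gene lengths) use
two-sided Mann–Whitney U against the non-regulated reference, medians
reported, no multiple-testing correction by default (categories are few
and the comparisons are descriptive; a flag enables correction).

## Cohort statistics

The per-gene enrichment permutation test drops the observed number of
events uniformly at random onto the quantified genes (multinomially —
a gene can receive several events per permutation; sampling without
replacement would cap genes at one event and is not what "randomly
distributing events over genes" describes) and counts genes receiving
≥ k = 2 events. The one-sided p-value is (1 + #{null ≥ observed}) /
(1 + n_perm), which is super-uniform under the null by construction; a
weight-by-quantified-exon-count placement option exists because long
genes host more quantifiable events. Paired ΔPSI correlation is Pearson
r over within-gene significant-exon pairs, each unordered pair once,
lower ladder index first; the control re-pairs the pooled exons at
random (never pairing a value with itself). RBP block-event enrichment
divides each RBP's block-event fraction by the median fraction over RBPs
with at least one block event; RBPs with zero block events are reported
but excluded from the median and carry no enrichment value. With an even
number of qualifying RBPs the median is the midpoint of the central two,
so no RBP need sit exactly at 1.0.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes —
not the biology that produces it. Defaults define the validation cohort:

| parameter | default | meaning |
| --- | --- | --- |
| n_genes / n_blocks | 20 / 8 | genes, with blocks planted in 8 of them |
| exons_per_gene | 6–10 | ladder length (uniform) |
| exon_len / intron_len_other | 80–200 / 150–400 nt | background geometry |
| intron_len_flanking | 600–1200 nt | block-flanking introns drawn longer |
| dpsi_block / dpsi_block_sd | 0.198 / 0.08 | per-block skipping magnitude (cohort mean ≈ 0.198; between-block spread gives within-gene pairs something to correlate on) |
| dpsi_block_jitter | ± 0.008 | within-block member spread, truncated so consecutive members always chain under the 0.02 tolerance — planted recovery is a property of the construction, not of a particular seed |
| dpsi_noise_sd | 0.005 | ΔPSI noise on non-block exons (probability < 0.5, never significant) |
| decoy_single_fraction | 0.05 | isolated significant singles, never adjacent to a block or each other |
| skip_fraction_treat / ctrl | 0.125 / 0.0 | long-read block-skipping isoform fraction |
| spi internal / flanking / other | 0.9 / 0.3 / 0.7 | per-intron efficiencies (internal spliced efficiently, flanking poorly) |
| spi_treat_shift | +0.15 | treatment efficiency gain on 'other' introns (globally faster splicing upon depletion) |
| order_prob first / last block exon | 0 / 1 | upstream-intron-first probability: internal introns always spliced before flanking |
| site_weaken_prob | 0.6 | per-position mutation rate of flanking-site motifs (GT/AG cores kept); other sites get 0.05 |
| replicates / psi_rep_sd | 3 / 0.002 | replicate PSI noise, recentred so replicate means equal the planted values exactly |
| n_long_reads_per_gene | 200 | |
| n_spi_reads_per_intron / n_order_reads_per_exon | 100 / 50 | |

Genes land on two chromosomes and alternate strands; placement is
random with overlap redraws. Splice-site motifs are written into the
genome so sequence-based scoring sees the planted strength structure.
Reads are emitted pre-aligned as SAM text with M/N CIGARs and no
sequence or quality strings — alignment is out of scope, and an
optional wobble knob (± n nt at gap boundaries) exists purely to stress
the tolerance logic. PSI replicate noise is Gaussian truncated to
[0, 1]; the empirical noise structure of real PSI estimates is more
complex. Every stage derives its random stream from the seed plus a
stage offset, so identical configurations produce byte-identical files.

What passing on this cohort does **not** show: robustness to
mis-annotation, to PSI estimates biased by coverage, to spliced-aligner
soft-clipping artifacts, to overlapping genes, or to blocks whose
members drift more than the chaining tolerance. The generator's noise
model is intentionally clean so that failures indicate logic errors, not
simulation ambiguity.

The validation suite and the acceptance script use modest problem sizes
(20 genes, hundreds of reads per gene, ≤ 1000 permutation datasets) —
large enough for the binomial error bounds they assert, small enough to
run in seconds.

## Numerical details

- Percent-vs-fraction units in ΔPSI inputs are fixed per dialect (the
  Whippet-like dialect carries percent, the native dialect fractions);
  magnitudes are never guessed.
- Duplicate junction lines in SJ tables are summed (merged lanes), with
  a warning.
- Ties in the collapsed ladder (same start) order by end; block
  summaries use exact fractions; the permutation and pairing operations
  take explicit seeds that are recorded in provenance sidecars.
- Degenerate inputs: empty block lists summarize to an empty summary
  (not an error); zero-variance correlation inputs raise; terminal exons
  raise for order statistics and are skipped for site extraction at
  contig edges.
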