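# Methods

## Overview

`mirclip` reconstructs a chimeric eCLIP analysis as a chain of small,
independently testable stages. The library processes one subcellular
fraction × replicate at a time: paired IP and size-matched-input FASTQ →
UMI extraction → 3′ adapter trimming → repeat/rRNA filtering → genome
mapping → chimera detection on genome-unmapped reads → miRNA-portion
trimming and target mapping → UMI deduplication → cluster calling →
IP-vs-input enrichment → threshold and reproducibility filtering → feature
annotation → family summaries → candidate-gene selection. All genomic
coordinates are 0-based half-open internally; GTF output is 1-based
inclusive.

## The synthetic data generator

The generator stands in for a human-genome-scale experiment. It emits:

- a toy genome (default: 2 chromosomes, ~50 kb total) of protein-coding
  genes with 5′UTR/CDS/intron/3′UTR structure on both strands, noncoding
  multi-exon genes, and one tandem-repeat ("rRNA-like") interval per
  chromosome;
- mature miRNAs (default 12) grouped into seed families (default 5) by an
  identical 7-mer at positions 2–8;
- per library: single-end reads laid out as
  `UMI (10 nt) + insert + 3′ adapter`, truncated to the read length
  (default 75 nt). Chimeric inserts are a full mature miRNA followed by a
  target fragment from a planted site (miRNA-first geometry: the ligation
  joins the miRNA 3′ end to the target 5′ end — the convention the
  detector assumes). The input library is pure transcriptome background
  with no site enrichment, modeling what the size-matched input measures:
  background abundance.

Planted sites (default: 2 non-overlapping 60-bp sites in the 3′UTRs of 10
of the 20 genes, miRNAs assigned round-robin) generate both nonchimeric
occupancy reads and chimeric reads. PCR duplicates (default rate 0.15)
re-emit an earlier molecule's UMI and insert with independent sequencing
errors (substitutions only, default 0.001/base). One seeded NumPy
generator drives every draw, so fixed seeds give byte-identical outputs.

Two generator choices deserve explanation:

- **Background share is set by density, not by read fraction.** The toy
  transcriptome is ~10⁵-fold smaller than a human one, so a realistic
  *read share* of scattered background would produce wildly unrealistic
  *per-base* background density and chain all clusters together. The
  default background fraction (0.01 of IP reads, and the whole input
  library) is chosen so that per-base background start density is far
  below one per fragment length, as in real data. Consequently the share
  of site-derived reads is much higher than in a real IP; what is
  preserved is the density contrast that the enrichment statistics
  actually measure.
- **Adapter-aliased fragments are resampled.** A fragment whose visible 3′
  end coincides with a prefix of the adapter is indistinguishable from
  adapter read-through for any 3′ trimmer. The generator redraws such
  fragments (a few percent of draws) so that "post-trim read equals
  planted insert" is exactly true on error-free data, and trimming can be
  idempotent without eating genuine insert.

The input library is simulated at the same read depth as the IP. The 2%
size-matched input refers to the material aliquot taken before library
amplification, not to sequencing depth; enrichment statistics compare
library-normalized rates, so depth matching is the neutral choice.

What the generator does **not** model: crosslink-induced mutations and
truncations, indels, paired-end reads, isoform diversity, expression
heterogeneity across genes, and genome-scale repeat complexity. Tests
passing on this generator therefore demonstrate the correctness of the
pipeline's logic and arithmetic, not its robustness to real-data noise.

## Preprocessing

UMIs are the first 10 bases (configurable) and are moved into the read
name after `_`, so deduplication can recover them from FASTQ alone.
Adapter trimming is ungapped suffix-vs-prefix matching (min overlap 3,
mismatch rate ≤ 0.1), removing everything from the first qualifying
position and re-applying to a fixpoint so the operation is idempotent.
Reads shorter than 18 nt after trimming are dropped and counted — too
short to map or to contain a miRNA.

## Alignment

A self-contained seeded aligner replaces a production mapper, which would
be pointless at toy-genome scale: exact k-mer seeding (k = 16) on both
strands, ungapped extension counting substitutions (max 2), unique /
multi / unmapped classification. When a read is long enough for
`max_mismatches + 1` disjoint k-mers, pigeonhole guarantees a hit; shorter
reads are probed at every offset, which is exhaustive for error-free reads
but can miss heavily erroneous short reads — an accepted limitation, and
one reason the aligner is not meant for real genomes. Multi-mapped reads
are discarded and counted (standard unique-mapping eCLIP practice; the
multimapper policy is not something the analysis criteria depend on).
Repeat filtering uses the same machinery against an index of the repeat
intervals and runs *before* genome mapping.

## Chimera detection

Only reads that failed repeat filtering and genome mapping are tested.
Each mature miRNA's 5′ end is aligned ungapped to the read's 5′ end; the
best call is the longest span with ≥ 18 matched bases and ≤ 1 mismatch,
ties broken by fewer mismatches then lexicographically smaller name, with
equally scoring co-winners preserved in `ambiguous_with`. Ambiguity among
same-seed family members is expected and harmless: family-level summaries
are invariant to within-family tie-breaks. Reads whose miRNA match leaves
a target residue < 18 nt are counted as miRNA-only and excluded. The
residual target is mapped with the genome aligner; unique hits become
fragments tagged with the miRNA name.

## Quantification

- **Deduplication** collapses fragments by (UMI, chromosome, start,
  strand), keeping the first read by identifier, so survivor sets are
  order-insensitive. With sequencing errors, a duplicate of a chimeric
  read can shift the miRNA/target boundary by a base and survive as a
  second "molecule"; at error rate 0 survivors equal truth molecules
  exactly, and at the default error rate the excess is ~0.3%.
- **Cluster calling** is a strand-aware single-linkage merge of fragments
  overlapping by ≥ 1 bp. A production peak-caller's statistical cluster
  model would add nothing at toy-genome scale: what the downstream
  analysis hinges on are the filtering criteria (≥ 3 reads, log2FC > 3,
  reproducibility), and those are implemented exactly.
- **Scoring**: RPM and log2FC as in the README, with a +1 pseudocount on
  both counts (+1 is the common continuity correction and makes zero
  input counts well-defined). The p-value
  is the one-sided Fisher exact (hypergeometric tail) for enrichment of
  IP counts, verified against exact rational summation to 1e-12.
  Chimeric and nonchimeric fragments are clustered and scored as separate
  universes, each RPM-normalized to its own deduplicated fragment total —
  chimeric libraries are orders of magnitude smaller, and normalizing
  them against the nonchimeric total would make their enrichment
  unmeasurable.
- **Filtering**: a peak passes with ip_count ≥ 3 and log2FC strictly
  > 3; it is reproducible iff a passing peak in the other replicate
  overlaps it by ≥ 1 bp on the same strand. Final peaks are the
  deduplicated interval unions of overlapping passing pairs, with summed
  counts and miRNA tallies, mean log2FC, and the more conservative
  (larger) p-value. The read-count/fold-change filters are applied to
  both universes by default; a config switch exempts chimeric clusters,
  since reasonable pipelines differ on whether the sparse chimeric
  universe should face the same thresholds.

## Annotation

Each peak collects all same-strand features it overlaps by ≥ 1 bp and
takes the highest-priority category under
CDS > UTR3 > UTR5 > intron > nc_exon > nc_intron, else intergenic. The
order of the two UTRs within the protein-coding block is not fixed by the
hierarchy's source; UTR3 is placed first (the miRNA-target context makes
it the informative class) and the order is configurable. Reordering
within the protein-coding block can never move a peak between the
protein-coding, noncoding, and intergenic super-classes (property-tested).
Gene ties at equal priority resolve to the lexicographically smallest
gene id. Full-interval overlap (not peak midpoint) is used.

## Families and prioritization

Families default to seed equivalence classes (positions 2–8, window
configurable to 2–7), named after the lexicographically smallest member;
an explicit family map file wins when provided. An allowlist
(miRGeneDB-style) restricts which miRNAs contribute to chimeric summaries.
Family fractions are computed over deduplicated chimeric fragments (not
raw reads) — duplicates carry no independent evidence.

Candidate genes require both binding evidence (strictly more than 5
chimeric UTR3 final peaks in one fraction, or ≥ 1 in all of cytoplasm /
nucleus / chromatin) and expression evidence (|log2FC| ≥ 1 between
wild-type and miRNA-depleted cells, flagged significant — "altered
expression" needs an operational rule, and this one is explicit and
configurable).
Counts use final reproducible peaks. Genes without expression data are
flagged unknown and never selected.

## qPCR arithmetic

Technical replicates are averaged on the Ct scale before exponentiation
(the standard convention); amplification efficiency is fixed at 2.
Relative expression is 2^−ΔΔCt with reference-gene normalization per
condition. The splicing readout is 2^−(Ct_inclusion − Ct_skipping) from
the same sample; when a full-length-transcript abundance factor is
supplied, the normalized ratio is reported alongside the raw one;
division by a user-supplied relative-abundance factor is the transparent
way to express full-length normalization.
The accompanying test is the two-tailed pooled-variance Student's t-test
(Welch available but off by default, matching the named test).

## Problem sizes and determinism

Default study conditions: 3 fractions × 2 replicates, 50,000 IP reads and
a depth-matched input per library, chimera fraction 0.02. The test suite
exercises the full chain at these sizes once and uses reduced depths
(2,500–10,000 reads) elsewhere; cluster/p-value/annotation oracles run on
constructed fixtures. Seeds derive arithmetically from the single
configured seed and stay below 2³¹. Two runs with the same configuration
produce byte-identical FASTQ, BED, and TSV outputs.

## Known limitations

- The aligner is ungapped and unspliced; fragments spanning exon
  junctions in real data would be lost. The simulator does not generate
  them.
- Single-linkage clustering merges adjacent binding sites closer than one
  fragment length into one peak; family/gene-level summaries are
  unaffected, but per-site resolution is limited.
- Peaks at a feature boundary can take the higher-priority neighboring
  label through a 1-bp overlap (e.g. a UTR3 site peak whose interval
  extends one base into the CDS).
- No multiple-testing correction across peaks: reported peaks are
  thresholded, mirroring the analysis this package re-creates.
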