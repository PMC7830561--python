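# Methods

## Scope and model

`rsnpscan` predicts regulatory SNPs (rSNPs) by allele-swap PWM scanning of
promoter flanks, tests TFBS over-representation in promoters of
differentially expressed genes against GC-matched backgrounds, and ranks
rSNPs by phenotype association with an iterated Boruta random-forest
consensus.  All coordinates are 0-based half-open internally; external
formats (VCF, GFF3) keep their native 1-based inclusive conventions and are
converted exactly once at the I/O boundary.

## Motif model and scoring

A PWM is stored as per-position base frequencies.  Position frequency
matrices (counts) are converted by dividing by the column sum, adding a
pseudo-frequency ε = 1e−4 to every entry and renormalizing.  ε keeps every
logarithm in the information vector finite without materially shifting
curated frequencies; its one visible side effect is that the per-column
information I(i) = Σ_b f·ln(4f) tops out slightly below ln 4 even for a
perfectly conserved column.

The matrix similarity score (MSS) is the information-weighted sum of the
observed base frequencies, min–max normalized over the achievable range, so
MSS(consensus) = 1 and MSS(anti-consensus) = 0 *exactly* (the same
summation order is used for the score and its bounds, making the equality
bitwise).  A matrix whose columns are all uniform has zero range and is
rejected as unscorable.  Natural logarithms throughout.

Scanning slides the matrix over every offset of the target sequence; minus-
strand candidates score the reverse complement of the window.  Windows
containing N are skipped rather than scored with a zero-frequency
convention — scoring them would create threshold artifacts near assembly
gaps.  Site lists at a higher threshold are always subsets of those at a
lower one; scanning a sequence and its reverse complement yields
strand-mirrored site sets with identical scores.

## rSNP consequence calls

For each SNP the two 51-bp flanks (±25 bp, SNP centered; reference vs
alternate base) are scanned at threshold 0.85 and filtered to sites whose
interval covers the SNP base.  Sites are matched across alleles by
(matrix, offset, strand): present on both → NoChange if |ΔMSS| ≤ 1e−9
(floating-point guard) else ScoreChange; reference-only → LossOfTFBS;
alternate-only → GainOfTFBS.  A site that *shifts position* under the
allele swap is therefore counted as a Loss plus a Gain — positional
identity is the strictest reproducible matching rule, and the consequence
taxonomy defines Loss/Gain per site, not per matrix.  Consequence
prediction is symmetric by construction: exchanging the two alleles (and
the genome base) flips every Loss ↔ Gain and fixes NoChange/ScoreChange.
A SNP hosted by several overlapping promoters produces per-gene rows but a
single genome-wide rSNP call.

## Promoter geometry

The TSS is the gene-feature start (plus strand) or end (minus strand) —
one TSS per gene, since the annotations this pipeline targets are
gene-level and per-transcript TSSs would be spuriously precise.  The
promoter window spans `up` bases upstream to `down` bases downstream of
the TSS in transcription orientation (defaults 500/100).  Offset 0 is the
TSS base itself; downstream offsets run 0…down−1, upstream −1…−up, so
(TSS, strand, offset) reconstructs the genomic coordinate exactly — an
invariant the test suite checks for every assignment, including
promoter-edge SNPs on both strands.  Windows crossing a chromosome
boundary are clipped and flagged, never silently shortened.  The window
used for rSNP selection defaults to the enrichment window but is
configurable independently, as the two stages serve different questions.

## Enrichment

GC content is (G+C)/(length−N).  Background promoters are drawn without
replacement from non-foreground genes binned by GC (bin width 0.05, ratio
1:1), borrowing from the nearest neighbouring bins with a warning when a
bin's pool runs short, and failing loudly when the whole pool cannot supply
the request.  Per matrix, presence is a binary gene-level indicator (≥ 1
site at threshold on either strand) and over-representation is a one-sided
Fisher exact test on the 2×2 presence table, Bonferroni-corrected over the
matrices actually tested; enriched means adjusted p < 0.01.  One-sided is a
deliberate choice (the question is over-representation in the foreground)
and is recorded in the output schema.  The test suite pins the p-values to
an exact-rational hypergeometric enumeration and checks the family-wise
false-positive rate on null replicates.

## Boruta association

Genotypes are 0/1/2 alternate-allele counts; missing entries are
mode-imputed per feature before the run (tree ensembles need complete
matrices).  Each iteration doubles the undecided matrix with one
independently row-permuted shadow per feature, fits a
`RandomForestClassifier` (stratified class weighting for imbalanced
groups), and computes per-column z = mean/sd of per-tree Gini importances;
columns with zero importance variance get z = 0 with a warning.  A feature
scores a hit when its z exceeds the best shadow's.  Because all undecided
features share the same round count, the two-sided Binomial(n, ½) decision
p-values are computed in closed form (2·CDF(min(k, n−k)), capped at 1),
which matches `scipy.stats.binomtest` and avoids per-feature test calls.
Features decided (p < 0.05, direction by hit excess) leave the matrix;
undecided features at the iteration cap are Tentative and never count as
important.

Defaults: 500 trees, depth cap 7, 100 iterations, hit α = 0.05, 20
consensus runs (CLI-overridable up to the 1000 used at publication scale).
The depth cap follows standard Boruta practice; it bounds the variance of
Gini importances and the cost of an iteration.  Desk-scale runs in the
test suite and acceptance script use 30–50 trees, depth 5 and up to 60
iterations with 20-run consensus on 100-feature, 200-sample matrices —
problem sizes chosen so the full suite runs on a single CPU in minutes;
recovery at these sizes is exact on the planted benchmarks.  Two behaviors
worth knowing:

- z = mean/sd saturates when several strong features compete (each tree
  splits on whichever it sees first), so strong features are confirmed in
  waves rather than simultaneously; the binomial accumulation absorbs the
  occasional missed hit, at the price of extra iterations.
- `consensus_important` short-circuits once the running intersection is
  empty; by intersection monotonicity the result equals running all
  repeats.  Jointly permuting sample order changes RNG consumption and may
  change individual decisions; determinism is guaranteed for identical
  inputs and seeds, not across row reorderings.

## DEG filtering and joins

Up-regulated: log2FC > 2 and padj < 0.05; down-regulated: log2FC < −2 and
padj < 0.05 — both strict, so boundary rows are excluded, and missing padj
(NA, as produced by independent filtering in standard DE tools) is never
significant.  Joins are exact-string on gene ids.  Per-tissue tables keep
rSNP × gene rows so both SNP-level and SNP×gene-level tallies can be
recomputed from row-level output; Venn region counts are derived by
explicit membership enumeration.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at desk scale:

- **Genome/genes**: i.i.d. bases at GC 0.37 (Brassica-like), two 150-kb
  chromosomes, 60 genes on both strands with disjoint footprints and
  unclipped promoters.
- **Planted consequences**: 50 gain, 50 loss, 100 neutral SNPs (defaults).
  For a gain, a word is designed from a chosen matrix so that the version
  with the strong SNP base scores ≥ 0.86 and with the weak base ≤ 0.84,
  deliberately adding mismatches at other columns when a single base swap
  cannot straddle 0.85 on its own; the weak version is embedded in the
  genome and the alternate allele restores the strong base.  Losses are
  the mirror image.  Every planted label — including neutrality — is
  verified by running the production scanner and classifier during
  generation, with spacing guards and a final re-verification pass, so
  downstream recovery tests are exact rather than statistical.
- **Genotypes**: Hardy–Weinberg within group; non-associated SNPs share one
  alt-allele frequency ~ U(0.1, 0.5) across groups, associated SNPs differ
  by δ (default 0.4, clipped into (0.05, 0.95) with a warning); 100 + 100
  samples; empirical MAF > 0.05 enforced by resampling.
- **DEG tables**: planted up/down genes get |log2FC| ∈ (2.5, 6) and padj ∈
  (1e−8, 1e−3); nulls get |log2FC| < 2 with mixed padj and ~5% NA rows; a
  configurable fraction of planted genes is shared across tissues.

One seed reproduces every fixture file byte-identically.  What the
generator does **not** emulate: linkage disequilibrium between SNPs,
population structure or kinship, transcript-level TSS heterogeneity,
dinucleotide composition of real promoters, and correlated DE across
tissues beyond the shared planted core.  Passing tests therefore
demonstrate algorithmic correctness under the stated model, not
performance on real resequencing data, where LD in particular will make
Boruta's all-relevant set larger and less stable.  A chance in-sample
frequency difference can make an unplanned SNP genuinely associated in a
finite sample (see the README's worked example); repeat-consensus is the
designed mitigation.

## Pipeline and reproducibility

Stages run in analysis order (DEG filtering → promoters → enrichment →
SNP assignment → consequence classification → Boruta consensus → joins →
histograms), each writing its table; any failure aborts with the stage
name while completed outputs remain.  One global seed fans out to
per-stage seeds via `SeedSequence(seed).spawn`, so stages are individually
reproducible and a rerun with the same config and seed is byte-identical.
The manifest records package and library versions, the seed, a SHA-256
parameter hash, the full config and the record-count funnel.
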