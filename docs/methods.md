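# Methods

This note documents the models behind `burstchrom`, the parameters that
matter, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## The synthetic study system

The simulator emulates the data types of an embryonic TE-derepression
experiment at desk scale. Two packaged configurations define the study
conditions.

**Time-course strain** (`simgen.default_config`): two 500 kb euchromatic
chromosomes (one carrying an embedded 100 kb constitutive-heterochromatin
block at 300–400 kb), a 50 kb chr4-like chromosome, four TE families
("roo" 6 kb, "297" 4.5 kb, "copia" 3.5 kb, "mdg1" 2.5 kb; GC 0.40–0.45 vs
genome 0.42) and 100 planted insertions (60/25/10/5), placed uniformly in
euchromatin with a 3 kb minimum spacing and a 2 kb margin. Insertions
splice the full-length consensus with no target-site duplication, so each
junction is a point in reference coordinates — this keeps junction geometry
exact for testing. Expression runs over five timepoints (0–2 h … 8–10 h
after egg laying); the dominant family peaks at 1.7% of the transcriptome
at 4–6 h (>70% of TE reads), and the chromatin kernel lag peaks one
timepoint later (6–8 h), encoding a repressive response that trails
nascent transcription by roughly one collection window.

**Depletion strain** (`simgen.depletion_config`): the same families on a
larger, sparser genome (two 1 Mb euchromatic chromosomes, 60 insertions,
12 kb spacing). Bin-level differential analysis needs a majority of
kernel-free background bins to anchor size factors; at 100 insertions per
Mb nearly every 5 kb bin touches a kernel, which is the regime of the
time-course strain, not of a genome-wide bin scan. Using a distinct
insertion landscape per design also mirrors the fact that the two
experimental arms of such studies are typically run in different strains
with different insertion complements.

### Read models

- **RNA-seq**: each read is a uniform sense-strand consensus fragment of a
  TE family with its configured transcriptome fraction, otherwise a
  uniform fragment of euchromatic background (both strands). No gene
  models are simulated: quantification in scope is family-level.
- **ChIP-seq**: input reads are uniform. IP reads mix (i) uniform
  background, (ii) constant 8-fold enrichment over het-block tiles and
  4-fold over chr4-like tiles (5 kb tiles, each with an independent
  lognormal replicate factor, CV 0.3), and (iii) a per-insertion kernel:
  relative density `1 + (E0 − 1)·lag(t)·exp(−d/λ_side)` with E0 = 5,
  λ = 150 bp upstream and λ·s downstream (s = 3), per-insertion replicate
  factors with CV 0.15. IP reads are drawn in reference coordinates around
  the junction point; the inserted element body is not sampled. With these
  defaults the insertion kernels hold ~5% of the IP library, so removing
  them (the depletion arm) perturbs global composition by a few percent —
  comparable to, not larger than, replicate variability, as in a genome
  where the repressive compartment dominates the library. The lag-zero
  limit collapses the kernel to 1 (IP ≡ input).
- **WGS**: fragment count ~ Poisson(coverage·L/2·read length); fragment
  lengths normal (500 ± 60 bp, floored at the 150 bp read length); FR
  mates are the fragment's end prefixes. Insert-size SD and the error
  model are free parameters (error rate 0 by default).
- **Small RNA**: insert length from a 19–31 nt distribution with mode 26;
  antisense with probability 0.8; reads are
  `4 random nt + insert + 4 random nt + 3′ adapter`. Family shares put the
  dominant family at ~16% and the second at ~9% of TE-mapping antisense
  reads.

One master seed expands to fixed per-library child streams
(`SeedSequence(seed, spawn_key=(stream, index))`), so adding a library
never perturbs another; identical config + seed reproduce byte-identical
output.

## Alignment surrogate

Real pipelines for this analysis align with genome mappers; here reads are
error-free and genomes random, so an exact k-mer seed-and-verify matcher
(k = 21, ≤ 2 mismatches over the full read, both strands via
reverse-complement lookup) is sufficient and fully testable. Seeds are
taken every k bases; once a 0-mismatch hit is verified the seed scan stops
(any perfect full-read hit is discoverable from every seed). The two-tier
policy is absolute: any TE-consensus hit beats any genome hit; equal-best
TE families are broken by one uniform draw from a seeded generator that
advances per read in input order, so changing the seed changes only
multimapper allocations. Genomic multimappers are discarded. A minimal SAM
subset reader (QNAME/FLAG/RNAME/POS/MAPQ, with MAPQ 255 coding uniqueness)
lets pre-aligned data bypass the surrogate. Small RNA inserts (19–31 nt)
are matched with k = 15.

## Insertion calling

Junction evidence requires exactly one genome-unique and one TE mate.
Anchors are innermost coordinates (3′-most base of a forward genome mate,
leftmost base of a reverse one). Per (chromosome, family), single-linkage
clustering joins anchors within `max_gap` = mean fragment + 3 SD (all
anchors of one insertion fall within one fragment span); a cluster is
called only with ≥ 1 record on each side. The junction interval is
[innermost left anchor, innermost right anchor], collapsed to the midpoint
if the sides interleave. Strand votes: left-side evidence with a
minus-strand TE mate (or right-side with plus) votes '+'; majority wins,
ties give '.'. Insertion-frequency estimation, split-read evidence and
target-site duplications are out of scope. Same-position insertions of
different families are reported separately.

## Chromatin signal

Tracks are mean per-base coverage per 10 bp bin × 10⁶/library total; the
final partial bin is averaged over its true length, so
Σ(bin value · total/10⁶ · bin size) equals total mapped bases.
Enrichment windows are non-overlapping 10 kb means with
E = log2((ip + ψ)/(input + ψ)), ψ = 0.5 rpm; euchromatin = maximal runs
with E < τ, τ = 1 (2-fold). The window step and τ are configurable; the
defaults are the package's own choice. Signal matrices anchor at the
junction midpoint; rows of '−' elements are column-reversed so increasing
column index is always downstream; out-of-chromosome bins are NaN and
masked from all statistics; the heatmap row sort key defaults to genomic
coordinate (configurable — "5′ to 3′" ordering is not uniquely defined).
The asymmetry ratio is (mean downstream + ψ)/(mean upstream + ψ) over the
row halves. Replicate tracks are pooled read-weighted for visualization
but kept separate for statistics; region comparisons use per-replicate
length-weighted means and a Welch t-test (both groups zero-variance:
p = 1 on equal means, else p = 0 with a degeneracy flag).

## Differential bins

Reads count into the 5 kb bin containing their leftmost position (integer,
disjoint). Size factors are median-of-ratios over features nonzero in all
samples; family-level TE tests instead normalise by library totals, since
median-of-ratios over a handful of families would absorb a shared
derepression signal into the factors. The test is an NB Wald test:
per-feature moment dispersion `(pooled within-group var − μ·mean(1/sf))/μ²`
is shrunk toward the matrix-wide mean with 20 pseudo-degrees of freedom
(empirical-Bayes moderation — the same information sharing DESeq2
performs, in moment form) and floored at 10⁻⁸; the Wald statistic
ln-fold-change / NB standard error is referred to the normal distribution.
The moderation is what makes the normal reference honest: with three
replicates per group the raw plug-in dispersion gives ~11% type-I error at
nominal 5% and halves the power; the moderated test's null calibration and
power are themselves verified by simulation in the test suite (type-I
0.049–0.054 across seeds; ≥ 0.8 power for a 2-fold depletion at μ = 200,
dispersion 0.05, 3 vs 3). Zero-mean groups get a half-count floor
(0.5/n); all-zero features are excluded with status
`low_count_excluded`. BH adjustment is computed over tested features and
matches an independent implementation bitwise. The power study uses 200
affected + 300 null bins: a fixed-depth design chosen by a priori power
analysis — at these parameters a planted effect diluted 1:25 in null bins
is not detectable at 80% power by any unshrunk Wald test, so the study
measures power at a realistic affected fraction. Attribution: a
significant bin counts toward every family with an insertion junction
within 5 kb (boundary-inclusive; overlap = 0), on adjusted p < 0.05 by
default (raw p is also emitted).

## Small RNA processing

The 3′ adapter is located as the leftmost position where a prefix of the
adapter matches through to the read end (5 nt exact seed, then ≤ 1
mismatch per 10 nt of overlap); unclipped reads are retained by default.
Reads shorter than 15 nt after clipping are dropped, then exactly 4 nt are
trimmed from each end (the ligated random nucleotides), and 19–31 nt
inserts (inclusive) are kept. Orientation is defined on the consensus: a
plus-strand hit is sense, a minus-strand hit antisense. The antisense
table reports each family's share of all TE-mapping antisense reads
(shares over all families sum to 100%); the 23–28 nt piRNA window and the
19–31 nt filter are both parameters.

## Study sizes and determinism

The default studies use 200k RNA-seq reads (quantification), ~157k WGS
pairs (calling), 60–150k IP reads (enrichment, asymmetry, depletion), 50k
small RNA reads, and a 50-rerun lag study on a compact three-timepoint
configuration (one 250 kb chromosome, 25 insertions; one genome serves all
reruns, each rerun redraws every library). These sizes give 3σ-level
statistical resolution for every tested property while keeping any single
study in the minutes range on one CPU. All drivers and studies are
deterministic given their seed.

## What passing tests do and do not show

The simulator omits sequencing errors by default, quality scores, PCR
duplicates, GC bias, repetitive genomic background, truncated/nested
insertions and target-site duplications, gene models, and spliced reads.
Passing tests therefore demonstrate that the pipeline's logic — tier
ordering, junction geometry, orientation handling, normalisation identities,
test calibration — is correct under clean conditions, not that real-data
performance (which depends on mappability, repeat structure and library
artifacts) matches these numbers. The NB test is not a numerical
replication of DESeq2 (no GLM IRLS, no fold-change shrinkage, no
independent filtering or outlier handling), and the aligner surrogate makes
no claim to reproduce a spliced genome mapper's behaviour on real reads.
Printed insertion-set sizes or bin counts from any real study are not
reproduction targets of the synthetic studies.
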