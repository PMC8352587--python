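# burstchrom

A tested, reusable pipeline for studying a transient transposon (TE)
expression burst in early fly embryos and the chromatin response it
provokes — exercised end to end on synthetic sequencing data with known
ground truth.

During early embryogenesis a single dominant TE family can transiently
occupy a measurable slice of the transcriptome (~1.7% at its peak, >70% of
all TE-derived reads). Maternally deposited antisense piRNAs target that
family; repressive H3K9me3 chromatin accumulates at its euchromatic
insertions with a lag behind the expression peak and a skew downstream of
the element's direction of transcription; and depleting the piRNA effector
erases that signal specifically in genome-wide 5 kb bins near the targeted
insertions. `burstchrom` implements every computational stage of that
analysis arc for people who want to develop, test or teach these methods
without multi-hundred-gigabyte raw data: every read it processes comes from
a bundled simulator that emits truth tags, so every stage is checkable
against ground truth.

## What it computes

- **Read assignment & quantification** (`assignquant`) — a two-tier policy:
  reads are matched to TE consensus sequences first (multimappers allocated
  uniformly at random among equal-best families), then to the genome keeping
  unique hits only; genomic multimappers are discarded. Counts are scaled to
  rpm with the whole-library denominator (all TE + genome-mapped reads), so
  rpm(f) = count(f) · 10⁶ / (TE + genome reads) and 17,000 rpm = 1.7% of the
  transcriptome.
- **Non-reference insertion calling** (`inscall`) — read pairs with one
  genome-unique and one TE-consensus mate become junction evidence; anchors
  are clustered per (chromosome, family) by single linkage and called only
  with support on **both** sides of the junction (the "1p1" rule); the
  element's strand is a majority vote over the FR pair geometry.
- **Chromatin signal** (`chromsig`) — 10 bp rpm coverage tracks; log2
  IP/input enrichment in 10 kb windows; euchromatin = maximal runs of
  windows below threshold; oriented ±10 kb signal matrices around insertion
  junctions (columns always run 5′→3′ of the element); metaprofiles;
  downstream/upstream asymmetry ratios; region-level Welch t-tests.
- **Differential bins** (`diffbins`) — negative-binomial Wald tests on 5 kb
  bin counts with median-of-ratios size factors, moment dispersion estimates
  moderated across features, Benjamini–Hochberg adjustment, and attribution
  of significant bins to TE families with insertions within 5 kb.
- **Small RNA / piRNA profiles** (`pirna`) — 3′ adapter clipping, trimming
  of the 4 ligated random nucleotides from each end, inclusive 19–31 nt size
  selection, consensus orientation assignment (antisense = reverse
  complement of consensus), size profiles and per-family antisense
  percentages.
- **Synthetic data** (`simgen`) — toy genomes with planted full-length TE
  insertions, plus RNA-seq, ChIP-seq (exponential insertion-centric
  enrichment kernel with configurable lag and downstream skew), paired-end
  WGS and small RNA libraries, each with a complete truth table.
- **Drivers** (`orchestrate`, `analysis/`) — the two experimental designs:
  the developmental time course and the effector-depletion comparison.

## Worked example

```sh
python analysis/03_call_insertions.py --seed 1 --outdir results/insertions
```

```
156,654 read pairs -> 3,985 junction-evidence pairs
100 calls vs 100 planted: precision 1.000, recall 1.000, strand accuracy 1.000, median junction error 3 bp
```

30× paired-end WGS of a ~1.05 Mb sample genome yields ~157k pairs, of which
~4k span an insertion junction with one mate in the genome and one in a TE
consensus; clustering + the 1p1 filter recover all 100 planted insertions
with no false calls, correct strands, and junctions placed within a few bp.

```sh
python analysis/02_te_expression_timecourse.py --seed 1
```

```
total TE % per timepoint:
    0-2h:  0.07%
    2-4h:  0.96%
    4-6h:  2.14%
    6-8h:  1.22%
   8-10h:  0.59%
RNA peak at 4-6h, H3K9me3 peak at 6-8h (trails RNA: True)
```

The TE share of the transcriptome bursts mid-course (the dominant family
alone reaches ~1.7%) and the insertion-centric H3K9me3 maximum arrives one
timepoint later — the configured lag of the chromatin response, recovered
through the full pipeline. The remaining drivers
(`analysis/01…06`) cover simulation output, chromatin dynamics/asymmetry,
the depletion differential with attribution, and piRNA profiles.

## Layout

```
src/burstchrom/    library (simgen, assignquant, inscall, chromsig,
                   diffbins, pirna, orchestrate, studies, io)
analysis/          numbered narrative drivers writing results/
tests/             pytest suite incl. end-to-end acceptance tests
scripts/           acceptance.py reproduction script
docs/methods.md    models, parameters, assumptions, limitations
```
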