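# Methods

## The analysis model

`riboclast` analyzes translation on a transcriptome undergoing widespread
endonucleolytic cleavage — the regime created when an innate-immune
endonuclease such as RNase L (activated by 2–5A and cutting preferentially
at UU/UA dinucleotides) or a generic pyrimidine-specific RNase is active in
the cytoplasm.  Three consequences structure everything the package
computes:

1. **Global mRNA loss.**  Most transcripts are degraded (roughly 60% to
   more than 99% in the cell), but libraries are sequenced to a fixed
   depth.  All count-based comparisons are therefore *relative*: a gene
   that appears upregulated has lost less than the bulk (through cleavage
   resistance or transcriptional compensation), not necessarily gained
   molecules.
2. **altORF translation.**  Ribosomes can load the 5' ends of 3' cleavage
   fragments and initiate at the first available ORF, placing footprints
   into 3'UTRs, 5'UTRs, and out-of-frame stretches of the CDS.
3. **Translational re-tuning.**  The loss of translatable mRNA changes
   ribosome availability and interacts with the integrated stress response
   (ISR): genes whose 5'UTR uORFs normally repress the main ORF (the
   ATF4/GADD34/CHOP configuration, and IFIT genes with near-cognate CUG/GUG
   uORF starts) shift initiation between uORF and main ORF.

### Coordinates and regions

All positions are 0-based, half-open, in transcript space.  The CDS
interval *includes* the stop codon, so 5'UTR `[0, cds_start)`,
CDS `[cds_start, cds_end)`, and 3'UTR `[cds_end, length)` tile every
transcript exactly; this makes the per-gene conservation identity
(region counts sum to the track total minus discards) exact.  GTF input
(1-based inclusive, genomic) is projected onto transcript coordinates by
exon concatenation, strand-resolved; `stop_codon` features are folded into
the CDS.  Multi-isoform GTFs are reduced to one isoform per gene,
preferring MANE/RefSeq-Select-tagged transcripts and otherwise the longest
CDS, mirroring the reduced single-isoform transcriptomes standard for
region-level footprint analysis.

### P-sites

A footprint is collapsed to its ribosome P-site at `5'-end + 12 nt`, one
global offset for all read lengths (26–32 nt).  Reads whose shifted P-site
falls past the transcript 3' end are discarded (never clamped) and
tallied.  `calibrate_psite_offset` validates the 12-nt assumption on data:
for candidate offsets 10–14 it sums 5'-end counts at `cds_start − offset`
over all transcripts and takes the argmax, exploiting the initiation peak
at start codons; exact ties resolve to 12 and are flagged low-confidence.
At least 100 reads must overlap the start-codon windows.

### Region counts, rpm, and UTR:ORF ratios

P-site tracks are summed per region per gene; `rpm` divides by the
sample's total transcriptome-mapped P-sites (×10⁶).  Where an annotated
uORF overlaps the CDS, the overlap is assigned to the 5'UTR by default
(`overlap_to_utr`) — the convention required for ATF4-style genes, applied
uniformly; the complement policy is available.  The UTR:ORF ratio is
computed per gene (utr rpm / cds rpm, genes below `min_cds_rpm` = 1
excluded) and as the aggregate ratio of sums over the same gene set.  The
aggregate is the headline statistic: it matches the one-bar-per-sample
presentation of transcriptome-wide altORF levels and is invariant under
library scaling.  The expression filter default is a repository choice,
exposed as a parameter.

### Metagene profiles

For each gene passing a mean-CDS-density filter (default 0.5 reads/nt)
whose window fits entirely inside the transcript, the positional count
vector around the anchor (start-codon P-site, or the stop codon itself) is
divided by that gene's mean CDS density; profiles are equal-weight gene
averages, so uniform translation gives a flat profile at 1.  Genes whose
window would cross a transcript edge are excluded rather than zero-padded
to avoid edge deflation.

### Differential expression

The DE stage is a deliberately simple, fully documented stand-in for a
negative-binomial DE package: median-of-ratios size factors,
`log2(normalized + 0.5)`, a two-sided t-test across replicates, and
Benjamini–Hochberg adjustment.  The pooled-variance (Student) test is the
default because it is exactly calibrated for exchangeable equal-size
groups at the 2–3 replicates typical here; the Welch/Satterthwaite
approximation is measurably conservative at n=3 (intrinsic level ≈0.035
at nominal 0.05) and remains available via `equal_var=False`.  The
pseudocount 0.5 keeps zero-count genes finite and symmetric.  Genes with
zero variance in both groups get p=1 when means agree.  DE flags use
padj < 0.05 and |log2fc| > 1 by default.  Externally produced DE tables
(gene, log2fc, pvalue, padj) can be imported unchanged, preserving full
fidelity when users run a dedicated DE package themselves.  Gene-set
summaries return per-gene log2fc vectors per contrast and paired t-tests
across contrasts (gene-level pairing; zero-variance difference vectors are
flagged degenerate rather than tested).

### Translation efficiency

TE = CDS footprint rpm / CDS RNA-seq rpm per sample; RNA rpm of 0 makes TE
undefined for that sample (excluded and logged).  TE *changes* are read
off matched DE tables as `delta_log2_te = log2fc(ribo) − log2fc(rna)`
after the filter cascade: |log2fc| > 4 with padj < 0.01 in either assay
(the "log2 fold changes >4" gate is taken literally on the log2 scale —
the intent is ambiguous, and the alternative reading is one flag away),
then normalized mean counts > 50 in *both* assays (the per-assay/both
choice is likewise undocumented upstream; "both" is implemented and
logged).  Genes beyond ±log2(2) from the diagonal are te_up/te_down.
Every removal records the gate that caused it.  Mitochondrial genes are
tagged by a configurable name-prefix list (default `MT-`).

### uORF analysis

Candidate uORF starts come from scanning the 5'UTR for AUG/CUG/GUG
(configurable) ORFs of at least 2 codons (`min_codons` default — a
repository choice; no minimum length is standard).  A candidate's peak is
the P-site count in its start codon ±1 codon (9 nt); the background is
the mean 5'UTR density outside all candidate windows; `peak_score =
peak / (background × window width)`, called at score ≥ 5 and ≥ 10 reads.
These thresholds quantify what is often judged by eye and are exposed in
configuration.  The 5'UTR:main-ORF shift uses whole-5'UTR rpm over CDS rpm
per replicate (a uORF-window-restricted variant exists as an option);
`log2_shift` compares treated and control means, with a Welch t-test on
per-replicate log2 ratios.

## The synthetic-data generator

The generator produces the full input bundle (transcriptome FASTA +
table, per-sample footprint BED, RNA-seq counts) plus ground truth, and
is the package's test bed.  Its defaults are the reference study
conditions: 2,000 genes, 3 control + 3 treated replicates, 2×10⁶
footprints and RNA-seq fragments per sample, UU/UA cleavage at per-site
probability 0.02, 90% global loss, 20× induction of 5% of genes, fragment
re-initiation probability 0.3.

* **Cleavage** is a memoryless per-copy Bernoulli cut at each motif site
  (probability = per-site probability × weight/max-weight), chosen because
  no cleavage kinetics are established and this model is analytically
  checkable: the intact fraction is exactly (1−p)^sites.  Presets:
  `rnasel_like` (UU/UA dinucleotides), `rnasea_like` (U/C pyrimidines).
  Fragment decay is a single per-fragment survival draw; global loss is
  emulated by scaling pre-cleavage copy numbers, induction by multiplying
  them for the induced set, and cleavage resistance by exempting chosen
  transcripts from cutting.
* **Footprints.**  Expected footprint counts per translation unit are
  copies × TE × ORF length; uORF-bearing genes split initiation between
  uORF and main ORF by a per-condition probability (0.8 unstressed; an
  ISR-like condition lowers it).  Within an ORF, P-sites sit at codon
  positions with frame weights (0.70, 0.15, 0.15) — a generic 3-nt
  periodicity, not a measured value — and a 5× initiation-peak weight on
  the first codon, which gives offset calibration and uORF peak detection
  a realistic signal.  3' fragments containing CDS or 3'UTR sequence
  contribute their first available ORF with the re-initiation probability
  folded into the expected weight (identical in expectation to per-copy
  thinning, far cheaper); a configurable fraction of fragment footprints
  stalls at the last complete codon before the fragment 3' end.  A uniform
  background of 0.01 reads/nt (relative to CDS density 1) represents the
  nonzero floor real controls show; without it control UTR ratios would be
  exactly zero and ratio fold changes undefined.
* **RNA-seq** counts are multinomial over per-gene CDS-overlap mass of
  intact copies and surviving fragments, emulating CDS fragment counting.
* **Determinism.**  One root seed drives sequence generation, abundances,
  and per-sample streams through spawned child generators; identical seeds
  give byte-identical bundles.

What the generator does *not* emulate: sequencing error, positional bias
from ligation or nuclease preference, codon-level dwell times, isoform
mixtures, rRNA contamination, batch effects, and the coupling between
cleavage of actively translated mRNAs and ribosome positions.  Passing
recovery tests therefore demonstrates that the statistics measure what
they claim under the stated stochastic model — not that real libraries
are free of these additional structures.

### A note on "relative upregulation" arithmetic

With loss fraction L and induction factor k, an induced gene's absolute
abundance changes by k(1−L) while its DE fold approaches k: at L = 0.9 and
k = 20 the apparent ~20× coexists with a true absolute change of 2×
(an absolute *decrease* additionally requires k < 1/(1−L)).  The
recovery tests assert the defensible form of the semantics — the apparent
fold far exceeds the absolute fold, and non-induced genes decrease
absolutely — rather than an absolute decrease of induced genes, which
those parameter values cannot produce.

## Problem sizes and numerical choices

The acceptance script and heavy tests run the reference design (2,000
genes, 6 samples, 2×10⁶ reads/sample) for the altORF, TE-recovery, and
null analyses; the uORF-shift analysis uses 800 genes at 10⁶ footprints
with half the genes uORF-bearing, and offset calibration uses 300 genes at
10⁵ footprints — sizes at which every recovered quantity is far from its
decision boundary while a full run stays in the tens of seconds on one
core.  Ties in offset calibration break toward 12; empty metagenes, empty
libraries, zero library sizes, and sub-replicated groups raise immediately
with named errors; P-sites shifted past transcript ends are discarded and
tallied, and 5' ends clip at zero (footprints within 12 nt of the cap
keep their record but lose exact P-site recoverability).

## Known limitations

* The DE stand-in has no dispersion shrinkage; at 2–3 replicates its
  power is below a negative-binomial package's, which is why the import
  path for external DE tables exists.
* TE classification inherits DE normalization; strong asymmetric
  composition changes between assays could bias `delta_log2_te`.
* uORF peak calling quantifies a visual convention; its thresholds are
  package defaults, not field standards.
* The 3'-fragment re-initiation fraction is a free parameter — no
  measured value exists — so analyses sweep it rather than assume it.
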