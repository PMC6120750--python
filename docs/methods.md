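# Methods

## Study design being modelled

The pipeline targets a small two-group transcriptome study: case tissue
(e.g. ossified spinal ligament) vs. control, four samples per group by
default, profiled for four transcript classes — mRNA, lncRNA and circRNA as
array-style intensities and miRNA as sequencing counts. All identifiers are
opaque, case-sensitive strings; genomic coordinates are 0-based half-open;
sequences are held in the RNA alphabet (DNA input is converted at the
boundary).

## Differential expression

Array classes are quantile-normalized across samples before testing: each
column's rank *r* is replaced by the across-sample mean of the *r*-th order
statistics, and tied values within a column receive the mean of their tied
ranks' target values, which keeps the transform total-sum preserving and
idempotent on equal distributions.

The per-transcript test is a two-sided equal-variance Student's *t* on
log2 values (counts enter as log2(count + pseudo-count), pseudo-count 1).
Fold change is the ratio of linear-scale group means — the usual array
convention of "test on logs, report linear FC". The filter is strict on
both sides: max(FC, 1/FC) > 2 **and** raw p < 0.05. BH-adjusted FDR is
computed per transcript class and reported in every output row, so a
filtering rule based on FDR instead of raw p can be applied by the reader;
the package's own filter uses raw p because that is the variant whose
thresholds are printed with the results it emulates, while FDR is part of
the reported record. Degenerate rows follow fixed conventions: zero
variance in both groups with equal means gives p = 1; zero variance with
unequal means gives the smallest positive double and a `degenerate` flag.

Hierarchical leaf ordering for heatmaps uses average linkage on the
distance 1 − PCC across samples, rows pre-sorted lexicographically so ties
break deterministically; a constant row (undefined PCC) is assigned
distance 1 to every other row and triggers a warning. qPCR support is the
plain 2^−ΔΔCt with a reference gene and a calibrator condition.

## lncRNA positional classification

Six categories with a fixed precedence (first match wins):
exon sense-overlapping → intron sense-overlapping → intronic antisense →
natural antisense → bidirectional → intergenic. Sense overlap outranks the
antisense categories and containment outranks adjacency; this precedence is
a design decision of the package — the category names are standard but no
universally agreed precedence exists. "Bidirectional" requires opposite
strands, head-to-head (divergent) orientation, TSS-to-TSS distance within a
window (default 1,000 bp, a common promoter-sharing convention) and no
gene-body overlap. Overlap is evaluated at gene-body/exon resolution
against supplied coding gene models; no isoform reconciliation is
attempted. Chromosome enrichment is the fraction of deregulated transcripts
on a chromosome divided by the chromosome's fraction of all genes, so it is
invariant to uniform scaling of the gene counts.

## Seed-site scanning

Canonical site taxonomy: 6mer (reverse complement of miRNA positions 2–7 on
the target strand), 7mer-m8 (positions 2–8), 7mer-A1 (6mer plus a literal A
opposite miRNA position 1), 8mer (7mer-m8 plus the A). The A anchor is
required on the target regardless of the miRNA's own first base. miRNA
positions are 1-based (field convention), target positions 0-based
(package convention). Overlapping calls anchored at the same seed locus are
collapsed to the most specific type (8mer > 7mer-m8 > 7mer-A1 > 6mer); raw
hits are available behind a flag. Circular targets are scanned on the
sequence extended by its own 7-nt prefix, positions reported modulo length,
junction-spanning sites flagged. No thermodynamic scoring, 3′-supplementary
pairing or non-canonical sites: the scanner is a transparent, exactly
testable stand-in for database target prediction.

## Networks

All correlations are Pearson on log2 expression pooled across **all**
samples of both groups — with n = 8 this is what makes DE-driven
co-expression detectable at the |PCC| ≥ 0.968, p < 0.05 retention rule used
throughout (p from t = r√(n−2)/√(1−r²) on n−2 df; |r| = 1 is reported as
p = 0 with an exact-fit flag). Gates:

* **CNC**: any-sign edges between filtered DE lncRNAs and DE mRNAs.
* **Target network**: an miRNA–mRNA edge needs (i) ≥ 1 canonical seed site,
  (ii) r < 0 with |r| ≥ threshold and p < threshold, (iii) anti-directional
  DE calls. Consequently every retained edge is negative.
* **ceRNA**: a circRNA–miRNA–mRNA triplet needs the same miRNA to carry a
  site on both partners (circRNA scanned as a circle) and both
  miRNA-involving edges to pass the target-network gate. The circRNA–mRNA
  correlation is annotated (expected positive) but deliberately not gated —
  only the two miRNA-involving relations carry the mechanism.

The same threshold pair is reused for all three products and is
configurable; the minimum site specificity for "shared site" defaults to
any canonical type.

## Enrichment

Upper-tail hypergeometric over-representation: p = P(X ≥ k) for overlap k
of a size-K term with a size-n query in a size-N universe; k = 0 is
reported with p = 1. The universe defaults to all transcripts of the
platform/simulation and is configurable. Scores are −log10(p); BH FDR is
applied across terms. Ranked (GSEA-style) enrichment and ontology topology
are out of scope; any GMT file works.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions every
recovery property is measured under.

* **Expression.** Intensities are Normal on the log2 scale and
  exponentiated (log-normal noise, the standard array assumption);
  baselines Uniform(6, 12) log2 a.u.; within-group sd 0.25. miRNAs use
  baselines Uniform(8, 14) and are rounded to integer counts. A planted DE
  transcript of effect β gets group means ±β/2 on log2, so its expected
  observed log2FC equals β. Effects are |N(2, 0.5)| truncated at ≥ 1.2.
* **Correlated structures.** Members of a planted co-expressed pair or
  ceRNA triplet share one latent per-sample profile (the ±β/2 group signal
  plus shared log2 jitter of sd noise_sd/2, scaled by each member's own
  effect and direction) plus an independent residual of sd 0.01. The
  scaling keeps each member's marginal behaviour similar to a regular DE
  transcript while pushing the within-structure population PCC to ≈ 0.9999,
  so the sample PCC at n = 8 clears 0.968 essentially surely — structure
  recovery failures then indicate implementation bugs, not sampling noise.
  For the same reason structure members draw effects truncated at ≥ 2.0
  (regular DE keeps the 1.2 floor): at the 1.2 floor the strict FC > 2
  filter would miss a member in roughly one case in ten at n = 4 vs 4,
  which would contaminate exact-recovery testing. Triplets have the ceRNA
  sign structure (circRNA and mRNA co-directional, miRNA anti-directional)
  or its mirror; pairs are positive or negative with equal probability.
* **Sequences.** Each planted triplet gets one site on its mRNA (linear)
  and one on its circRNA (junction-spanning with probability 0.3), site
  type uniform over the four canonical types, realized as the exact
  complementary string. Backgrounds are uniform ACGU and then *scrubbed*:
  every unplanned occurrence of any simulated miRNA's 6mer core (every site
  type contains the core, so removing cores removes all types) is rewritten
  at a non-protected position, with bounded retries and a full re-draw on
  collision; planted sites are boundary-guarded so they cannot be upgraded
  to a more specific type by flanking bases. miRNA sets are drawn with
  rejection so no two miRNAs share a 6mer core and no core occurs inside
  another miRNA's patterns — together these make site attribution exact and
  the zero-false-triplet property structural. Each triplet uses a distinct
  miRNA.
* **Annotation.** A toy genome: 3-exon coding genes (300/1,000 bp
  exons/introns) laid out every 10 kb across five chromosomes; lncRNAs are
  placed to realize each of the six positional categories by construction,
  with the true label recorded. Bidirectional lncRNAs are planted within
  280 bp of a coding TSS, inside the classifier's 1,000 bp default window.
* **Gene sets.** One planted term containing up to 15 planted upregulated
  mRNAs plus random background terms of the same size.

Default problem sizes (120/80/40/24 transcripts per class, 200-nt targets,
10 studies per acceptance evaluation) were chosen so that every recovery
statistic rests on hundreds of planted items while a full simulate-through-
enrich run stays well under a second; all randomness flows from
`numpy.random.default_rng` seeded per stream from the config, so output is
bit-reproducible across platforms.

What the generator does **not** emulate: batch or spatial array artifacts,
GC bias, count over-dispersion, read-level miRNA-seq, isoform structure,
correlated null transcripts, realistic effect-size distributions. Passing
recovery tests therefore demonstrates correctness of the implemented rules
under the stated noise model, not performance on real tissue data.

## Pipeline and numerical conventions

Steps run in dependency order (simulate → de / classify → networks →
enrich); later steps can resume from the artifacts of an earlier invocation
in the same output directory, and a step whose inputs are absent fails with
an error naming the missing step. Writes are atomic (temp file + rename).
Floats serialize via `repr` and parse back via strtod, so file round-trips
are exact and two runs with the same config and seed are byte-identical;
wall time is logged but kept out of `summary.json` to preserve that
property. Missing expression values are rejected, not imputed. Edge and
node orderings in every output are lexicographic, making serialization
independent of input order.

## Known limitations

* Student's t with pooled variance at n = 4 per group has little power and
  no variance moderation (no limma-style shrinkage, by design).
* The |PCC| ≥ 0.968 rule at n = 8 is a very lenient multiple-testing
  posture inherited from the emulated workflow; the permutation-null test
  quantifies, but the pipeline does not correct, the residual false-edge
  rate.
* The seed scanner ignores binding energetics and site context; database
  target prediction and real GO/KEGG ontologies are intentionally out of
  scope (user-supplied GMT files stand in).
* Transcript identifiers are not mapped across namespaces (probe vs.
  transcript vs. symbol); supply consistent ids.
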