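"""lncRNA positional classification and descriptive genomic summaries.

A differentially expressed lncRNA is placed, relative to a set of coding
gene models, into exactly one of six positional categories. The precedence
order (first match wins) is: exon sense-overlapping, intron
sense-overlapping, intronic antisense, natural antisense, bidirectional,
intergenic. Sense overlap outranks antisense; containment outranks
adjacency. "Bidirectional" requires a head-to-head (divergent) TSS pair on
opposite strands within a configurable window (default 1,000 bp) and no
overlap with any gene body.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ConfigurationError, FormatError
from .model import GeneModel, TranscriptAnnotation

LNCRNA_CATEGORIES = (
    "intergenic",
    "intronic_antisense",
    "natural_antisense",
    "bidirectional",
    "intron_sense_overlapping",
    "exon_sense_overlapping",
)

DEFAULT_LENGTH_EDGES = (200, 1000, 2000, 3000)
SUB_MINIMUM_BIN = "sub_minimum"


@dataclass(frozen=True)
class LncRNACategory:
    transcript_id: str
    category: str


@dataclass(frozen=True)
class ChromosomeEnrichment:
    chrom: str
    n_deregulated: int
    n_genes_on_chrom: int
    fraction_deregulated: float
    fraction_genes: float
    enrichment_ratio: float


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def _contained(a_start, a_end, b_start, b_end) -> bool:
    return b_start <= a_start and a_end <= b_end


def _divergent(lnc: TranscriptAnnotation, gene: GeneModel) -> bool:
    """Head-to-head orientation: the two TSSs face away from each other."""
    if gene.strand == "+":
        return lnc.strand == "-" and lnc.tss <= gene.tss
    return lnc.strand == "+" and lnc.tss >= gene.tss


def classify_lncrna(lnc: TranscriptAnnotation, coding_models,
                    divergence_window: int = 1000) -> LncRNACategory:
    """Assign one of the six positional categories to a lncRNA."""
    if lnc.strand not in ("+", "-"):
        raise FormatError(f"{lnc.transcript_id}: strand required for classification")
    same_chrom = [g for g in coding_models if g.chrom == lnc.chrom]

    overlapping = [g for g in same_chrom
                   if _overlaps(lnc.start, lnc.end, g.start, g.end)]
    sense = [g for g in overlapping if g.strand == lnc.strand]
    antisense = [g for g in overlapping if g.strand != lnc.strand]

    category = None
    if any(_overlaps(lnc.start, lnc.end, es, ee)
           for g in sense for es, ee in g.exons):
        category = "exon_sense_overlapping"
    elif sense:
        category = "intron_sense_overlapping"
    elif any(_contained(lnc.start, lnc.end, is_, ie)
             for g in antisense for is_, ie in g.introns):
        category = "intronic_antisense"
    elif antisense:
        category = "natural_antisense"
    elif any(abs(lnc.tss - g.tss) <= divergence_window and _divergent(lnc, g)
             for g in same_chrom):
        category = "bidirectional"
    else:
        category = "intergenic"
    return LncRNACategory(transcript_id=lnc.transcript_id, category=category)


def classify_many(lncrnas, coding_models, divergence_window: int = 1000):
    return [classify_lncrna(l, coding_models, divergence_window) for l in lncrnas]


def category_percentages(categories) -> dict[str, float]:
    """Percentage of lncRNAs per category (sums to 100 over non-empty input)."""
    counts = {c: 0 for c in LNCRNA_CATEGORIES}
    for rec in categories:
        counts[rec.category] += 1
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in LNCRNA_CATEGORIES}
    return {c: 100.0 * n / total for c, n in counts.items()}


def length_histogram(transcripts, bin_edges=DEFAULT_LENGTH_EDGES) -> dict[str, int]:
    """Left-closed right-open length bins; the last bin is open-ended.

    Lengths below the first edge go to a "sub_minimum" overflow bin with a
    warning (lncRNAs are >= 200 nt by definition, so the default first edge
    is 200).
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(edges) < 1:
        raise ConfigurationError("bin edges must be ascending and non-empty")
    labels = [f"[{a},{b})" for a, b in zip(edges, edges[1:])]
    labels.append(f"[{edges[-1]},inf)")
    counts = {SUB_MINIMUM_BIN: 0, **{lab: 0 for lab in labels}}
    n_sub = 0
    for t in transcripts:
        length = t.length if isinstance(t, TranscriptAnnotation) else int(t)
        if length < edges[0]:
            counts[SUB_MINIMUM_BIN] += 1
            n_sub += 1
            continue
        idx = len([e for e in edges if e <= length]) - 1
        counts[labels[idx]] += 1
    if n_sub:
        warnings.warn(f"{n_sub} transcript(s) shorter than the first bin edge "
                      f"({edges[0]} bp)", stacklevel=2)
    return counts


def chromosome_enrichment(deregulated_ids, annotations,
                          genes_per_chrom: dict[str, int]):
    """Deregulated-transcript density per chromosome, gene-count normalized.

    enrichment_ratio = fraction of deregulated transcripts on the chromosome
    divided by the chromosome's fraction of all genes; invariant to uniform
    scaling of ``genes_per_chrom``. Returns ``(results, skipped_ids)`` with
    results sorted by descending ratio (lexicographic chrom tie-break).
    """
    ann_by_id = {a.transcript_id: a for a in annotations}
    counts: dict[str, int] = {}
    skipped = []
    for tid in deregulated_ids:
        ann = ann_by_id.get(tid)
        if ann is None:
            skipped.append(tid)
            continue
        counts[ann.chrom] = counts.get(ann.chrom, 0) + 1
    if skipped:
        warnings.warn(f"{len(skipped)} deregulated id(s) absent from the "
                      "annotation were excluded", stacklevel=2)
    for chrom in counts:
        if genes_per_chrom.get(chrom, 0) <= 0:
            raise ConfigurationError(
                f"genes_per_chrom must be positive for chromosome {chrom!r}"
            )
    n_total = sum(counts.values())
    g_total = sum(genes_per_chrom.values())
    results = []
    for chrom, n in counts.items():
        frac_de = n / n_total
        frac_genes = genes_per_chrom[chrom] / g_total
        results.append(ChromosomeEnrichment(
            chrom=chrom,
            n_deregulated=n,
            n_genes_on_chrom=genes_per_chrom[chrom],
            fraction_deregulated=frac_de,
            fraction_genes=frac_genes,
            enrichment_ratio=frac_de / frac_genes if frac_genes > 0 else math.inf,
        ))
    results.sort(key=lambda r: (-r.enrichment_ratio, r.chrom))
    return results, skipped
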