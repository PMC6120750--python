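"""Canonical miRNA seed-site detection on linear and circular transcripts.

Site taxonomy (canonical, TargetScan-style), with miRNA positions 1-based
5'->3' on the mature miRNA and target positions 0-based 5'->3':

* 6mer     — target matches the reverse complement of miRNA positions 2-7;
* 7mer-m8  — reverse complement of positions 2-8;
* 7mer-A1  — the 6mer followed by an A on the target (opposite position 1);
* 8mer     — reverse complement of positions 2-8 followed by an A.

The A anchor is a literal adenosine on the target regardless of the miRNA's
position-1 identity. Every site type contains the 6mer core; overlapping
calls anchored at the same seed locus are collapsed to the most specific
type with precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer (raw hits are available
via ``collapse=False``).

Circular targets (circRNAs) are scanned across the backsplice junction by
extending the sequence with its own prefix; positions are reported modulo
the length and junction-spanning sites are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .model import SequenceRecord

#: precedence, strongest first
SITE_TYPES = ("8mer", "7mer_m8", "7mer_A1", "6mer")

#: specificity levels for shared-site thresholds ("7mer" admits both 7mers)
_SITE_LEVEL = {"6mer": 0, "7mer_A1": 1, "7mer_m8": 1, "8mer": 2}
_MIN_LEVEL = {"6mer": 0, "7mer": 1, "7mer_A1": 1, "7mer_m8": 1, "8mer": 2}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: offset of the 6mer core within each pattern (patterns starting with the
#: m8 complement carry the core one position in)
_CORE_OFFSET = {"6mer": 0, "7mer_A1": 0, "7mer_m8": 1, "8mer": 1}

MAX_PATTERN_LENGTH = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SeedSite:
    """One miRNA binding site on a target transcript."""

    mirna_id: str
    target_id: str
    site_type: str
    start: int  # 0-based 5' end of the site on the target
    length: int
    spans_junction: bool = False


def site_patterns(mirna: SequenceRecord) -> dict[str, str]:
    """Target-strand (5'->3') patterns for the four canonical site types."""
    seq = mirna.sequence
    if len(seq) < 8:
        raise ConfigurationError(
            f"miRNA {mirna.id!r} is {len(seq)} nt; >= 8 nt required for seed patterns"
        )
    core = reverse_complement(seq[1:7])       # positions 2-7
    core_m8 = reverse_complement(seq[1:8])    # positions 2-8
    return {
        "6mer": core,
        "7mer_m8": core_m8,
        "7mer_A1": core + "A",
        "8mer": core_m8 + "A",
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan(mirna: SequenceRecord, target: SequenceRecord,
         collapse: bool = True) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` on ``target``.

    With ``collapse=True`` (default) co-anchored calls are reduced to the
    most specific site type; with ``collapse=False`` every raw pattern
    occurrence is reported.
    """
    patterns = site_patterns(mirna)
    seq = target.sequence
    n = len(seq)
    circular = target.topology == "circular"
    search_space = seq + seq[: MAX_PATTERN_LENGTH - 1] if circular else seq

    hits: list[SeedSite] = []
    for site_type in SITE_TYPES:
        pattern = patterns[site_type]
        plen = len(pattern)
        if circular and plen > n:
            continue  # site cannot fit on the circle without re-wrapping
        for start in _find_all(search_space, pattern):
            if circular:
                if start >= n:
                    continue  # duplicate of an in-range start
                spans = start + plen > n
            else:
                spans = False
            hits.append(SeedSite(mirna_id=mirna.id, target_id=target.id,
                                 site_type=site_type, start=start,
                                 length=plen, spans_junction=spans))
    if not collapse:
        return sorted(hits, key=lambda h: (h.start, SITE_TYPES.index(h.site_type)))

    # collapse by seed-core locus: keep the most specific call per anchor
    best: dict[int, SeedSite] = {}
    for hit in hits:
        locus = hit.start + _CORE_OFFSET[hit.site_type]
        if circular:
            locus %= n
        prev = best.get(locus)
        if prev is None or (SITE_TYPES.index(hit.site_type)
                            < SITE_TYPES.index(prev.site_type)):
            best[locus] = hit
    return sorted(best.values(), key=lambda h: (h.start, SITE_TYPES.index(h.site_type)))


def shared_sites(mirna: SequenceRecord, target_a: SequenceRecord,
                 target_b: SequenceRecord, min_site_type: str = "6mer"):
    """Does the miRNA have a binding site on *both* targets?

    Returns ``(shared, evidence)`` where ``evidence`` maps each target id to
    its supporting sites of at least ``min_site_type`` specificity.
    """
    if min_site_type not in _MIN_LEVEL:
        raise ConfigurationError(f"unknown min_site_type {min_site_type!r}")
    level = _MIN_LEVEL[min_site_type]
    evidence = {}
    for target in (target_a, target_b):
        sites = [s for s in scan(mirna, target)
                 if _SITE_LEVEL[s.site_type] >= level]
        evidence[target.id] = sites
    shared = all(evidence[t.id] for t in (target_a, target_b))
    return shared, evidence


def filter_sites(sites, min_site_type: str = "6mer"):
    """Subset of sites meeting a minimum specificity level."""
    if min_site_type not in _MIN_LEVEL:
        raise ConfigurationError(f"unknown min_site_type {min_site_type!r}")
    level = _MIN_LEVEL[min_site_type]
    return [s for s in sites if _SITE_LEVEL[s.site_type] >= level]
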