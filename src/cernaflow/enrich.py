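"""Gene-set over-representation analysis.

Significance is the upper-tail hypergeometric probability P(X >= k) of
drawing k or more members of a K-sized term when sampling n query genes
from an N-sized universe. The reported enrichment score is -log10(p); p is
corrected across terms by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .errors import ConfigurationError
from .model import GeneSetCollection

from .diffexpr import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap count
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_value: float
    fdr: float
    enrichment_score: float


def hypergeometric_enrich(query, gene_sets: GeneSetCollection,
                          universe) -> list[EnrichmentResult]:
    """Over-representation of every term in the query, BH-corrected.

    Query ids outside the universe are dropped with a warning; term members
    are intersected with the universe before testing. k = 0 is reported with
    p = 1 (the upper tail X >= 0 is certain).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigurationError("enrichment universe is empty")
    query_all = list(dict.fromkeys(query))
    query_set = {q for q in query_all if q in universe_set}
    dropped = len(query_all) - len(query_set)
    if dropped:
        warnings.warn(f"{dropped} query id(s) outside the universe dropped",
                      stacklevel=2)
    n = len(query_set)
    N = len(universe_set)

    rows = []
    for gs in sorted(gene_sets, key=lambda g: g.term_id):
        members = set(gs.members) & universe_set
        K = len(members)
        k = len(members & query_set)
        if k == 0 or n == 0:
            p = 1.0
        else:
            # P(X >= k) for X ~ Hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p = min(max(p, 0.0), 1.0)
            if p == 0.0:
                p = 5e-324  # smallest subnormal; keeps -log10 finite-ish
        rows.append((gs, K, k, p))

    fdrs = bh_fdr([p for *_ignored, p in rows])
    results = []
    for (gs, K, k, p), fdr in zip(rows, fdrs):
        results.append(EnrichmentResult(
            term_id=gs.term_id, term_name=gs.term_name,
            k=k, K=K, n=n, N=N,
            p_value=p, fdr=float(fdr),
            enrichment_score=-math.log10(p),
        ))
    return results


def top_terms(results, k: int = 10, by: str = "enrichment_score"):
    """Top-k terms by descending enrichment score.

    Ties break by smaller FDR then lexicographic term id; k is capped at the
    number of available terms.
    """
    if by != "enrichment_score":
        raise ConfigurationError(f"unsupported ranking key {by!r}")
    ranked = sorted(results,
                    key=lambda r: (-r.enrichment_score, r.fdr, r.term_id))
    return ranked[:max(0, k)]
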