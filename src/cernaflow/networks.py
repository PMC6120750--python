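"""The three integration products of the pipeline.

* CNC network — coding/non-coding co-expression: lncRNA-mRNA pairs retained
  at |PCC| >= 0.968 and p < 0.05 (the thresholds the workflow prescribes),
  correlations pooled across all samples of both groups.
* miRNA-mRNA target network — a pair is an edge only with (i) at least one
  canonical seed site, (ii) a strong *negative* correlation passing the same
  thresholds, (iii) anti-directional differential expression.
* ceRNA network — circRNA-miRNA-mRNA triplets: the miRNA must carry a seed
  site on both the circRNA (scanned as a circle) and the mRNA, and both
  miRNA-involving correlations must pass the negative-correlation gate. The
  circRNA-mRNA correlation is annotated but not gated.

Correlations are computed on log2 expression; two-sided p-values come from
t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError
from .model import ExpressionMatrix, SequenceRecord
from .seeds import SeedSite, filter_sites, scan

_EXACT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class CoexpressionConfig:
    """Retention thresholds for correlation edges."""

    pcc_threshold: float = 0.968
    p_threshold: float = 0.05
    min_site_type: str = "6mer"

    def __post_init__(self) -> None:
        if not 0 < self.pcc_threshold <= 1:
            raise ConfigurationError("pcc_threshold must be in (0, 1]")
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class CorrelationEdge:
    node_a: str
    node_b: str
    pcc: float
    p_value: float
    class_a: str = ""
    class_b: str = ""

    @property
    def sign(self) -> str:
        return "positive" if self.pcc > 0 else "negative"


@dataclass(frozen=True)
class CeRNATriplet:
    circ_id: str
    mirna_id: str
    mrna_id: str
    r_circ_mir: float
    p_circ_mir: float
    r_mir_mrna: float
    p_mir_mrna: float
    r_circ_mrna: float
    sites_on_circ: tuple[SeedSite, ...] = field(default_factory=tuple)
    sites_on_mrna: tuple[SeedSite, ...] = field(default_factory=tuple)
    de_signs: tuple[str, str, str] = ("", "", "")  # circ, miR, mRNA directions


class PearsonResult(NamedTuple):
    pcc: float
    p_value: float
    exact_fit: bool


def pearson_with_p(x, y) -> PearsonResult:
    """Product-moment r with a two-sided p from the t transform.

    |r| = 1 (a perfect affine fit) is reported as p = 0 with the exact-fit
    flag set; constant input raises UndefinedCorrelationError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("pearson_with_p needs two equal-length vectors")
    n = x.size
    if n < 3:
        raise ConfigurationError("pearson correlation needs n >= 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigurationError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < _EXACT_FIT_TOL:
        return PearsonResult(pcc=r, p_value=0.0, exact_fit=True)
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PearsonResult(pcc=r, p_value=min(p, 1.0), exact_fit=False)


def _pairwise_pcc(a: np.ndarray, b: np.ndarray):
    """All cross-correlations between rows of a and rows of b, with p-values."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((az ** 2).sum(axis=1))
    sb = np.sqrt((bz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(1.0 - np.abs(r) < _EXACT_FIT_TOL, 0.0, p)
    return r, p


def _passing_ids(de_records, matrix: ExpressionMatrix, label: str):
    ids = []
    for rec in de_records:
        if not rec.passes_filter:
            continue
        if rec.transcript_id not in matrix.values.index:
            warnings.warn(f"{label} {rec.transcript_id!r} absent from the "
                          "expression matrix; excluded", stacklevel=3)
            continue
        ids.append(rec.transcript_id)
    return ids


def build_cnc_network(de_mrnas, de_lncrnas, matrix: ExpressionMatrix,
                      config: CoexpressionConfig = CoexpressionConfig()):
    """Coding/non-coding co-expression edges over all filtered DE pairs."""
    mrna_ids = _passing_ids(de_mrnas, matrix, "mRNA")
    lnc_ids = _passing_ids(de_lncrnas, matrix, "lncRNA")
    if not mrna_ids or not lnc_ids:
        return []
    log = matrix.log2().to_numpy()
    index = {t: i for i, t in enumerate(matrix.values.index)}
    a = log[[index[t] for t in lnc_ids]]
    b = log[[index[t] for t in mrna_ids]]
    r, p = _pairwise_pcc(a, b)
    edges = []
    for i, lnc in enumerate(lnc_ids):
        for j, mrna in enumerate(mrna_ids):
            if abs(r[i, j]) >= config.pcc_threshold and p[i, j] < config.p_threshold:
                edges.append(CorrelationEdge(node_a=lnc, node_b=mrna,
                                             pcc=float(r[i, j]),
                                             p_value=float(p[i, j]),
                                             class_a="lncRNA", class_b="mRNA"))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def _negative_edge_ok(r: float, p: float, config: CoexpressionConfig) -> bool:
    return r < 0 and abs(r) >= config.pcc_threshold and p < config.p_threshold


def build_mirna_target_network(de_mirnas, de_mrnas, sites, matrix: ExpressionMatrix,
                               config: CoexpressionConfig = CoexpressionConfig()):
    """miRNA-mRNA edges gated on seed evidence, strong negative correlation
    and anti-directional differential expression."""
    dir_of = {r.transcript_id: r.direction for r in list(de_mirnas) + list(de_mrnas)}
    mir_ids = _passing_ids(de_mirnas, matrix, "miRNA")
    mrna_ids = _passing_ids(de_mrnas, matrix, "mRNA")
    sites = filter_sites(sites, config.min_site_type)
    site_pairs: dict[tuple[str, str], list[SeedSite]] = {}
    for s in sites:
        site_pairs.setdefault((s.mirna_id, s.target_id), []).append(s)
    if not mir_ids or not mrna_ids:
        return []
    log = matrix.log2().to_numpy()
    index = {t: i for i, t in enumerate(matrix.values.index)}
    r, p = _pairwise_pcc(log[[index[t] for t in mir_ids]],
                         log[[index[t] for t in mrna_ids]])
    edges = []
    for i, mir in enumerate(mir_ids):
        for j, mrna in enumerate(mrna_ids):
            if (mir, mrna) not in site_pairs:
                continue
            if dir_of[mir] == dir_of[mrna]:
                continue  # anti-directional DE required
            if _negative_edge_ok(float(r[i, j]), float(p[i, j]), config):
                edges.append(CorrelationEdge(node_a=mir, node_b=mrna,
                                             pcc=float(r[i, j]),
                                             p_value=float(p[i, j]),
                                             class_a="miRNA", class_b="mRNA"))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def build_cerna_network(de_circs, de_mirnas, de_mrnas,
                        sequences: dict[str, SequenceRecord],
                        matrix: ExpressionMatrix,
                        config: CoexpressionConfig = CoexpressionConfig()):
    """circRNA-miRNA-mRNA triplets sharing a seed site for the same miRNA.

    circRNA sequences are scanned with circular topology (sites may span the
    backsplice junction), mRNAs as linear. Both miRNA-involving correlations
    must pass the negative-correlation gate; the circRNA-mRNA correlation is
    recorded as annotation only. Returns ``(triplets, n_missing_sequences)``.
    """
    dir_of = {r.transcript_id: r.direction
              for r in list(de_circs) + list(de_mirnas) + list(de_mrnas)}
    circ_ids = _passing_ids(de_circs, matrix, "circRNA")
    mir_ids = _passing_ids(de_mirnas, matrix, "miRNA")
    mrna_ids = _passing_ids(de_mrnas, matrix, "mRNA")

    n_missing = 0
    usable_circs, usable_mrnas = [], []
    for tid, pool, topology in ((circ_ids, usable_circs, "circular"),
                                (mrna_ids, usable_mrnas, "linear")):
        for t in tid:
            rec = sequences.get(t)
            if rec is None:
                warnings.warn(f"no sequence for {t!r}; ceRNA candidates skipped",
                              stacklevel=2)
                n_missing += 1
                continue
            if topology == "circular" and rec.topology != "circular":
                rec = SequenceRecord(id=rec.id, sequence=rec.sequence,
                                     topology="circular")
            pool.append(rec)

    mirnas = [sequences[m] for m in mir_ids if m in sequences]
    n_missing += len(mir_ids) - len(mirnas)

    # seed-site evidence
    circ_sites: dict[tuple[str, str], list[SeedSite]] = {}
    mrna_sites: dict[tuple[str, str], list[SeedSite]] = {}
    for mir in mirnas:
        for rec in usable_circs:
            hits = filter_sites(scan(mir, rec), config.min_site_type)
            if hits:
                circ_sites[(mir.id, rec.id)] = hits
        for rec in usable_mrnas:
            hits = filter_sites(scan(mir, rec), config.min_site_type)
            if hits:
                mrna_sites[(mir.id, rec.id)] = hits

    log = matrix.log2()
    index = set(matrix.values.index)

    def corr(a: str, b: str):
        return pearson_with_p(log.loc[a], log.loc[b])

    triplets = []
    for mir in mirnas:
        circ_partners = [c for c in usable_circs if (mir.id, c.id) in circ_sites]
        mrna_partners = [m for m in usable_mrnas if (mir.id, m.id) in mrna_sites]
        for circ in circ_partners:
            if circ.id not in index or mir.id not in index:
                continue
            if dir_of[circ.id] == dir_of[mir.id]:
                continue
            r_cm = corr(circ.id, mir.id)
            if not _negative_edge_ok(r_cm.pcc, r_cm.p_value, config):
                continue
            for mrna in mrna_partners:
                if mrna.id not in index:
                    continue
                if dir_of[mir.id] == dir_of[mrna.id]:
                    continue
                r_mm = corr(mir.id, mrna.id)
                if not _negative_edge_ok(r_mm.pcc, r_mm.p_value, config):
                    continue
                r_ccm = corr(circ.id, mrna.id)
                triplets.append(CeRNATriplet(
                    circ_id=circ.id, mirna_id=mir.id, mrna_id=mrna.id,
                    r_circ_mir=r_cm.pcc, p_circ_mir=r_cm.p_value,
                    r_mir_mrna=r_mm.pcc, p_mir_mrna=r_mm.p_value,
                    r_circ_mrna=r_ccm.pcc,
                    sites_on_circ=tuple(circ_sites[(mir.id, circ.id)]),
                    sites_on_mrna=tuple(mrna_sites[(mir.id, mrna.id)]),
                    de_signs=(dir_of[circ.id], dir_of[mir.id], dir_of[mrna.id]),
                ))
    # dedupe + deterministic order
    seen = set()
    unique = []
    for t in sorted(triplets, key=lambda t: (t.circ_id, t.mirna_id, t.mrna_id)):
        key = (t.circ_id, t.mirna_id, t.mrna_id)
        if key not in seen:
            seen.add(key)
            unique.append(t)
    return unique, n_missing


def triplet_edges(triplets):
    """Expand triplets into their two gating correlation edges."""
    edges = []
    for t in triplets:
        edges.append(CorrelationEdge(node_a=t.circ_id, node_b=t.mirna_id,
                                     pcc=t.r_circ_mir, p_value=t.p_circ_mir,
                                     class_a="circRNA", class_b="miRNA"))
        edges.append(CorrelationEdge(node_a=t.mirna_id, node_b=t.mrna_id,
                                     pcc=t.r_mir_mrna, p_value=t.p_mir_mrna,
                                     class_a="miRNA", class_b="mRNA"))
    return edges


def network_summary(edges_or_triplets) -> dict:
    """Deterministic node/edge/degree/sign summary of a network."""
    items = list(edges_or_triplets)
    if items and isinstance(items[0], CeRNATriplet):
        edges = triplet_edges(items)
    else:
        edges = items
    degree: dict[str, int] = {}
    sign_counts = {"positive": 0, "negative": 0}
    edge_keys = set()
    for e in edges:
        key = tuple(sorted((e.node_a, e.node_b)))
        if key in edge_keys:
            continue
        edge_keys.add(key)
        degree[e.node_a] = degree.get(e.node_a, 0) + 1
        degree[e.node_b] = degree.get(e.node_b, 0) + 1
        sign_counts[e.sign] += 1
    table = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_nodes": len(degree),
        "n_edges": len(edge_keys),
        "degree_table": table,
        "sign_counts": sign_counts,
    }
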