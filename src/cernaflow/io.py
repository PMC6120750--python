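"""Readers and writers for the standard formats the pipeline touches.

Formats: tab-separated expression matrices (first column transcript_id,
header row of sample ids), FASTA (via Biopython), GMT gene sets, BED-like
6-column annotations (chrom, start, end, transcript_id, class, strand), and
networks as SIF / GraphML / edge-list TSV. All outputs are UTF-8 with LF
line endings and deterministically ordered.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError
from .model import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SequenceRecord,
    TranscriptAnnotation,
)

NETWORK_DIALECTS = ("SIF", "GraphML", "edge-TSV")

_EDGE_TSV_COLUMNS = ("node_a", "class_a", "node_b", "class_b", "pcc", "p_value", "sign")


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file + rename so readers never see partial files."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_expression_tsv(path, group_map: dict[str, str],
                        transcript_class=None) -> ExpressionMatrix:
    """Read a transcripts x samples TSV into a validated ExpressionMatrix.

    ``transcript_class`` may be a single class applied to all rows, or a
    mapping transcript_id -> class.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"duplicate transcript id(s) in {path}: {dup}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        probe = pd.to_numeric(df[col], errors="coerce")
        if probe.isna().any():
            row = df.index[probe.isna()][0]
            raise FormatError(
                f"non-numeric value at (row={row!r}, column={col!r}) in {path}"
            )
        # numpy's strtod parse is correctly rounded (exact repr round-trip)
        values[col] = df[col].to_numpy(dtype=float)
    if isinstance(transcript_class, str):
        classes = {t: transcript_class for t in values.index}
    else:
        classes = dict(transcript_class or {})
    return ExpressionMatrix(values=values, group_of=dict(group_map),
                            transcript_class=classes)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    lines = ["transcript_id\t" + "\t".join(matrix.sample_ids)]
    for tid, row in matrix.values.iterrows():
        lines.append(tid + "\t" + "\t".join(repr(float(v)) for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_fasta(path, topology: str = "linear") -> list[SequenceRecord]:
    """Read FASTA; ids are the first whitespace token; T is mapped to U."""
    if topology not in ("linear", "circular"):
        raise ConfigurationError(f"unknown topology {topology!r}")
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq),
                                      topology=topology))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    chunks = []
    for rec in records:
        chunks.append(">" + rec.id)
        seq = rec.sequence
        chunks.extend(seq[i:i + width] for i in range(0, len(seq), width))
    atomic_write_text(path, "\n".join(chunks) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term_id TAB description TAB member..."""
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            collection.add(GeneSet(term_id=fields[0], term_name=fields[1],
                                   members=tuple(fields[2:])))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([gs.term_id, gs.term_name, *gs.members])
        for gs in sorted(collection, key=lambda g: g.term_id)
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_annotation_tsv(path) -> list[TranscriptAnnotation]:
    """BED-like 6-column TSV: chrom, start, end, transcript_id, class, strand."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, tid, cls, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append(TranscriptAnnotation(transcript_id=tid, chrom=chrom,
                                            start=start_i, end=end_i,
                                            strand=strand, transcript_class=cls))
    return out


def write_annotation_tsv(annotations: Iterable[TranscriptAnnotation], path) -> None:
    lines = [
        "\t".join([a.chrom, str(a.start), str(a.end), a.transcript_id,
                   a.transcript_class, a.strand])
        for a in annotations
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


def _sorted_edges(edges):
    return sorted(edges, key=lambda e: (e.node_a, e.node_b, e.sign))


def write_network(edges, path, dialect: str = "edge-TSV") -> None:
    """Serialize signed correlation edges with deterministic ordering."""
    if dialect not in NETWORK_DIALECTS:
        raise ConfigurationError(
            f"unknown network dialect {dialect!r}; choose from {NETWORK_DIALECTS}"
        )
    edges = _sorted_edges(edges)
    if dialect == "SIF":
        text = "".join(f"{e.node_a}\t{e.sign}\t{e.node_b}\n" for e in edges)
        atomic_write_text(path, text)
    elif dialect == "edge-TSV":
        lines = ["\t".join(_EDGE_TSV_COLUMNS)]
        for e in edges:
            lines.append("\t".join([
                e.node_a, e.class_a, e.node_b, e.class_b,
                repr(float(e.pcc)), repr(float(e.p_value)), e.sign,
            ]))
        atomic_write_text(path, "\n".join(lines) + "\n")
    else:  # GraphML
        g = nx.Graph()
        for e in edges:
            g.add_node(e.node_a, transcript_class=e.class_a)
            g.add_node(e.node_b, transcript_class=e.class_b)
            g.add_edge(e.node_a, e.node_b, pcc=float(e.pcc),
                       p_value=float(e.p_value), sign=e.sign)
        lines = nx.generate_graphml(g)
        atomic_write_text(path, "\n".join(lines) + "\n")


def read_network_tsv(path):
    """Round-trip reader for the edge-TSV dialect."""
    from .networks import CorrelationEdge

    edges = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_EDGE_TSV_COLUMNS):
            raise FormatError(f"{path}: unexpected edge-TSV header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, ca, b, cb, pcc, p, sign = line.split("\t")
            edges.append(CorrelationEdge(node_a=a, class_a=ca, node_b=b, class_b=cb,
                                         pcc=float(pcc), p_value=float(p)))
    return edges
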