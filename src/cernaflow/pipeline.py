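"""End-to-end orchestration: simulate -> DE -> classify -> networks -> enrich.

A run is driven by a YAML config (defaults injected, unknown keys rejected)
and a seed; identical config + seed produce byte-identical outputs. Every
artifact is written atomically. Steps may be run in separate invocations
against the same output directory: a step whose inputs are neither computed
in this run nor present on disk fails with an error naming the missing
step. The machine-readable ``summary.json`` contains only quantities
recomputable from the step outputs (wall time goes to the log, keeping
summaries deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .annotation import category_percentages, classify_many
from .diffexpr import DEConfig, DERecord, de_records_to_frame, \
    differential_expression, quantile_normalize
from .enrich import hypergeometric_enrich, top_terms
from .errors import ConfigurationError, DependencyError, FormatError
from .io import (
    atomic_write_text,
    read_annotation_tsv,
    read_expression_tsv,
    read_fasta,
    read_gmt,
    write_annotation_tsv,
    write_expression_tsv,
    write_fasta,
    write_gmt,
    write_network,
)
from .model import ExpressionMatrix, GeneModel
from .networks import (
    CoexpressionConfig,
    build_cerna_network,
    build_cnc_network,
    build_mirna_target_network,
    network_summary,
)
from .seeds import scan
from .simulate import TruthSet, SimulationConfig, simulate_all

log = logging.getLogger("cernaflow")

STEPS = ("simulate", "de", "classify", "networks", "enrich")

CLASS_ORDER = ("mRNA", "lncRNA", "circRNA", "miRNA")


@dataclass
class PipelineConfig:
    out_dir: str = "cernaflow_run"
    seed: int = 1
    steps: tuple[str, ...] = STEPS
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    de: DEConfig = field(default_factory=DEConfig)
    coexpression: CoexpressionConfig = field(default_factory=CoexpressionConfig)

    def __post_init__(self) -> None:
        unknown = [s for s in self.steps if s not in STEPS]
        if unknown:
            raise ConfigurationError(f"unknown step(s): {unknown}")


def _build_section(cls, raw: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name in ("baseline_log2_range", "mirna_baseline_log2_range"):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid value under {path}: {exc}") from exc


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and normalize a YAML pipeline config (empty file -> defaults)."""
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("pipeline config must be a YAML mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    allowed = {"out_dir", "seed", "steps", "log_level",
               "simulation", "de", "coexpression"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    sim_raw = dict(raw.get("simulation") or {})
    # the run seed drives the simulation unless the section pins its own
    sim_raw.setdefault("seed", int(raw.get("seed", 1)))
    return PipelineConfig(
        out_dir=str(raw.get("out_dir", "cernaflow_run")),
        seed=int(raw.get("seed", 1)),
        steps=tuple(raw.get("steps", STEPS)),
        log_level=str(raw.get("log_level", "INFO")),
        simulation=_build_section(SimulationConfig, sim_raw, "simulation"),
        de=_build_section(DEConfig, dict(raw.get("de") or {}), "de"),
        coexpression=_build_section(CoexpressionConfig,
                                    dict(raw.get("coexpression") or {}),
                                    "coexpression"),
    )


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["steps"] = list(config.steps)
    for key in ("baseline_log2_range", "mirna_baseline_log2_range"):
        d["simulation"][key] = list(d["simulation"][key])
    return d


def _json_text(payload) -> str:
    return json.dumps(payload, sort_keys=True, indent=1) + "\n"


class _Artifacts:
    """In-memory products of the current run, with fall-back to disk."""

    def __init__(self, out_dir: str):
        self.out = out_dir
        self.matrices: dict[str, ExpressionMatrix] | None = None
        self.sequences = None
        self.annotations = None
        self.gene_models: list[GeneModel] | None = None
        self.gene_sets = None
        self.truth: TruthSet | None = None
        self.de_records: dict[str, list[DERecord]] | None = None

    # -- loaders ----------------------------------------------------------
    def _need(self, filename: str, step: str) -> str:
        path = os.path.join(self.out, filename)
        if not os.path.exists(path):
            raise DependencyError(
                f"missing {filename}: run step {step!r} first"
            )
        return path

    def get_matrices(self) -> dict[str, ExpressionMatrix]:
        if self.matrices is None:
            matrices = {}
            for cls in CLASS_ORDER:
                path = self._need(f"expression_{cls}.tsv", "simulate")
                header = open(path, encoding="utf-8").readline().rstrip("\n")
                samples = header.split("\t")[1:]
                groups = {s: ("case" if s.startswith("case") else "control")
                          for s in samples}
                matrices[cls] = read_expression_tsv(path, groups, cls)
            self.matrices = matrices
        return self.matrices

    def get_sequences(self):
        if self.sequences is None:
            seqs = {}
            for fname, topology in (("mirnas.fa", "linear"),
                                    ("mrna_utrs.fa", "linear"),
                                    ("circrnas.fa", "circular")):
                for rec in read_fasta(self._need(fname, "simulate"), topology):
                    seqs[rec.id] = rec
            self.sequences = seqs
        return self.sequences

    def get_annotations(self):
        if self.annotations is None:
            self.annotations = read_annotation_tsv(
                self._need("annotation.bed", "simulate"))
        return self.annotations

    def get_gene_models(self) -> list[GeneModel]:
        if self.gene_models is None:
            self.gene_models = read_gene_models(
                self._need("gene_models.tsv", "simulate"))
        return self.gene_models

    def get_gene_sets(self):
        if self.gene_sets is None:
            self.gene_sets = read_gmt(self._need("gene_sets.gmt", "simulate"))
        return self.gene_sets

    def get_de_records(self) -> dict[str, list[DERecord]]:
        if self.de_records is None:
            records = {}
            for cls in CLASS_ORDER:
                records[cls] = read_de_tsv(self._need(f"de_{cls}.tsv", "de"))
            self.de_records = records
        return self.de_records


def write_gene_models(models, path) -> None:
    lines = ["gene_id\tchrom\tstart\tend\tstrand\texons"]
    for g in models:
        exons = ";".join(f"{s}-{e}" for s, e in g.exons)
        lines.append(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{exons}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gene_models(path) -> list[GeneModel]:
    models = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_id\t"):
            raise FormatError(f"{path}: unexpected gene-model header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gid, chrom, start, end, strand, exons = line.split("\t")
            exon_tuples = tuple(tuple(map(int, e.split("-")))
                                for e in exons.split(";"))
            models.append(GeneModel(gene_id=gid, chrom=chrom, start=int(start),
                                    end=int(end), strand=strand,
                                    exons=exon_tuples))
    return models


def read_de_tsv(path) -> list[DERecord]:
    frame = pd.read_csv(path, sep="\t")
    records = []
    for row in frame.itertuples(index=False):
        records.append(DERecord(
            transcript_id=str(row.transcript_id),
            mean_case=float(row.mean_case),
            mean_control=float(row.mean_control),
            fold_change=float(row.fold_change),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            fdr=float(row.fdr),
            direction=str(row.direction),
            passes_filter=bool(row.passes_filter),
        ))
    return records


def run(config: PipelineConfig) -> dict:
    """Execute the requested steps in dependency order; returns the summary."""
    t0 = time.monotonic()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    try:
        return _run_steps(config, out, t0)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_steps(config: PipelineConfig, out: str, t0: float) -> dict:
    atomic_write_text(os.path.join(out, "config.yaml"),
                      yaml.safe_dump(config_to_dict(config), sort_keys=True))
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "steps_run": list(config.steps),
        "steps_skipped": [s for s in STEPS if s not in config.steps],
    }
    art = _Artifacts(out)
    steps = [s for s in STEPS if s in config.steps]  # dependency order

    if "simulate" in steps:
        log.info("simulating study (seed=%d)", config.simulation.seed)
        study = simulate_all(config.simulation)
        art.matrices = study.matrices
        art.sequences = study.sequences
        art.annotations = study.annotations
        art.gene_models = study.gene_models
        art.gene_sets = study.gene_sets
        art.truth = study.truth
        for cls, matrix in study.matrices.items():
            write_expression_tsv(matrix,
                                 os.path.join(out, f"expression_{cls}.tsv"))
        for fname, prefix in (("mirnas.fa", "MIR"), ("mrna_utrs.fa", "MRNA"),
                              ("circrnas.fa", "CIRC")):
            write_fasta([study.sequences[k] for k in sorted(study.sequences)
                         if k.startswith(prefix)], os.path.join(out, fname))
        write_annotation_tsv(study.annotations,
                             os.path.join(out, "annotation.bed"))
        write_gene_models(study.gene_models,
                          os.path.join(out, "gene_models.tsv"))
        write_gmt(study.gene_sets, os.path.join(out, "gene_sets.gmt"))
        atomic_write_text(os.path.join(out, "truth.json"),
                          study.truth.to_json() + "\n")

    if "de" in steps:
        matrices = art.get_matrices()
        de_counts = {}
        art.de_records = {}
        for cls in CLASS_ORDER:
            matrix = matrices[cls]
            if cls != "miRNA":
                matrix = quantile_normalize(matrix)
            de_cfg = (dataclasses.replace(config.de, count_data=True)
                      if cls == "miRNA" else config.de)
            records = differential_expression(matrix, de_cfg)
            art.de_records[cls] = records
            atomic_write_text(
                os.path.join(out, f"de_{cls}.tsv"),
                de_records_to_frame(records).to_csv(sep="\t", index=False,
                                                    lineterminator="\n"),
            )
            up = sum(1 for r in records if r.passes_filter and r.direction == "up")
            down = sum(1 for r in records
                       if r.passes_filter and r.direction == "down")
            de_counts[cls] = {"up": up, "down": down, "tested": len(records)}
            log.info("DE %s: %d up / %d down of %d", cls, up, down, len(records))
        summary["de_counts"] = de_counts

    if "classify" in steps:
        lncs = [a for a in art.get_annotations()
                if a.transcript_class == "lncRNA"]
        categories = classify_many(lncs, art.get_gene_models())
        lines = ["transcript_id\tcategory"]
        lines += [f"{c.transcript_id}\t{c.category}" for c in categories]
        atomic_write_text(os.path.join(out, "lncrna_classes.tsv"),
                          "\n".join(lines) + "\n")
        summary["lncrna_category_percentages"] = {
            k: round(v, 6) for k, v in category_percentages(categories).items()
        }

    if "networks" in steps:
        de_records = art.get_de_records()
        matrices = art.get_matrices()
        sequences = art.get_sequences()
        cnc = build_cnc_network(
            de_records["mRNA"], de_records["lncRNA"],
            ExpressionMatrix.combine([matrices["lncRNA"], matrices["mRNA"]]),
            config.coexpression)
        write_network(cnc, os.path.join(out, "cnc_edges.tsv"), "edge-TSV")
        write_network(cnc, os.path.join(out, "cnc_edges.sif"), "SIF")

        sites = []
        mirna_ids = [r.transcript_id for r in de_records["miRNA"]
                     if r.passes_filter]
        mrna_ids = [r.transcript_id for r in de_records["mRNA"]
                    if r.passes_filter]
        for mid in mirna_ids:
            for tid in mrna_ids:
                if mid in sequences and tid in sequences:
                    sites.extend(scan(sequences[mid], sequences[tid]))
        targets = build_mirna_target_network(
            de_records["miRNA"], de_records["mRNA"], sites,
            ExpressionMatrix.combine([matrices["miRNA"], matrices["mRNA"]]),
            config.coexpression)
        write_network(targets, os.path.join(out, "target_edges.tsv"), "edge-TSV")

        triplets, n_missing = build_cerna_network(
            de_records["circRNA"], de_records["miRNA"], de_records["mRNA"],
            sequences,
            ExpressionMatrix.combine([matrices["circRNA"], matrices["miRNA"],
                                      matrices["mRNA"]]),
            config.coexpression)
        _write_triplets(triplets, out, de_records)
        summary["networks"] = {
            "cnc": _summary_dict(cnc),
            "targets": _summary_dict(targets),
            "cerna": {**_summary_dict(triplets),
                      "n_triplets": len(triplets),
                      "n_missing_sequences": n_missing},
        }
        log.info("networks: cnc %d edges, targets %d edges, %d triplets",
                 len(cnc), len(targets), len(triplets))

    if "enrich" in steps:
        de_records = art.get_de_records()
        query = [r.transcript_id for r in de_records["mRNA"] if r.passes_filter]
        universe = [r.transcript_id for r in de_records["mRNA"]]
        results = hypergeometric_enrich(query, art.get_gene_sets(), universe)
        lines = ["term_id\tterm_name\tk\tK\tn\tN\tp_value\tfdr\tenrichment_score"]
        for r in sorted(results, key=lambda r: r.term_id):
            lines.append("\t".join([
                r.term_id, r.term_name, str(r.k), str(r.K), str(r.n), str(r.N),
                repr(r.p_value), repr(r.fdr), repr(r.enrichment_score)]))
        atomic_write_text(os.path.join(out, "enrichment.tsv"),
                          "\n".join(lines) + "\n")
        summary["top_terms"] = [
            {"term_id": r.term_id,
             "enrichment_score": round(r.enrichment_score, 6),
             "fdr": float(r.fdr)}
            for r in top_terms(results, k=10)
        ]

    atomic_write_text(os.path.join(out, "summary.json"), _json_text(summary))
    log.info("run finished in %.2f s", time.monotonic() - t0)
    return summary


def _summary_dict(network) -> dict:
    s = network_summary(network)
    s["degree_table"] = [[tid, deg] for tid, deg in s["degree_table"]]
    return s


def _write_triplets(triplets, out: str, de_records) -> None:
    lines = ["circ_id\tmirna_id\tmrna_id\tr_circ_mir\tp_circ_mir"
             "\tr_mir_mrna\tp_mir_mrna\tr_circ_mrna\tde_signs"]
    for t in triplets:
        lines.append("\t".join([
            t.circ_id, t.mirna_id, t.mrna_id,
            repr(t.r_circ_mir), repr(t.p_circ_mir),
            repr(t.r_mir_mrna), repr(t.p_mir_mrna),
            repr(t.r_circ_mrna), ",".join(t.de_signs)]))
    atomic_write_text(os.path.join(out, "cerna_triplets.tsv"),
                      "\n".join(lines) + "\n")
    # node-attribute sidecar mirroring the network figure aesthetics:
    # id, class, direction, |log2fc|, p
    by_id = {}
    for cls, records in de_records.items():
        for r in records:
            by_id[r.transcript_id] = (cls, r)
    nodes = sorted({n for t in triplets
                    for n in (t.circ_id, t.mirna_id, t.mrna_id)})
    lines = ["id\tclass\tdirection\tabs_log2fc\tp_value"]
    for n in nodes:
        cls, r = by_id[n]
        lines.append("\t".join([n, cls, r.direction,
                                repr(abs(r.log2fc)), repr(r.p_value)]))
    atomic_write_text(os.path.join(out, "cerna_nodes.tsv"),
                      "\n".join(lines) + "\n")


def output_hashes(out_dir: str) -> dict[str, str]:
    """SHA-256 of every artifact (excluding the log), for determinism checks."""
    hashes = {}
    for name in sorted(os.listdir(out_dir)):
        if name == "run.log":
            continue
        path = os.path.join(out_dir, name)
        if os.path.isfile(path):
            with open(path, "rb") as fh:
                hashes[name] = hashlib.sha256(fh.read()).hexdigest()
    return hashes
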