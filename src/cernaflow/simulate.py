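"""Synthetic multi-omics study generator with a known planted truth.

Emulates the study design the pipeline targets: a two-group comparison
(default 4 ossified vs 4 normal samples) of four transcript classes, with

* log-normal intensity noise (values simulated as Normal on the log2 scale
  and exponentiated; miRNA counts are rounded exponentiated values),
* planted differentially expressed transcripts whose group-mean log2
  difference equals the planted effect,
* planted lncRNA-mRNA co-expressed pairs and circRNA-miRNA-mRNA ceRNA
  triplets built from a shared latent profile per structure, so their
  population correlation is far above the 0.968 retention threshold,
* planted miRNA seed sites (including backsplice-junction-spanning sites on
  circRNAs) realized as exact complementary site strings, with the random
  background *scrubbed* so no unplanned site of any type for any simulated
  miRNA remains,
* a toy genome realizing all six lncRNA positional categories, and
* a gene-set file with one planted enriched term.

Everything is driven by ``numpy.random.default_rng`` seeded from the
config, so identical seeds give identical output on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import (
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    SequenceRecord,
    TranscriptAnnotation,
)
from .seeds import SITE_TYPES, scan, site_patterns

_BASES = np.array(list("ACGU"))

# construction cycle for the six positional categories
_CATEGORY_CYCLE = (
    "intergenic",
    "intronic_antisense",
    "natural_antisense",
    "bidirectional",
    "intron_sense_overlapping",
    "exon_sense_overlapping",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Effect sizes are |log2 fold change|; ``noise_sd`` is the within-group
    standard deviation on the log2 scale. Members of planted correlated
    structures (pairs, triplets) draw their effects from the same
    distribution but truncated at ``structured_log2fc_min`` so they clear
    the strict fold-change filter essentially surely.
    """

    n_case: int = 4
    n_control: int = 4
    n_mrna: int = 120
    n_lncrna: int = 80
    n_circrna: int = 40
    n_mirna: int = 24
    de_fraction: float = 0.3
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5
    log2fc_min: float = 1.2
    structured_log2fc_min: float = 2.0
    noise_sd: float = 0.25
    coexpr_residual_sd: float = 0.01
    baseline_log2_range: tuple[float, float] = (6.0, 12.0)
    mirna_baseline_log2_range: tuple[float, float] = (8.0, 14.0)
    n_coexpressed_pairs: int = 8
    n_cerna_triplets: int = 5
    utr_length: int = 200
    circ_length: int = 200
    mirna_length: int = 22
    junction_site_fraction: float = 0.3
    n_background_terms: int = 10
    term_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_mrna", "n_lncrna",
                     "n_circrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.mirna_length < 8:
            raise ConfigurationError("mirna_length must be >= 8")
        if min(self.utr_length, self.circ_length) < 8:
            raise ConfigurationError("target lengths must be >= 8 nt")


@dataclass
class TruthSet:
    """Everything the generator planted, for recovery testing."""

    de_transcripts: dict[str, dict] = field(default_factory=dict)
    coexpressed_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, str, int, bool]] = field(default_factory=list)
    cerna_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    lncrna_categories: dict[str, str] = field(default_factory=dict)
    enriched_term: str | None = None

    def to_json(self) -> str:
        payload = asdict(self)
        payload["coexpressed_pairs"] = [list(t) for t in self.coexpressed_pairs]
        payload["planted_sites"] = [list(t) for t in self.planted_sites]
        payload["cerna_triplets"] = [list(t) for t in self.cerna_triplets]
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        raw = json.loads(text)
        return cls(
            de_transcripts=raw["de_transcripts"],
            coexpressed_pairs=[tuple(t) for t in raw["coexpressed_pairs"]],
            planted_sites=[tuple(t) for t in raw["planted_sites"]],
            cerna_triplets=[tuple(t) for t in raw["cerna_triplets"]],
            lncrna_categories=raw["lncrna_categories"],
            enriched_term=raw.get("enriched_term"),
        )


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    matrices: dict[str, ExpressionMatrix]
    truth: TruthSet
    sequences: dict[str, SequenceRecord]
    annotations: list[TranscriptAnnotation]
    gene_models: list[GeneModel]
    gene_sets: GeneSetCollection
    genes_per_chrom: dict[str, int]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _draw_effects(rng, size, mean, sd, floor):
    """|log2FC| ~ N(mean, sd) truncated below at ``floor`` (rejection)."""
    if sd == 0:
        return np.full(size, max(mean, floor), dtype=float)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[draw >= floor]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def simulate_expression(config: SimulationConfig):
    """One expression matrix per transcript class plus the planted truth."""
    rng = _rng(config, 0)
    samples = ([f"case_{i + 1}" for i in range(config.n_case)]
               + [f"ctrl_{i + 1}" for i in range(config.n_control)])
    group_of = {s: ("case" if s.startswith("case") else "control")
                for s in samples}
    g = np.array([0.5 if group_of[s] == "case" else -0.5 for s in samples])
    n_samples = len(samples)

    ids = {
        "mRNA": [f"MRNA{i:04d}" for i in range(config.n_mrna)],
        "lncRNA": [f"LNC{i:04d}" for i in range(config.n_lncrna)],
        "circRNA": [f"CIRC{i:04d}" for i in range(config.n_circrna)],
        "miRNA": [f"MIR{i:04d}" for i in range(config.n_mirna)],
    }
    n_de = {cls: int(round(config.de_fraction * len(ids[cls]))) for cls in ids}
    if config.n_cerna_triplets > min(n_de["circRNA"], n_de["miRNA"]):
        raise ConfigurationError(
            "n_cerna_triplets exceeds the planted DE budget for circRNA/miRNA"
        )
    if config.n_coexpressed_pairs > n_de["lncRNA"]:
        raise ConfigurationError(
            "n_coexpressed_pairs exceeds the planted DE budget for lncRNA"
        )
    if config.n_cerna_triplets + config.n_coexpressed_pairs > n_de["mRNA"]:
        raise ConfigurationError(
            "triplets + pairs exceed the planted DE budget for mRNA"
        )

    de_ids = {cls: [str(t) for t in
                    np.array(ids[cls])[rng.permutation(len(ids[cls]))[:n_de[cls]]]]
              for cls in ids}

    truth = TruthSet()
    # per-transcript generation plans: id -> (kind, params)
    plan: dict[str, dict] = {}
    for cls in ids:
        for tid in ids[cls]:
            plan[tid] = {"kind": "null"}

    def mark_de(tid, direction, lfc):
        truth.de_transcripts[tid] = {"direction": direction,
                                     "planted_log2fc": float(lfc)}

    # ceRNA triplets: circ and mRNA co-directional, miRNA anti-directional
    tri_circ = de_ids["circRNA"][:config.n_cerna_triplets]
    tri_mir = de_ids["miRNA"][:config.n_cerna_triplets]
    tri_mrna = de_ids["mRNA"][:config.n_cerna_triplets]
    for i in range(config.n_cerna_triplets):
        mirror = bool(rng.random() < 0.5)
        d_circ = -1 if mirror else 1
        latent_sd = config.noise_sd / 2.0
        h = rng.normal(0.0, latent_sd, size=n_samples)
        lfcs = _draw_effects(rng, 3, config.log2fc_mean, config.log2fc_sd,
                             config.structured_log2fc_min)
        members = ((tri_circ[i], d_circ, lfcs[0]),
                   (tri_mir[i], -d_circ, lfcs[1]),
                   (tri_mrna[i], d_circ, lfcs[2]))
        for tid, d, lfc in members:
            plan[tid] = {"kind": "structured", "direction": d, "lfc": lfc,
                         "profile": g + h}
            mark_de(tid, "up" if d > 0 else "down", lfc)
        truth.cerna_triplets.append((tri_circ[i], tri_mir[i], tri_mrna[i]))

    # co-expressed lncRNA-mRNA pairs (positive or negative sign)
    pair_lnc = de_ids["lncRNA"][:config.n_coexpressed_pairs]
    pair_mrna = de_ids["mRNA"][config.n_cerna_triplets:
                               config.n_cerna_triplets + config.n_coexpressed_pairs]
    for i in range(config.n_coexpressed_pairs):
        sign = "positive" if rng.random() < 0.5 else "negative"
        d_lnc = 1 if rng.random() < 0.5 else -1
        d_mrna = d_lnc if sign == "positive" else -d_lnc
        h = rng.normal(0.0, config.noise_sd / 2.0, size=n_samples)
        lfcs = _draw_effects(rng, 2, config.log2fc_mean, config.log2fc_sd,
                             config.structured_log2fc_min)
        for tid, d, lfc in ((pair_lnc[i], d_lnc, lfcs[0]),
                            (pair_mrna[i], d_mrna, lfcs[1])):
            plan[tid] = {"kind": "structured", "direction": d, "lfc": lfc,
                         "profile": g + h}
            mark_de(tid, "up" if d > 0 else "down", lfc)
        truth.coexpressed_pairs.append((pair_lnc[i], pair_mrna[i], sign))

    # remaining planted DE transcripts: independent noise
    for cls in ids:
        rest = [t for t in de_ids[cls] if plan[t]["kind"] == "null"]
        lfcs = _draw_effects(rng, len(rest), config.log2fc_mean,
                             config.log2fc_sd, config.log2fc_min)
        dirs = rng.random(len(rest)) < 0.5
        for tid, lfc, up in zip(rest, lfcs, dirs):
            d = 1 if up else -1
            plan[tid] = {"kind": "de", "direction": d, "lfc": lfc}
            mark_de(tid, "up" if d > 0 else "down", lfc)

    matrices: dict[str, ExpressionMatrix] = {}
    for cls in ids:
        lo, hi = (config.mirna_baseline_log2_range if cls == "miRNA"
                  else config.baseline_log2_range)
        rows = np.empty((len(ids[cls]), n_samples))
        for r, tid in enumerate(ids[cls]):
            spec = plan[tid]
            baseline = rng.uniform(lo, hi)
            if spec["kind"] == "structured":
                vals = (baseline
                        + spec["direction"] * spec["lfc"] * spec["profile"]
                        + rng.normal(0.0, config.coexpr_residual_sd, n_samples))
            elif spec["kind"] == "de":
                vals = (baseline + spec["direction"] * spec["lfc"] * g
                        + rng.normal(0.0, config.noise_sd, n_samples))
            else:
                vals = baseline + rng.normal(0.0, config.noise_sd, n_samples)
            rows[r] = vals
        linear = np.power(2.0, rows)
        if cls == "miRNA":
            linear = np.maximum(np.round(linear), 1.0)
        matrices[cls] = ExpressionMatrix(
            values=pd.DataFrame(linear, index=ids[cls], columns=samples),
            group_of=dict(group_of),
            transcript_class={t: cls for t in ids[cls]},
        )
    return matrices, truth


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _patterns_clean(new_mirna: SequenceRecord, accepted: list[SequenceRecord]) -> bool:
    """Reject seed collisions that would break exact site attribution.

    Requires the candidate's 6mer core to be distinct from every accepted
    core, absent from every accepted miRNA's site patterns (and vice versa),
    and present in its own patterns only at the canonical offsets.
    """
    pats = site_patterns(new_mirna)
    core = pats["6mer"]
    expected_offsets = {"6mer": {0}, "7mer_A1": {0}, "7mer_m8": {1}, "8mer": {1}}
    for site_type, pattern in pats.items():
        hits = {i for i in range(len(pattern) - 5)
                if pattern[i:i + 6] == core}
        if hits != expected_offsets[site_type]:
            return False
    for other in accepted:
        other_pats = site_patterns(other)
        other_core = other_pats["6mer"]
        if other_core == core:
            return False
        if any(core in p for p in other_pats.values()):
            return False
        if any(other_core in p for p in pats.values()):
            return False
    return True


def _generate_mirnas(config: SimulationConfig, rng) -> list[SequenceRecord]:
    mirnas: list[SequenceRecord] = []
    for i in range(config.n_mirna):
        for _attempt in range(1000):
            cand = SequenceRecord(id=f"MIR{i:04d}",
                                  sequence=_random_seq(rng, config.mirna_length))
            if _patterns_clean(cand, mirnas):
                mirnas.append(cand)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("could not draw a collision-free miRNA set")
    return mirnas


def _plant_window(chars: list[str], pattern: str, pos: int, circular: bool):
    """Write the site pattern at pos (wrapping on circles); returns indices."""
    n = len(chars)
    written = []
    for off, base in enumerate(pattern):
        idx = (pos + off) % n if circular else pos + off
        chars[idx] = base
        written.append(idx)
    return written


def _guard_boundaries(chars: list[str], site_type: str, pattern: str, pos: int,
                      circular: bool, mir_pats: dict[str, str], rng) -> list[int]:
    """Keep a planted site from being upgraded to a more specific type.

    A planted 6mer/7mer-m8 must not be followed by an A on the target, and a
    planted 6mer/7mer-A1 must not be preceded by the m8-complement base.
    Returns the extra protected indices.
    """
    n = len(chars)
    guarded = []
    if site_type in ("6mer", "7mer_m8"):
        after = pos + len(pattern)
        if circular or after < n:
            idx = after % n
            if chars[idx] == "A":
                chars[idx] = str(rng.choice([b for b in "CGU"]))
            guarded.append(idx)
    if site_type in ("6mer", "7mer_A1"):
        before = pos - 1
        if circular or before >= 0:
            idx = before % n
            m8_base = mir_pats["7mer_m8"][0]
            if chars[idx] == m8_base:
                chars[idx] = str(rng.choice([b for b in "ACGU" if b != m8_base]))
            guarded.append(idx)
    return guarded


def _core_positions(seq: str, core: str, circular: bool) -> list[int]:
    space = seq + seq[:5] if circular else seq
    n = len(seq)
    out = []
    start = space.find(core)
    while start != -1:
        if start < n:
            out.append(start)
        start = space.find(core, start + 1)
    return out


def _scrub_target(chars: list[str], mirnas, cores: dict[str, str],
                  expected_cores: dict[str, set[int]], protected: set[int],
                  circular: bool, rng, max_rounds: int = 100) -> bool:
    """Rewrite unplanned seed-core occurrences until none remain."""
    n = len(chars)
    for _round in range(max_rounds):
        dirty = False
        seq = "".join(chars)
        for mir in mirnas:
            core = cores[mir.id]
            allowed = expected_cores.get(mir.id, set())
            for pos in _core_positions(seq, core, circular):
                if pos in allowed:
                    continue
                free = [(pos + off) % n if circular else pos + off
                        for off in range(6)]
                free = [i for i in free if i not in protected]
                if not free:
                    return False  # cannot scrub without touching a planted site
                idx = int(rng.choice(free))
                old = chars[idx]
                chars[idx] = str(rng.choice([b for b in "ACGU" if b != old]))
                dirty = True
        if not dirty:
            return True
    return False


def simulate_sequences(config: SimulationConfig, truth: TruthSet,
                       rng: np.random.Generator | None = None):
    """miRNA, mRNA and circRNA sequences realizing the planted seed sites.

    Fills ``truth.planted_sites`` with (mirna_id, target_id, site_type,
    position, spans_junction) tuples; every planted ceRNA triplet gets one
    site on its circRNA (junction-spanning with the configured probability)
    and one on its mRNA. The background is scrubbed so a scan of any target
    finds exactly the planted sites and nothing else.
    """
    rng = _rng(config, 1) if rng is None else rng
    mirnas = _generate_mirnas(config, rng)
    mir_by_id = {m.id: m for m in mirnas}
    cores = {m.id: site_patterns(m)["6mer"] for m in mirnas}

    # plan sites for every planted triplet
    site_plan: dict[str, list[tuple[str, str, int, bool]]] = {}
    truth.planted_sites = []
    for circ_id, mir_id, mrna_id in truth.cerna_triplets:
        pats = site_patterns(mir_by_id[mir_id])
        for target_id, length, circular in ((mrna_id, config.utr_length, False),
                                            (circ_id, config.circ_length, True)):
            site_type = str(rng.choice(SITE_TYPES))
            plen = len(pats[site_type])
            if length < plen:
                raise ConfigurationError(
                    f"target length {length} too short for a {site_type} site"
                )
            junction = circular and bool(rng.random() < config.junction_site_fraction)
            if junction:
                pos = int(rng.integers(length - plen + 1, length))
            else:
                pos = int(rng.integers(0, length - plen + 1))
            site_plan.setdefault(target_id, []).append(
                (mir_id, site_type, pos, junction))
            truth.planted_sites.append((mir_id, target_id, site_type, pos, junction))

    sequences: dict[str, SequenceRecord] = {m.id: m for m in mirnas}
    targets = ([(f"MRNA{i:04d}", config.utr_length, False)
                for i in range(config.n_mrna)]
               + [(f"CIRC{i:04d}", config.circ_length, True)
                  for i in range(config.n_circrna)])
    for target_id, length, circular in targets:
        planted = site_plan.get(target_id, [])
        for _attempt in range(100):
            chars = list(_random_seq(rng, length))
            protected: set[int] = set()
            expected_cores: dict[str, set[int]] = {}
            for mir_id, site_type, pos, _junction in planted:
                pats = site_patterns(mir_by_id[mir_id])
                written = _plant_window(chars, pats[site_type], pos, circular)
                protected.update(written)
                guarded = _guard_boundaries(chars, site_type, pats[site_type],
                                            pos, circular, pats, rng)
                protected.update(guarded)
                core_off = 1 if site_type in ("7mer_m8", "8mer") else 0
                expected_cores.setdefault(mir_id, set()).add(
                    (pos + core_off) % length if circular else pos + core_off)
            if not _scrub_target(chars, mirnas, cores, expected_cores,
                                 protected, circular, rng):
                continue
            record = SequenceRecord(id=target_id, sequence="".join(chars),
                                    topology="circular" if circular else "linear")
            if _verify_target(record, mirnas, planted):
                sequences[target_id] = record
                break
        else:
            raise ConfigurationError(
                f"could not realize a clean sequence for {target_id}"
            )
    return sequences


def _verify_target(record: SequenceRecord, mirnas, planted) -> bool:
    """Collapsed scan must report exactly the planted sites."""
    expected = {(mir_id, site_type, pos) for mir_id, site_type, pos, _j in planted}
    found = set()
    for mir in mirnas:
        for hit in scan(mir, record):
            found.add((hit.mirna_id, hit.site_type, hit.start))
    return found == expected


# ---------------------------------------------------------------------------
# annotation

_N_CHROMS = 5
_EXON = 300
_INTRON = 1000
_GENE_SPAN = 3 * _EXON + 2 * _INTRON
_GENE_STEP = 10000


def _gene_coords(i: int):
    chrom = f"chr{i % _N_CHROMS + 1}"
    start = _GENE_STEP + (i // _N_CHROMS) * _GENE_STEP
    return chrom, start


def simulate_annotation(config: SimulationConfig, truth: TruthSet,
                        rng: np.random.Generator | None = None):
    """Toy genome layout realizing all six lncRNA positional categories.

    Returns ``(annotations, gene_models)``; true category labels are stored
    in ``truth.lncrna_categories``.
    """
    rng = _rng(config, 2) if rng is None else rng
    gene_models, annotations = [], []
    for i in range(config.n_mrna):
        chrom, gs = _gene_coords(i)
        exons = ((gs, gs + _EXON),
                 (gs + _EXON + _INTRON, gs + 2 * _EXON + _INTRON),
                 (gs + 2 * (_EXON + _INTRON), gs + _GENE_SPAN))
        gene_models.append(GeneModel(gene_id=f"GENE{i:04d}", chrom=chrom,
                                     start=gs, end=gs + _GENE_SPAN,
                                     strand="+", exons=exons))
        annotations.append(TranscriptAnnotation(
            transcript_id=f"MRNA{i:04d}", chrom=chrom, start=gs,
            end=gs + _GENE_SPAN, strand="+", transcript_class="mRNA"))

    truth.lncrna_categories = {}
    for i in range(config.n_lncrna):
        category = _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
        host = gene_models[i % len(gene_models)]
        gs = host.start
        if category == "intergenic":
            length = int(rng.integers(250, 900))
            start, end, strand = gs - 6000, gs - 6000 + length, "+"
        elif category == "intronic_antisense":
            length = int(rng.integers(250, 800))
            start, end, strand = gs + _EXON + 100, gs + _EXON + 100 + length, "-"
        elif category == "natural_antisense":
            length = int(rng.integers(300, 900))
            start, end, strand = gs + _EXON + _INTRON - 100, \
                gs + _EXON + _INTRON - 100 + length, "-"
        elif category == "bidirectional":
            d = int(rng.integers(50, 280))
            length = int(rng.integers(250, 1500))
            start, end, strand = gs - d - length, gs - d, "-"
        elif category == "intron_sense_overlapping":
            length = int(rng.integers(250, 800))
            start = gs + 2 * _EXON + _INTRON + 100
            end, strand = start + length, "+"
        else:  # exon_sense_overlapping
            length = int(rng.integers(250, 900))
            start, end, strand = gs + 100, gs + 100 + length, "+"
        tid = f"LNC{i:04d}"
        annotations.append(TranscriptAnnotation(
            transcript_id=tid, chrom=host.chrom, start=start, end=end,
            strand=strand, transcript_class="lncRNA"))
        truth.lncrna_categories[tid] = category

    for i in range(config.n_circrna):
        host = gene_models[i % len(gene_models)]
        annotations.append(TranscriptAnnotation(
            transcript_id=f"CIRC{i:04d}", chrom=host.chrom,
            start=host.start + 50, end=host.start + 50 + config.circ_length,
            strand="+", transcript_class="circRNA",
            length=config.circ_length))
    for i in range(config.n_mirna):
        host = gene_models[i % len(gene_models)]
        annotations.append(TranscriptAnnotation(
            transcript_id=f"MIR{i:04d}", chrom=host.chrom,
            start=host.start - 3000, end=host.start - 3000 + 80,
            strand="+", transcript_class="miRNA"))
    return annotations, gene_models


def genes_per_chromosome(gene_models) -> dict[str, int]:
    counts: dict[str, int] = {}
    for g in gene_models:
        counts[g.chrom] = counts.get(g.chrom, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# gene sets

PLANTED_TERM_ID = "SIM:PLANTED"


def simulate_gene_sets(config: SimulationConfig, truth: TruthSet,
                       rng: np.random.Generator | None = None) -> GeneSetCollection:
    """A GMT with one planted enriched term (co-upregulated mRNAs) plus
    random background terms."""
    rng = _rng(config, 3) if rng is None else rng
    all_mrnas = [f"MRNA{i:04d}" for i in range(config.n_mrna)]
    planted_up = sorted(t for t, rec in truth.de_transcripts.items()
                        if t.startswith("MRNA") and rec["direction"] == "up")
    members = planted_up[:config.term_size]
    if len(members) < 3:
        raise ConfigurationError(
            "too few planted upregulated mRNAs for an enriched term"
        )
    collection = GeneSetCollection()
    collection.add(GeneSet(term_id=PLANTED_TERM_ID,
                           term_name="planted_coregulated_module",
                           members=tuple(members)))
    for b in range(config.n_background_terms):
        size = min(config.term_size, config.n_mrna)
        picks = rng.choice(len(all_mrnas), size=size, replace=False)
        collection.add(GeneSet(term_id=f"SIM:BG{b:02d}",
                               term_name=f"background_set_{b:02d}",
                               members=tuple(all_mrnas[j] for j in sorted(picks))))
    truth.enriched_term = PLANTED_TERM_ID
    return collection


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Full study bundle: matrices, truth, sequences, annotation, gene sets."""
    matrices, truth = simulate_expression(config)
    sequences = simulate_sequences(config, truth)
    annotations, gene_models = simulate_annotation(config, truth)
    gene_sets = simulate_gene_sets(config, truth)
    return SimulatedStudy(
        config=config,
        matrices=matrices,
        truth=truth,
        sequences=sequences,
        annotations=annotations,
        gene_models=gene_models,
        gene_sets=gene_sets,
        genes_per_chrom=genes_per_chromosome(gene_models),
    )
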