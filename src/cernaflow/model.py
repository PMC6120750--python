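"""Domain types shared by every pipeline stage.

Conventions used throughout the package:

* genomic coordinates are 0-based, half-open;
* sequences are stored in the RNA alphabet (ACGU); DNA input (T) is accepted
  and converted at the boundary;
* transcript and sample identifiers are opaque, case-sensitive strings;
* expression values are linear-scale intensities or counts (>= 0, finite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

TRANSCRIPT_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
GROUPS = ("case", "control")

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(sequence: str) -> str:
    """Uppercase and map T->U. Idempotent. Raises on non-ACGU characters."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise FormatError(
            f"sequence contains non-RNA characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence, linear (mRNA/miRNA/lncRNA) or circular (circRNA)."""

    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.topology not in ("linear", "circular"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """BED-like record: genomic interval, strand and transcript class."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcript_class: str
    length: int | None = None  # defaults to end - start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"{self.transcript_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.length is None:
            object.__setattr__(self, "length", self.end - self.start)
        if self.length < 1:
            raise FormatError(f"{self.transcript_id}: length must be >= 1")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GeneModel:
    """A coding gene with exon structure, used for lncRNA classification."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise FormatError(f"{self.gene_id}: gene model needs >= 1 exon")
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise FormatError(f"{self.gene_id}: exon ({s},{e}) outside gene body")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class ExpressionMatrix:
    """A transcripts x samples table with a two-group design.

    ``values`` keeps the original row/column order; ``group_of`` assigns every
    sample to exactly one of {"case", "control"}; ``transcript_class`` tags
    every row with one of the four transcript classes.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    transcript_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate transcript id(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample id(s): {dup}")
        missing = [s for s in df.columns if s not in self.group_of]
        if missing:
            raise ConfigurationError(f"samples missing from group map: {missing}")
        bad_groups = {g for g in self.group_of.values() if g not in GROUPS}
        if bad_groups:
            raise ConfigurationError(f"unknown group label(s): {sorted(bad_groups)}")
        groups = {self.group_of[s] for s in df.columns}
        if groups != set(GROUPS):
            raise ConfigurationError("both 'case' and 'control' groups must be non-empty")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at (row={df.index[r]!r}, column={df.columns[c]!r})"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value at (row={df.index[r]!r}, column={df.columns[c]!r})"
            )
        bad_cls = {
            c for c in self.transcript_class.values() if c not in TRANSCRIPT_CLASSES
        }
        if bad_cls:
            raise ConfigurationError(f"unknown transcript class(es): {sorted(bad_cls)}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def log2(self, pseudo_count: float = 0.0) -> pd.DataFrame:
        """log2-scale view of the matrix (pseudo-count for count data)."""
        return np.log2(self.values + pseudo_count)

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids if t in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[ids],
            group_of=dict(self.group_of),
            transcript_class={t: self.transcript_class[t] for t in ids
                              if t in self.transcript_class},
        )

    @classmethod
    def combine(cls, matrices) -> "ExpressionMatrix":
        """Stack matrices that share an identical sample design."""
        matrices = list(matrices)
        first = matrices[0]
        for m in matrices[1:]:
            if m.sample_ids != first.sample_ids or m.group_of != first.group_of:
                raise ConfigurationError("matrices to combine must share samples/groups")
        classes: dict[str, str] = {}
        for m in matrices:
            classes.update(m.transcript_class)
        return cls(
            values=pd.concat([m.values for m in matrices], axis=0),
            group_of=dict(first.group_of),
            transcript_class=classes,
        )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.term_id!r} is empty")
        # de-duplicate preserving first occurrence
        seen: dict[str, None] = dict.fromkeys(self.members)
        object.__setattr__(self, "members", tuple(seen))


@dataclass
class GeneSetCollection:
    """term_id -> GeneSet mapping (GMT contents)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.term_id in self.sets:
            raise FormatError(f"duplicate term id {gene_set.term_id!r}")
        self.sets[gene_set.term_id] = gene_set
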