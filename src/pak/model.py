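"""Shared domain types for the phage-annotation toolkit.

All genomic coordinates at this interface are GFF3-style: 1-based, inclusive
at both ends, with strand ``+`` or ``-``.  Internal helpers may use 0-based
half-open slices, but every boundary is converted exactly once at the edge of
each function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "PakError",
    "FormatError",
    "DataError",
    "GenomeSequence",
    "Feature",
    "FeatureSet",
    "Hsp",
    "AlignmentRecord",
    "XmfaBlock",
    "XmfaRow",
    "TerminatorRecord",
    "reverse_complement",
]


class PakError(Exception):
    """Base class for toolkit errors."""


class FormatError(PakError):
    """A document violated its file-format contract.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataError(PakError):
    """Input parsed but violated a semantic precondition."""


_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

# Full IUPAC nucleotide alphabet accepted after upper-casing.
_NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence; the coordinate reference for features.

    ``circular`` flags circular topology; the default is linear, matching how
    phage contigs are displayed and deposited even when the packaged genome
    circularizes.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id or re.search(r"\s", self.id):
            raise DataError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.seq:
            raise DataError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _NT_ALPHABET
        if bad:
            raise DataError(
                f"sequence {self.id!r} contains non-nucleotide letters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive span [start, end], strand-aware."""
        if not (1 <= start <= end <= len(self.seq)):
            raise DataError(
                f"span {start}..{end} outside sequence {self.id!r} (length {len(self.seq)})"
            )
        s = self.seq[start - 1 : end]
        return reverse_complement(s) if strand == "-" else s


@dataclass
class Feature:
    """A GFF3-style annotation: 1-based inclusive span on a genome."""

    feature_id: str
    so_type: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    phase: Optional[int] = None
    parent_id: Optional[str] = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    source: str = "pak"
    score: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(
                f"feature {self.feature_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise DataError(f"feature {self.feature_id!r}: start {self.start} < 1")
        if self.strand not in {"+", "-", "."}:
            raise DataError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def semantic_tuple(self) -> tuple:
        """The fields preserved by I/O round trips."""
        attrs = tuple(
            (k, tuple(v))
            for k, v in sorted(self.attributes.items())
            if k not in ("ID", "Parent")
        )
        return (
            self.feature_id,
            self.so_type,
            self.seq_id,
            self.start,
            self.end,
            self.strand,
            self.phase,
            self.parent_id,
            attrs,
        )

    def copy(self) -> "Feature":
        return replace(self, attributes={k: list(v) for k, v in self.attributes.items()})


class FeatureSet:
    """An ordered collection of features with a parent/child index.

    Feature ids are unique.  A feature whose ``parent_id`` does not resolve is
    retained but reported by :meth:`dangling`.
    """

    def __init__(self, features: Iterable[Feature] = ()):
        self._features: list[Feature] = []
        self._by_id: dict[str, Feature] = {}
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        if feature.feature_id in self._by_id:
            raise DataError(f"duplicate feature id {feature.feature_id!r}")
        self._features.append(feature)
        self._by_id[feature.feature_id] = feature

    @property
    def features(self) -> list[Feature]:
        return list(self._features)

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: str) -> Feature:
        try:
            return self._by_id[feature_id]
        except KeyError:
            raise DataError(f"no feature with id {feature_id!r}") from None

    def children_of(self, feature_id: str) -> list[Feature]:
        return [f for f in self._features if f.parent_id == feature_id]

    def roots(self) -> list[Feature]:
        """Features without a resolvable parent (dangling ones included)."""
        return [
            f
            for f in self._features
            if f.parent_id is None or f.parent_id not in self._by_id
        ]

    def dangling(self) -> list[Feature]:
        """Features whose parent_id does not resolve within the set."""
        return [
            f
            for f in self._features
            if f.parent_id is not None and f.parent_id not in self._by_id
        ]

    def of_type(self, so_type: str) -> list[Feature]:
        return [f for f in self._features if f.so_type == so_type]

    def copy(self) -> "FeatureSet":
        return FeatureSet(f.copy() for f in self._features)

    def semantic_tuples(self) -> set[tuple]:
        return {f.semantic_tuple() for f in self._features}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return self.semantic_tuples() == other.semantic_tuples()

    def __repr__(self) -> str:
        return f"FeatureSet({len(self._features)} features)"


@dataclass
class Hsp:
    """One high-scoring segment pair of a query-vs-subject alignment."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identities: int
    align_len: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if self.align_len < 1:
            raise DataError(f"HSP with align_len {self.align_len} < 1")
        if not (0 <= self.identities <= self.align_len):
            raise DataError(
                f"HSP identities {self.identities} outside [0, {self.align_len}]"
            )
        if self.evalue < 0:
            raise DataError(f"HSP with negative e-value {self.evalue}")

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.align_len

    def subject_interval(self) -> tuple[int, int]:
        """Subject span as (low, high), orientation-independent."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


@dataclass
class AlignmentRecord:
    """All HSPs of one query against one subject."""

    query_id: str
    subject_id: str
    hsps: list[Hsp]
    subject_taxid: Optional[str] = None
    subject_title: Optional[str] = None
    query_len: Optional[int] = None
    subject_len: Optional[int] = None
    # optional genomic placement of the query feature
    query_genome_start: Optional[int] = None
    query_genome_end: Optional[int] = None
    query_genome_strand: Optional[str] = None

    def __post_init__(self):
        if not self.hsps:
            raise DataError(
                f"alignment record {self.query_id!r} vs {self.subject_id!r} has no HSPs"
            )

    @property
    def organism(self) -> str:
        """Grouping key for per-organism tables: taxid, else title, else id."""
        return self.subject_taxid or self.subject_title or self.subject_id


@dataclass
class XmfaRow:
    """One aligned sequence within an XMFA block."""

    seq_index: int
    start: int
    end: int
    strand: str
    text: str  # aligned sequence with '-' gaps


@dataclass
class XmfaBlock:
    """One locally collinear block of an XMFA alignment."""

    rows: list[XmfaRow]

    def __post_init__(self):
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) > 1:
            raise DataError(
                f"XMFA block rows have unequal aligned lengths: {sorted(lengths)}"
            )


@dataclass
class TerminatorRecord:
    """A rho-independent terminator prediction (TransTermHP-style)."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    stem_matches: int
    tail_seq: str

    def __post_init__(self):
        bad = set(self.tail_seq.upper()) - set("ACGT")
        if bad:
            raise DataError(
                f"terminator tail {self.tail_seq!r} has letters outside ACGT"
            )
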