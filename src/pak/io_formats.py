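"""Readers and writers for the plain-text formats the toolkit touches.

FASTA goes through Biopython; GFF3, BLAST tabular, XMFA and terminator tables
are small line formats handled directly so that writing is deterministic and
round trips are exact.

Every reader accepts a file path, an open text handle, or the document itself
as a string (detected by the presence of a newline or a format sigil).
"""

from __future__ import annotations

import io
import os
import re
from typing import IO, Iterable, Optional, Union

from Bio import SeqIO

from .model import (
    AlignmentRecord,
    DataError,
    Feature,
    FeatureSet,
    FormatError,
    GenomeSequence,
    Hsp,
    TerminatorRecord,
    XmfaBlock,
    XmfaRow,
)

__all__ = [
    "read_sequences",
    "write_sequences",
    "read_gff3",
    "write_gff3",
    "DEFAULT_BLAST_COLUMNS",
    "read_alignment_tabular",
    "read_xmfa",
    "read_terminators",
    "write_terminators",
]

Source = Union[str, os.PathLike, IO[str]]


def _as_handle(source: Source) -> IO[str]:
    """Coerce path / handle / literal document text to a text handle."""
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = os.fspath(source) if isinstance(source, os.PathLike) else str(source)
    if "\n" not in text and os.path.exists(text):
        return open(text, "r")
    return io.StringIO(text)


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(source: Source, circular: bool = False) -> list[GenomeSequence]:
    """Parse FASTA into :class:`GenomeSequence` records (upper-cased).

    Raises :class:`FormatError` on an empty stream and :class:`DataError`
    (naming the record) on non-nucleotide letters.
    """
    handle = _as_handle(source)
    out: list[GenomeSequence] = []
    for rec in SeqIO.parse(handle, "fasta"):
        try:
            out.append(GenomeSequence(id=rec.id, seq=str(rec.seq), circular=circular))
        except DataError as exc:
            raise DataError(f"record {rec.id!r}: {exc}") from None
    if not out:
        raise FormatError("no FASTA records found in input")
    return out


def write_sequences(seqs: Iterable[GenomeSequence], width: int = 70) -> str:
    lines = []
    for g in seqs:
        lines.append(f">{g.id}")
        for i in range(0, len(g.seq), width):
            lines.append(g.seq[i : i + width])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFF3

_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09", "%": "%25"}


def _escape(value: str) -> str:
    value = value.replace("%", "%25")
    for char, esc in _ESCAPES.items():
        if char != "%":
            value = value.replace(char, esc)
    return value


def _unescape(value: str) -> str:
    return re.sub(r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def read_gff3(source: Source) -> FeatureSet:
    """Parse a GFF3 document into a :class:`FeatureSet`.

    Coordinates stay 1-based inclusive.  Features with an unresolvable
    ``Parent`` are kept and reported by :meth:`FeatureSet.dangling`.
    """
    handle = _as_handle(source)
    fs = FeatureSet()
    auto = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("##FASTA"):
                break
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
        seqid, src, so_type, start_s, end_s, score_s, strand, phase_s, attr_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
        if end < start:
            raise FormatError(f"end {end} < start {start}", lineno)
        attributes: dict[str, list[str]] = {}
        for pair in attr_s.split(";"):
            pair = pair.strip()
            if not pair:
                continue
            if "=" not in pair:
                raise FormatError(f"malformed attribute {pair!r}", lineno)
            key, _, val = pair.partition("=")
            attributes[key] = [_unescape(v) for v in val.split(",")]
        fid = attributes.get("ID", [None])[0]
        if fid is None:
            auto += 1
            fid = f"_anon{auto}"
        parent = attributes.get("Parent", [None])[0]
        try:
            fs.add(
                Feature(
                    feature_id=fid,
                    so_type=so_type,
                    seq_id=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-." else ".",
                    phase=int(phase_s) if phase_s in {"0", "1", "2"} else None,
                    parent_id=parent,
                    attributes={
                        k: v for k, v in attributes.items() if k not in ("ID", "Parent")
                    },
                    source=src,
                    score=None if score_s == "." else float(score_s),
                )
            )
        except DataError as exc:
            raise FormatError(str(exc), lineno) from None
    return fs


def _feature_line(f: Feature) -> str:
    parts = []
    if f.feature_id and not f.feature_id.startswith("_anon"):
        parts.append(f"ID={_escape(f.feature_id)}")
    if f.parent_id is not None:
        parts.append(f"Parent={_escape(f.parent_id)}")
    for key in sorted(f.attributes):
        vals = ",".join(_escape(v) for v in f.attributes[key])
        parts.append(f"{key}={vals}")
    attr_s = ";".join(parts) if parts else "."
    score_s = "." if f.score is None else f"{f.score:g}"
    phase_s = "." if f.phase is None else str(f.phase)
    return "\t".join(
        [
            f.seq_id,
            f.source,
            f.so_type,
            str(f.start),
            str(f.end),
            score_s,
            f.strand,
            phase_s,
            attr_s,
        ]
    )


def write_gff3(fs: FeatureSet) -> str:
    """Serialize deterministically: parents precede children; features are
    ordered by (seq_id, start, feature_id) at every nesting level."""
    dangling = fs.dangling()
    if dangling:
        ids = ", ".join(sorted(f.feature_id for f in dangling))
        raise DataError(f"cannot write GFF3 with dangling parents: {ids}")
    lines = ["##gff-version 3"]

    def emit(feature: Feature) -> None:
        lines.append(_feature_line(feature))
        for child in sorted(
            fs.children_of(feature.feature_id),
            key=lambda c: (c.seq_id, c.start, c.feature_id),
        ):
            emit(child)

    for root in sorted(fs.roots(), key=lambda f: (f.seq_id, f.start, f.feature_id)):
        emit(root)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BLAST tabular

DEFAULT_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

_INT_COLS = {
    "length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send",
    "nident", "qlen", "slen",
}
_FLOAT_COLS = {"pident", "evalue", "bitscore"}


def read_alignment_tabular(
    source: Source, columns: Optional[list[str]] = None
) -> list[AlignmentRecord]:
    """Parse outfmt-6-style tabular alignments, grouping rows that share a
    (query, subject) pair into one record with one HSP per row.

    ``columns`` declares the column order (BLAST+ ``-outfmt 6`` field names);
    the default is the standard 12-column layout.  Identity counts come from
    an ``nident`` column when declared, otherwise they are reconstructed as
    ``round(pident/100 * length)``.
    """
    cols = list(columns) if columns else list(DEFAULT_BLAST_COLUMNS)
    required = {"qseqid", "sseqid", "length", "evalue", "bitscore"}
    missing = required - set(cols)
    if missing:
        raise DataError(f"column declaration missing required fields: {sorted(missing)}")
    if "nident" not in cols and "pident" not in cols:
        raise DataError("column declaration needs either nident or pident")

    handle = _as_handle(source)
    records: dict[tuple[str, str], AlignmentRecord] = {}
    order: list[tuple[str, str]] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise FormatError(
                f"expected {len(cols)} columns, got {len(fields)}", lineno
            )
        row: dict[str, object] = {}
        for name, value in zip(cols, fields):
            try:
                if name in _INT_COLS:
                    row[name] = int(value)
                elif name in _FLOAT_COLS:
                    row[name] = float(value)
                else:
                    row[name] = value
            except ValueError:
                raise FormatError(f"bad value {value!r} for column {name}", lineno)
        align_len = int(row["length"])  # type: ignore[arg-type]
        if "nident" in row:
            identities = int(row["nident"])  # type: ignore[arg-type]
        else:
            identities = int(float(row["pident"]) / 100.0 * align_len + 0.5)
        s_start = int(row.get("sstart", 1))
        s_end = int(row.get("send", align_len))
        q_start = int(row.get("qstart", 1))
        q_end = int(row.get("qend", align_len))
        strand = "-" if (s_end < s_start) != (q_end < q_start) else "+"
        hsp = Hsp(
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            identities=identities,
            align_len=align_len,
            evalue=float(row["evalue"]),
            bitscore=float(row["bitscore"]),
            strand=strand,
        )
        key = (str(row["qseqid"]), str(row["sseqid"]))
        if key not in records:
            records[key] = AlignmentRecord(
                query_id=key[0],
                subject_id=key[1],
                hsps=[hsp],
                subject_taxid=str(row["staxids"]) if "staxids" in row else None,
                subject_title=str(row["stitle"]) if "stitle" in row else None,
                query_len=int(row["qlen"]) if "qlen" in row else None,
                subject_len=int(row["slen"]) if "slen" in row else None,
            )
            order.append(key)
        else:
            records[key].hsps.append(hsp)
    return [records[k] for k in order]


# ---------------------------------------------------------------------------
# XMFA

_XMFA_HEADER = re.compile(r"^>\s*(\d+):(\d+)-(\d+)\s+([+-])")


def read_xmfa(source: Source) -> list[XmfaBlock]:
    """Parse XMFA (progressiveMauve dialect) into blocks.

    Blocks are terminated by ``=`` lines; gap characters are preserved.
    Rows of unequal aligned length within one block raise an error naming
    the block.
    """
    handle = _as_handle(source)
    blocks: list[XmfaBlock] = []
    rows: list[XmfaRow] = []
    chunks: list[str] = []
    header: Optional[tuple[int, int, int, str]] = None

    def flush_row():
        nonlocal header, chunks
        if header is not None:
            idx, start, end, strand = header
            rows.append(XmfaRow(idx, start, end, strand, "".join(chunks)))
        header, chunks = None, []

    def flush_block():
        nonlocal rows
        flush_row()
        if rows:
            try:
                blocks.append(XmfaBlock(rows=rows))
            except DataError as exc:
                raise FormatError(f"block {len(blocks) + 1}: {exc}") from None
        rows = []

    for raw in handle:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("="):
            flush_block()
        elif line.startswith(">"):
            flush_row()
            m = _XMFA_HEADER.match(line)
            if not m:
                raise FormatError(f"unparseable XMFA header {line!r}")
            header = (int(m.group(1)), int(m.group(2)), int(m.group(3)), m.group(4))
        else:
            chunks.append(line)
    flush_block()
    return blocks


# ---------------------------------------------------------------------------
# Terminator tables (TransTermHP-style, tab-separated)


def read_terminators(source: Source) -> list[TerminatorRecord]:
    """Parse a tab-separated terminator table:
    seq_id, start, end, strand, score, stem_matches, tail_seq."""
    handle = _as_handle(source)
    out: list[TerminatorRecord] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 7:
            raise FormatError(f"expected 7 columns, got {len(cols)}", lineno)
        try:
            out.append(
                TerminatorRecord(
                    seq_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[3],
                    score=float(cols[4]),
                    stem_matches=int(cols[5]),
                    tail_seq=cols[6],
                )
            )
        except (ValueError, DataError) as exc:
            raise FormatError(str(exc), lineno) from None
    return out


def write_terminators(records: Iterable[TerminatorRecord]) -> str:
    lines = ["#seq_id\tstart\tend\tstrand\tscore\tstem_matches\ttail_seq"]
    for r in records:
        lines.append(
            f"{r.seq_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.score:g}\t"
            f"{r.stem_matches}\t{r.tail_seq}"
        )
    return "\n".join(lines) + "\n"
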