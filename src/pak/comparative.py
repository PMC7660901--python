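"""Dice-coefficient similarity arithmetic and comparative-genomics tables.

The Dice coefficient 2m/(len_a + len_b) — identical matches m over the two
full sequence lengths — rewards total coverage, not just local identity, so
it ranks truly related genomes above short high-identity matches.  This
module applies it to alignment records (with overlap-free HSP aggregation),
ranks related organisms by shared unique proteins and by nucleotide Dice,
and converts XMFA whole-genome alignments into pairwise percent-identity
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

from .model import AlignmentRecord, DataError, Hsp, XmfaBlock

__all__ = [
    "DiceInputs",
    "RelatedOrganismRow",
    "dice_coefficient",
    "record_dice_percent",
    "dice_filter",
    "rank_by_unique_proteins",
    "rank_nucleotide_hits",
    "xmfa_identity_table",
    "rows_to_tsv",
]


@dataclass(frozen=True)
class DiceInputs:
    identical_matches: int
    len_a: int
    len_b: int

    def __post_init__(self):
        if self.len_a < 1 or self.len_b < 1:
            raise DataError("sequence lengths must be >= 1")
        if not (0 <= self.identical_matches <= min(self.len_a, self.len_b)):
            raise DataError(
                f"identical_matches {self.identical_matches} outside "
                f"[0, {min(self.len_a, self.len_b)}]"
            )


@dataclass(frozen=True)
class RelatedOrganismRow:
    name: str
    metric: float
    taxid: Optional[str] = None


def dice_coefficient(d: DiceInputs) -> float:
    """2m / (len_a + len_b), as a fraction in [0, 1]."""
    return float(Fraction(2 * d.identical_matches, d.len_a + d.len_b))


def _aggregate_identities(hsps: Sequence[Hsp]) -> int:
    """Sum identities over HSPs after removing subject-interval overlaps
    (higher bit score wins a conflict), so identity is never counted twice."""
    kept: list[tuple[int, int]] = []
    total = 0
    for h in sorted(hsps, key=lambda h: (-h.bitscore, h.evalue, h.subject_interval())):
        lo, hi = h.subject_interval()
        if any(lo <= khi and klo <= hi for klo, khi in kept):
            continue
        kept.append((lo, hi))
        total += h.identities
    return total


def record_dice_percent(record: AlignmentRecord) -> float:
    """Aggregated Dice percent of one query-vs-subject record."""
    if record.query_len is None or record.subject_len is None:
        raise DataError(
            f"record {record.query_id!r} vs {record.subject_id!r} lacks "
            "query/subject lengths (qlen/slen columns required)"
        )
    m = _aggregate_identities(record.hsps)
    return 100.0 * dice_coefficient(DiceInputs(m, record.query_len, record.subject_len))


def dice_filter(
    records: list[AlignmentRecord], min_pct: float = 50.0, max_pct: float = 100.0
) -> list[AlignmentRecord]:
    """Keep records whose Dice percent lies in [min_pct, max_pct] (closed
    interval); order preserved."""
    return [r for r in records if min_pct <= record_dice_percent(r) <= max_pct]


def rank_by_unique_proteins(
    records: list[AlignmentRecord], top_n: int = 20
) -> list[RelatedOrganismRow]:
    """Rank organisms by the number of distinct query proteins with at least
    one hit to them.  Duplicated hits from the same query never inflate the
    count.  Ties break by organism name."""
    queries: dict[str, set[str]] = {}
    taxids: dict[str, Optional[str]] = {}
    for rec in records:
        org = rec.organism
        queries.setdefault(org, set()).add(rec.query_id)
        taxids.setdefault(org, rec.subject_taxid)
    rows = [
        RelatedOrganismRow(name=org, metric=float(len(qs)), taxid=taxids[org])
        for org, qs in queries.items()
    ]
    rows.sort(key=lambda r: (-r.metric, r.name))
    return rows[:top_n]


def rank_nucleotide_hits(
    records: list[AlignmentRecord], top_n: int = 10
) -> list[RelatedOrganismRow]:
    """Rank subject genomes by aggregated Dice percent against the query
    genome.  Ties break by subject id."""
    rows = [
        RelatedOrganismRow(
            name=rec.subject_id,
            metric=record_dice_percent(rec),
            taxid=rec.subject_taxid,
        )
        for rec in records
    ]
    rows.sort(key=lambda r: (-r.metric, r.name))
    return rows[:top_n]


def xmfa_identity_table(
    blocks: list[XmfaBlock], seq_lengths: dict[int, int]
) -> pd.DataFrame:
    """Pairwise percent-identity table of an XMFA alignment, as Dice
    percents.

    For each sequence pair, m is the number of alignment columns (over all
    blocks where both sequences are present) in which neither row is gapped
    and the letters agree, case-insensitively.  Cell = 100 * 2m / (len_a +
    len_b); the table is symmetric with 100 on the diagonal.
    """
    indices = sorted(seq_lengths)
    matches: dict[tuple[int, int], int] = {}
    for bi, block in enumerate(blocks, start=1):
        for row in block.rows:
            if row.seq_index not in seq_lengths:
                raise DataError(
                    f"block {bi} references unknown sequence index {row.seq_index}"
                )
        for i, ra in enumerate(block.rows):
            for rb in block.rows[i + 1 :]:
                if ra.seq_index == rb.seq_index:
                    continue
                a, b = ra.text.upper(), rb.text.upper()
                m = sum(
                    1
                    for ca, cb in zip(a, b)
                    if ca != "-" and cb != "-" and ca == cb
                )
                key = tuple(sorted((ra.seq_index, rb.seq_index)))
                matches[key] = matches.get(key, 0) + m

    table = pd.DataFrame(0.0, index=indices, columns=indices)
    for idx in indices:
        table.loc[idx, idx] = 100.0
    for (ia, ib), m in matches.items():
        pct = 100.0 * 2 * m / (seq_lengths[ia] + seq_lengths[ib])
        table.loc[ia, ib] = pct
        table.loc[ib, ia] = pct
    return table


def rows_to_tsv(rows: list[RelatedOrganismRow], metric_name: str = "metric") -> str:
    lines = [f"name\ttaxid\t{metric_name}"]
    for r in rows:
        taxid = r.taxid if r.taxid is not None else "."
        lines.append(f"{r.name}\t{taxid}\t{r.metric:g}")
    return "\n".join(lines) + "\n"
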