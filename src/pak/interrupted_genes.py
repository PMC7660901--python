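"""Interrupted-gene detection from protein-alignment evidence.

A gene split by an intron, a programmed translational frameshift, a
sequencing artifact, or a genome opened mid-gene leaves a characteristic
signature in similarity searches: several distinct query proteins from the
genome align to complementary regions of one database protein.  This module
finds that signature.  It reports candidates with their fragments ordered
along the subject; it does not attempt to classify the interruption or
refine boundaries — those calls need manual inspection of the alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import AlignmentRecord, DataError, Feature, FeatureSet, GenomeSequence, Hsp

__all__ = [
    "InterruptedParams",
    "InterruptedCandidate",
    "filter_low_identity_hsps",
    "detect_interrupted",
    "candidates_to_tsv",
]


@dataclass(frozen=True)
class InterruptedParams:
    """Detection thresholds.

    max_sep_nt: maximum genomic distance between consecutive fragments
    (default 10,000 nt), measured between nearest interval ends, modulo the
    genome length when circular.

    sep_min: signed allowance on subject-coordinate overlap between HSPs.
    The signed separation between two subject intervals (negative when they
    overlap) must be >= sep_min, so negative values allow overlap — useful
    when gene calls with wrong starts were input — and zero/positive values
    require separation.

    min_identity_fraction: HSPs with identities/align_len strictly below
    this are discarded before detection (default 0.3).
    """

    max_sep_nt: int = 10_000
    sep_min: int = 0
    min_identity_fraction: float = 0.3
    circular: bool = False

    def __post_init__(self):
        if self.max_sep_nt <= 0:
            raise DataError(f"max_sep_nt must be positive, got {self.max_sep_nt}")
        if not (0 < self.min_identity_fraction < 1):
            raise DataError(
                f"min_identity_fraction must be in (0,1), got {self.min_identity_fraction}"
            )


@dataclass
class InterruptedCandidate:
    """One database protein hit by >=2 same-strand genomic fragments."""

    subject_id: str
    fragments: list[Feature]  # ordered along the subject
    subject_intervals: list[tuple[int, int]]
    genomic_gaps_nt: list[int]  # between consecutive fragments, len = n-1
    spans_origin: bool
    evidence: list[Hsp]


def filter_low_identity_hsps(
    records: list[AlignmentRecord], min_identity_fraction: float = 0.3
) -> list[AlignmentRecord]:
    """Drop HSPs with identities/align_len < threshold (strict); records left
    without HSPs are dropped entirely.  Idempotent and monotone."""
    out: list[AlignmentRecord] = []
    for rec in records:
        kept = [h for h in rec.hsps if h.identity_fraction >= min_identity_fraction]
        if kept:
            out.append(
                AlignmentRecord(
                    query_id=rec.query_id,
                    subject_id=rec.subject_id,
                    hsps=kept,
                    subject_taxid=rec.subject_taxid,
                    subject_title=rec.subject_title,
                    query_len=rec.query_len,
                    subject_len=rec.subject_len,
                    query_genome_start=rec.query_genome_start,
                    query_genome_end=rec.query_genome_end,
                    query_genome_strand=rec.query_genome_strand,
                )
            )
    return out


def _genomic_gap(a: Feature, b: Feature, L: int, circular: bool) -> tuple[int, bool]:
    """Nearest-end distance between two feature intervals, and whether the
    shortest path wraps the origin (circular genomes only)."""
    if a.start <= b.end and b.start <= a.end:
        return 0, False
    if b.start > a.end:
        direct = b.start - a.end - 1
        wrap = (a.start - 1) + (L - b.end) if circular else None
    else:
        direct = a.start - b.end - 1
        wrap = (b.start - 1) + (L - a.end) if circular else None
    if wrap is not None and wrap < direct:
        return wrap, True
    return direct, False


def detect_interrupted(
    records: list[AlignmentRecord],
    features: FeatureSet,
    genome: GenomeSequence,
    params: InterruptedParams = InterruptedParams(),
) -> list[InterruptedCandidate]:
    """Find subjects hit by multiple discrete genomic fragments.

    For each subject protein hit by >=2 distinct query features, the best
    HSP per query (by bit score) defines that query's subject interval.
    Requirements, applied in order: at least two mutually non-redundant HSPs
    under the sep_min allowance; all contributing query features on the same
    genomic strand; consecutive fragments (in subject order) within
    max_sep_nt on the genome, computed modulo the genome length when
    circular.  One candidate per qualifying subject.
    """
    by_subject: dict[str, list[AlignmentRecord]] = {}
    subject_order: list[str] = []
    for rec in records:
        if rec.query_id not in features:
            raise DataError(f"query id {rec.query_id!r} has no feature in the gene set")
        if rec.subject_id not in by_subject:
            subject_order.append(rec.subject_id)
        by_subject.setdefault(rec.subject_id, []).append(rec)

    L = len(genome)
    candidates: list[InterruptedCandidate] = []
    for subject_id in subject_order:
        recs = by_subject[subject_id]
        if len({r.query_id for r in recs}) < 2:
            continue
        frags: list[tuple[Feature, Hsp]] = []
        for rec in recs:
            feat = features.get(rec.query_id)
            best = max(rec.hsps, key=lambda h: (h.bitscore, -h.evalue))
            frags.append((feat, best))
        if len({f.strand for f, _ in frags}) != 1:
            continue
        # order along the subject and enforce the separation-minimum rule
        frags.sort(key=lambda fh: (fh[1].subject_interval(), fh[0].feature_id))
        kept = [frags[0]]
        for feat, hsp in frags[1:]:
            lo, _hi = hsp.subject_interval()
            _klo, khi = kept[-1][1].subject_interval()
            separation = lo - khi - 1  # negative = overlap on the subject
            if separation >= params.sep_min:
                kept.append((feat, hsp))
        if len(kept) < 2:
            continue
        gaps: list[int] = []
        spans_origin = False
        ok = True
        for (fa, _), (fb, _) in zip(kept, kept[1:]):
            gap, wrapped = _genomic_gap(fa, fb, L, params.circular)
            if gap > params.max_sep_nt:
                ok = False
                break
            gaps.append(gap)
            spans_origin = spans_origin or wrapped
        if not ok:
            continue
        candidates.append(
            InterruptedCandidate(
                subject_id=subject_id,
                fragments=[f for f, _ in kept],
                subject_intervals=[h.subject_interval() for _, h in kept],
                genomic_gaps_nt=gaps,
                spans_origin=spans_origin,
                evidence=[h for _, h in kept],
            )
        )
    return candidates


def candidates_to_tsv(candidates: list[InterruptedCandidate]) -> str:
    lines = [
        "subject_id\tn_fragments\tfragments\tgenomic_gaps_nt\tspans_origin\t"
        "subject_intervals"
    ]
    for c in candidates:
        frag_ids = ";".join(f.feature_id for f in c.fragments)
        gaps = ";".join(str(g) for g in c.genomic_gaps_nt)
        ivals = ";".join(f"{lo}-{hi}" for lo, hi in c.subject_intervals)
        lines.append(
            f"{c.subject_id}\t{len(c.fragments)}\t{frag_ids}\t{gaps}\t"
            f"{str(c.spans_origin).lower()}\t{ivals}"
        )
    return "\n".join(lines) + "\n"
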