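"""Naive ORF calling and the bespoke structural-annotation filters.

Phage genomes are compact (>90% coding density) and gene callers trained on
bacteria miss overlapping or unusual genes, so the structural workflow keeps a
deliberately noisy six-frame ORF track alongside the statistical callers.
This module provides that caller plus the downstream filters: phage
start-codon filtering, gene-model parent correction, feature-type filtering,
and promotion criteria for rho-independent terminator predictions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .model import DataError, Feature, FeatureSet, GenomeSequence, TerminatorRecord

__all__ = [
    "OrfCallParams",
    "TerminatorCriteria",
    "PHAGE_START_CODONS",
    "call_orfs",
    "filter_by_start_codon",
    "filter_feature_types",
    "ensure_gene_parents",
    "filter_terminators",
]

#: The common phage initiation codons used by the explicit start filter.
PHAGE_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


@dataclass(frozen=True)
class OrfCallParams:
    """Parameters of the naive six-frame ORF caller.

    min_aa_len counts residues excluding the stop; translation_table is an
    NCBI genetic-code number (11 = bacteria/archaea/phage).  With
    all_starts=False one ORF is emitted per stop codon, running from the
    first in-frame start; with True every in-frame start yields a variant.
    """

    min_aa_len: int = 30
    translation_table: int = 11
    require_start_and_stop: bool = True
    all_starts: bool = False

    def __post_init__(self):
        if self.min_aa_len < 1:
            raise DataError(f"min_aa_len must be >= 1, got {self.min_aa_len}")
        if self.translation_table not in CodonTable.unambiguous_dna_by_id:
            raise DataError(f"unknown NCBI translation table {self.translation_table}")

    @property
    def codon_table(self) -> CodonTable.CodonTable:
        return CodonTable.unambiguous_dna_by_id[self.translation_table]


@dataclass(frozen=True)
class TerminatorCriteria:
    """Promotion criteria for terminator predictions.

    A record is promoted when score > min_score (strict), the hairpin stem
    has >= min_stem_matches paired positions, and the tail contains a run of
    >= min_t_run consecutive T's.
    """

    min_score: float = 95.0
    min_stem_matches: int = 5
    min_t_run: int = 4

    def __post_init__(self):
        if self.min_score <= 0 or self.min_stem_matches <= 0 or self.min_t_run <= 0:
            raise DataError("terminator criteria thresholds must be positive")


def _scan_strand(seq: str, starts: frozenset, stops: frozenset, params: OrfCallParams):
    """Yield 0-based half-open spans [a, b) of ORFs on the given strand text.

    Spans include the stop codon.  Within each stop-to-stop segment the first
    in-frame start defines the (longest) ORF; all_starts emits every variant.
    """
    n = len(seq)
    min_span = 3 * (params.min_aa_len + 1)  # start..stop inclusive
    for frame in range(3):
        pending: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in stops:
                end = i + 3
                for s in pending:
                    if end - s >= min_span:
                        yield (s, end)
                        if not params.all_starts:
                            break
                pending = []
            elif codon in starts and (params.all_starts or not pending):
                pending.append(i)
            i += 3
        if pending and not params.require_start_and_stop:
            # run off the end: truncate at the last full codon, no stop
            end = frame + 3 * ((n - frame) // 3)
            for s in pending:
                if end - s >= 3 * params.min_aa_len:
                    yield (s, end)
                    if not params.all_starts:
                        break


def call_orfs(genome: GenomeSequence, params: OrfCallParams = OrfCallParams()) -> FeatureSet:
    """Call ORFs on all six frames of ``genome``.

    Start codons are those the translation table declares as initiators;
    narrowing to the phage set {ATG, GTG, TTG} is a separate, explicit step
    (:func:`filter_by_start_codon`).  Each ORF is emitted as a gene feature
    with one CDS child whose span includes the stop codon.

    On genomes flagged circular, ORFs spanning the origin are additionally
    called from a doubled-sequence scan and represented as a gene with two
    joined CDS parts carrying a ``wraparound`` attribute.
    """
    table = params.codon_table
    starts = frozenset(table.start_codons)
    stops = frozenset(table.stop_codons)
    L = len(genome)
    from .model import reverse_complement

    spans: list[tuple[int, int, str]] = []  # (start1, end1, strand)
    for a, b in _scan_strand(genome.seq, starts, stops, params):
        spans.append((a + 1, b, "+"))
    rc = reverse_complement(genome.seq)
    for a, b in _scan_strand(rc, starts, stops, params):
        spans.append((L - b + 1, L - a, "-"))

    wraps: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    if genome.circular:
        doubled = genome.seq * 2
        for a, b in _scan_strand(doubled, starts, stops, params):
            if a < L < b and b - a <= L:
                wraps.append(((a + 1, L), (1, b - L), "+"))
        rc2 = reverse_complement(doubled)
        for a, b in _scan_strand(rc2, starts, stops, params):
            c, d = 2 * L - b, 2 * L - a
            if c < L < d and d - c <= L:
                wraps.append(((c + 1, L), (1, d - L), "-"))

    entries: list[tuple] = [((s, e), None, strand) for s, e, strand in spans]
    entries.extend((p1, p2, strand) for p1, p2, strand in wraps)
    entries.sort(key=lambda t: (t[0][0], t[0][1], t[2], t[1] or (0, 0)))

    fs = FeatureSet()
    for i, (part1, part2, strand) in enumerate(entries, start=1):
        gene_id = f"{genome.id}.orf{i:04d}"
        attrs = {"wraparound": ["true"]} if part2 else {}
        fs.add(
            Feature(
                feature_id=gene_id,
                so_type="gene",
                seq_id=genome.id,
                start=part1[0],
                end=part1[1],
                strand=strand,
                attributes={k: list(v) for k, v in attrs.items()},
            )
        )
        fs.add(
            Feature(
                feature_id=f"{gene_id}.cds" + ("1" if part2 else ""),
                so_type="CDS",
                seq_id=genome.id,
                start=part1[0],
                end=part1[1],
                strand=strand,
                phase=0,
                parent_id=gene_id,
                attributes={k: list(v) for k, v in attrs.items()},
            )
        )
        if part2:
            part1_len = part1[1] - part1[0] + 1
            fs.add(
                Feature(
                    feature_id=f"{gene_id}.cds2",
                    so_type="CDS",
                    seq_id=genome.id,
                    start=part2[0],
                    end=part2[1],
                    strand=strand,
                    phase=(3 - (part1_len % 3)) % 3,
                    parent_id=gene_id,
                    attributes={k: list(v) for k, v in attrs.items()},
                )
            )
    return fs


def first_codon(cds: Feature, genome: GenomeSequence) -> str:
    """Strand-aware first codon of a CDS."""
    if len(cds) < 3:
        raise DataError(f"CDS {cds.feature_id!r} shorter than one codon")
    return genome.subseq(cds.start, cds.end, cds.strand)[:3]


def filter_by_start_codon(
    fs: FeatureSet,
    genome: GenomeSequence,
    allowed: frozenset = PHAGE_START_CODONS,
) -> FeatureSet:
    """Keep only gene/CDS groups whose first codon is in ``allowed``.

    The gene parent is removed together with a failing CDS.  Non-CDS features
    outside gene/CDS groups pass through untouched.
    """
    allowed = frozenset(c.upper() for c in allowed)
    drop: set[str] = set()
    for cds in fs.of_type("CDS"):
        if first_codon(cds, genome) not in allowed:
            drop.add(cds.feature_id)
            if cds.parent_id is not None and cds.parent_id in fs:
                parent = fs.get(cds.parent_id)
                if parent.so_type == "gene":
                    drop.add(parent.feature_id)
                    # children of a dropped gene go with it
                    for child in fs.children_of(parent.feature_id):
                        drop.add(child.feature_id)
    return FeatureSet(f.copy() for f in fs if f.feature_id not in drop)


def filter_feature_types(
    fs: FeatureSet, types: set[str], mode: str = "drop"
) -> FeatureSet:
    """Filter a feature set by SO type.

    drop: remove listed types and their descendants.
    keep: retain listed types plus their ancestors.
    """
    if mode not in {"drop", "keep"}:
        raise DataError(f"mode must be 'drop' or 'keep', got {mode!r}")
    if mode == "drop":
        removed: set[str] = set()

        def mark(fid: str) -> None:
            removed.add(fid)
            for child in fs.children_of(fid):
                mark(child.feature_id)

        for f in fs:
            if f.so_type in types:
                mark(f.feature_id)
        return FeatureSet(f.copy() for f in fs if f.feature_id not in removed)

    kept: set[str] = set()
    for f in fs:
        if f.so_type in types:
            node = f
            while True:
                kept.add(node.feature_id)
                if node.parent_id is None or node.parent_id not in fs:
                    break
                node = fs.get(node.parent_id)
    return FeatureSet(f.copy() for f in fs if f.feature_id in kept)


def ensure_gene_parents(fs: FeatureSet) -> FeatureSet:
    """Give every orphan CDS a gene parent with the same span and strand.

    Idempotent: CDS features that already resolve to a parent are untouched.
    """
    out = FeatureSet()
    existing = {f.feature_id for f in fs}
    for f in fs:
        f = f.copy()
        if f.so_type == "CDS" and (f.parent_id is None or f.parent_id not in existing):
            gene_id = f"{f.feature_id}.gene"
            n = 0
            while gene_id in existing or gene_id in out:
                n += 1
                gene_id = f"{f.feature_id}.gene{n}"
            out.add(
                Feature(
                    feature_id=gene_id,
                    so_type="gene",
                    seq_id=f.seq_id,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                )
            )
            f.parent_id = gene_id
        out.add(f)
    return out


def filter_terminators(
    records: list[TerminatorRecord], crit: TerminatorCriteria = TerminatorCriteria()
) -> list[TerminatorRecord]:
    """Promote terminator predictions meeting all three criteria.

    The score threshold is exclusive (score must exceed it); the T-run is
    searched anywhere in the tail sequence.  Order is preserved.
    """
    t_run = re.compile("T" * crit.min_t_run)
    return [
        r
        for r in records
        if r.score > crit.min_score
        and r.stem_matches >= crit.min_stem_matches
        and t_run.search(r.tail_seq.upper())
    ]
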