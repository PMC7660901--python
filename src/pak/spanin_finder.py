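"""Candidate spanin discovery.

Spanins are the phage lysis proteins that disrupt the Gram-negative outer
membrane.  The inner-membrane spanin (i-spanin) carries a transmembrane
domain; the outer-membrane spanin (o-spanin) is a lipoprotein whose signal
peptide ends in a lipobox motif at the lipoylated Cys.  Their genes sit
together — often with the o-spanin embedded in an alternate reading frame
inside the i-spanin — which defeats similarity-only annotation.  The finder
therefore works from signatures: naive ORF calling, start-codon filtering,
translation, transmembrane/lipobox evidence, and a same-strand <=50 nt
pairing rule.  The signature approach is sensitive but noisy; pairs are
evidence for review, not calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .model import AlignmentRecord, DataError, Feature, FeatureSet, GenomeSequence
from .orf_models import OrfCallParams, PHAGE_START_CODONS, call_orfs, filter_by_start_codon
from .shinefind import SdParams, annotate_shine_dalgarno

__all__ = [
    "LIPOBOX_PATTERN_1",
    "LIPOBOX_PATTERN_2",
    "KYTE_DOOLITTLE",
    "LipoboxHit",
    "TmSegment",
    "SpaninCandidate",
    "SpaninPair",
    "SpaninOptions",
    "find_lipoboxes",
    "predict_tm_segments",
    "translate_cds",
    "pair_spanin_candidates",
    "find_spanins",
    "SpaninReport",
]

# Lipobox patterns: [ILMFTV]-[any residue except R,E,K,D]-[GAS]-C  and  A-W-[AGS]-C.
# X never matches a constrained position.
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NOT_REKD = "".join(a for a in _AA20 if a not in "REKD")
LIPOBOX_PATTERN_1 = re.compile(f"(?=([ILMFTV][{_NOT_REKD}][GAS]C))")
LIPOBOX_PATTERN_2 = re.compile("(?=(AW[AGS]C))")

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class LipoboxHit:
    protein_offset: int  # 1-based residue index of the motif's first residue
    motif_text: str
    pattern_id: int  # 1 or 2


@dataclass(frozen=True)
class TmSegment:
    protein_start: int  # 1-based residue span
    protein_end: int
    mean_hydropathy: float  # peak window mean within the segment


@dataclass
class SpaninCandidate:
    orf: Feature
    role: str  # "i-spanin" | "o-spanin"
    tm_segments: list[TmSegment] = field(default_factory=list)
    lipoboxes: list[LipoboxHit] = field(default_factory=list)
    blast_support: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.role == "i-spanin" and not self.tm_segments:
            raise DataError("i-spanin candidate requires >=1 transmembrane segment")
        if self.role == "o-spanin" and not self.lipoboxes:
            raise DataError("o-spanin candidate requires >=1 lipobox hit")


@dataclass
class SpaninPair:
    i_candidate: SpaninCandidate
    o_candidate: SpaninCandidate
    architecture: str  # embedded | overlapping | separated
    separation_nt: int


def find_lipoboxes(protein: str, region_end: int = 40) -> list[LipoboxHit]:
    """All lipobox occurrences starting at residue <= region_end.

    Overlapping occurrences are all reported; the search region default (the
    first 40 residues) reflects that lipoboxes terminate signal peptides.
    """
    protein = protein.upper()
    hits: list[LipoboxHit] = []
    for pattern_id, pattern in ((1, LIPOBOX_PATTERN_1), (2, LIPOBOX_PATTERN_2)):
        for m in pattern.finditer(protein):
            offset = m.start() + 1
            if offset <= region_end:
                hits.append(LipoboxHit(offset, m.group(1), pattern_id))
    hits.sort(key=lambda h: (h.protein_offset, h.pattern_id))
    return hits


def predict_tm_segments(
    protein: str, window: int = 19, threshold: float = 1.6
) -> list[TmSegment]:
    """Transmembrane segments from sliding-window Kyte-Doolittle hydropathy.

    A hydropathy stand-in for an HMM predictor: windows of ``window`` residues
    whose mean hydropathy meets ``threshold`` are merged into maximal runs and
    reported with the peak window mean.  Proteins shorter than the window give
    no segments.
    """
    protein = protein.upper()
    n = len(protein)
    if n < window:
        return []
    scores = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    total = sum(scores[:window])
    means = [total / window]
    for i in range(1, n - window + 1):
        total += scores[i + window - 1] - scores[i - 1]
        means.append(total / window)

    segments: list[TmSegment] = []
    run_start: Optional[int] = None
    peak = float("-inf")
    # 1e-9 slack keeps the threshold comparison robust to the rolling-sum
    # floating-point error so a window mean exactly at threshold qualifies
    for i, m in enumerate(means + [float("-inf")]):  # sentinel flushes the last run
        if m >= threshold - 1e-9:
            if run_start is None:
                run_start, peak = i, m
            else:
                peak = max(peak, m)
        elif run_start is not None:
            segments.append(
                TmSegment(run_start + 1, (i - 1) + window, round(peak, 6))
            )
            run_start, peak = None, float("-inf")
    return segments


def translate_cds(cds: Feature, genome: GenomeSequence, table: int = 11) -> str:
    """Translate a CDS (stop excluded); an initiator GTG/TTG/etc. becomes M."""
    nt = genome.subseq(cds.start, cds.end, cds.strand)
    trimmed = nt[: 3 * (len(nt) // 3)]
    aa = str(Seq(trimmed).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa and "*" not in aa:
        from Bio.Data import CodonTable

        if trimmed[:3] in CodonTable.unambiguous_dna_by_id[table].start_codons:
            aa = "M" + aa[1:]
    return aa


def interval_gap(a: Feature, b: Feature) -> int:
    """Minimum genomic distance between two feature intervals; 0 when they
    overlap or one contains the other."""
    if a.start <= b.end and b.start <= a.end:
        return 0
    if b.start > a.end:
        return b.start - a.end - 1
    return a.start - b.end - 1


def _architecture(i_orf: Feature, o_orf: Feature) -> str:
    a, b = i_orf, o_orf
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return "embedded"
    if a.start <= b.end and b.start <= a.end:
        return "overlapping"
    return "separated"


def pair_spanin_candidates(
    candidates: list[SpaninCandidate],
    max_sep: int = 50,
    genome: Optional[GenomeSequence] = None,
) -> list[SpaninPair]:
    """Every (i-spanin, o-spanin) pair on the same strand within ``max_sep``
    nt (interval gap; containment or overlap counts as 0).

    An ORF carrying both kinds of evidence may appear in both candidate
    lists, but never pairs with itself.  Output order is deterministic, by
    genomic position.
    """
    i_cands = [c for c in candidates if c.role == "i-spanin"]
    o_cands = [c for c in candidates if c.role == "o-spanin"]
    pairs: list[SpaninPair] = []
    for ic in i_cands:
        for oc in o_cands:
            if ic.orf.feature_id == oc.orf.feature_id:
                continue
            if ic.orf.strand != oc.orf.strand:
                continue
            gap = interval_gap(ic.orf, oc.orf)
            if gap > max_sep:
                continue
            pairs.append(
                SpaninPair(ic, oc, _architecture(ic.orf, oc.orf), gap)
            )
    pairs.sort(
        key=lambda p: (
            min(p.i_candidate.orf.start, p.o_candidate.orf.start),
            p.i_candidate.orf.feature_id,
            p.o_candidate.orf.feature_id,
        )
    )
    return pairs


@dataclass(frozen=True)
class SpaninOptions:
    """Knobs of the spanin pipeline; defaults follow the annotation workflow
    (table 11, 30 aa minimum, phage starts, 50 nt pairing, 0.001 e-value)."""

    orf_params: OrfCallParams = OrfCallParams()
    allowed_starts: frozenset = PHAGE_START_CODONS
    sd_params: SdParams = SdParams()
    annotate_sd: bool = True
    tm_window: int = 19
    tm_threshold: float = 1.6
    lipobox_region: int = 40
    max_sep: int = 50
    evalue_cutoff: float = 1e-3


@dataclass
class SpaninReport:
    pairs: list[SpaninPair]
    candidates: list[SpaninCandidate]
    unpaired: list[SpaninCandidate]
    orfs: FeatureSet

    def to_tsv(self) -> str:
        lines = [
            "i_orf\to_orf\tstrand\tarchitecture\tseparation_nt\t"
            "lipobox\ttm_segments\tblast_support"
        ]
        for p in self.pairs:
            lb = ";".join(
                f"{h.motif_text}@{h.protein_offset}" for h in p.o_candidate.lipoboxes
            )
            tm = ";".join(
                f"{s.protein_start}-{s.protein_end}" for s in p.i_candidate.tm_segments
            )
            support = ";".join(
                sorted(set(p.i_candidate.blast_support + p.o_candidate.blast_support))
            )
            lines.append(
                f"{p.i_candidate.orf.feature_id}\t{p.o_candidate.orf.feature_id}\t"
                f"{p.i_candidate.orf.strand}\t{p.architecture}\t{p.separation_nt}\t"
                f"{lb}\t{tm}\t{support}"
            )
        for c in self.unpaired:
            lines.append(f"# unpaired {c.role}: {c.orf.feature_id}")
        return "\n".join(lines) + "\n"


def find_spanins(
    genome: GenomeSequence,
    opts: SpaninOptions = SpaninOptions(),
    db_hits: Optional[list[AlignmentRecord]] = None,
    tm_predictions: Optional[dict[str, list[TmSegment]]] = None,
) -> SpaninReport:
    """Run the spanin-finding pipeline on a genome.

    Stages: naive ORF calling -> phage start-codon filter -> (optional) S-D
    annotation -> translation -> evidence classification (TM segments give
    i-spanin candidates, lipoboxes give o-spanin candidates) -> same-strand
    <=max_sep pairing.  ``db_hits`` overlays protein-similarity support from
    a search against a curated spanin database; hits above the e-value
    cutoff are ignored.  ``tm_predictions`` (externally produced segments
    keyed by ORF or CDS id) bypass the hydropathy predictor entirely.
    """
    fs = call_orfs(genome, opts.orf_params)
    fs = filter_by_start_codon(fs, genome, opts.allowed_starts)
    if opts.annotate_sd:
        fs = annotate_shine_dalgarno(fs, genome, opts.sd_params)

    support: dict[str, list[str]] = {}
    for rec in db_hits or []:
        best = min(h.evalue for h in rec.hsps)
        if best <= opts.evalue_cutoff:
            support.setdefault(rec.query_id, []).append(rec.subject_id)

    candidates: list[SpaninCandidate] = []
    for cds in fs.of_type("CDS"):
        protein = translate_cds(cds, genome, opts.orf_params.translation_table)
        if tm_predictions is not None:
            tm = list(
                tm_predictions.get(cds.feature_id, [])
                or tm_predictions.get(cds.parent_id or "", [])
            )
        else:
            tm = predict_tm_segments(protein, opts.tm_window, opts.tm_threshold)
        lipo = find_lipoboxes(protein, opts.lipobox_region)
        hits = support.get(cds.feature_id, []) + support.get(
            cds.parent_id or "", []
        )
        orf = fs.get(cds.parent_id) if cds.parent_id else cds
        if tm:
            candidates.append(
                SpaninCandidate(orf, "i-spanin", tm_segments=tm, lipoboxes=lipo,
                                blast_support=list(hits))
            )
        if lipo:
            candidates.append(
                SpaninCandidate(orf, "o-spanin", tm_segments=tm, lipoboxes=lipo,
                                blast_support=list(hits))
            )

    pairs = pair_spanin_candidates(candidates, opts.max_sep, genome)
    paired_ids = {
        (p.i_candidate.orf.feature_id, "i-spanin") for p in pairs
    } | {(p.o_candidate.orf.feature_id, "o-spanin") for p in pairs}
    unpaired = [
        c for c in candidates if (c.orf.feature_id, c.role) not in paired_ids
    ]
    return SpaninReport(pairs=pairs, candidates=candidates, unpaired=unpaired, orfs=fs)
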