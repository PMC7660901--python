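"""Seeded synthetic fixtures with known ground truth.

Every stage of the toolkit is testable offline because this module builds
genomes, gene models, alignment records, terminator tables and XMFA
documents whose correct answers are known by construction.

The genome generator gives a hard guarantee that no unintended ORF of at
least the minimum length exists outside the planted elements:

* between planted elements, background sequence uses only C and T — no codon
  over {C,T} is a start or a stop in any frame on either strand;
* a 21-nt "stop cassette" (``TTTTAACCTAAAACACTAACT``) is inserted so that no
  background stretch exceeds ~46 nt.  The cassette carries a stop codon in
  all six reading frames and, verified exhaustively against every C/T flank
  context, leaves no start codon dangling past its last in-frame stop on
  either strand.  Any open reading frame therefore hits a stop well before
  reaching the 30-codon minimum unless it lies inside a planted element;
* planted elements are built from G-free codons (the only G's in a fixture
  genome sit inside planted ATG starts, Shine-Dalgarno motifs and the
  lipobox Cys codon, each with controlled neighbours), and every assembled
  genome is re-verified with the toolkit's own six-frame caller; the
  builder deterministically resamples filler choices until the called gene
  set equals the declared truth exactly.

All randomness flows from the spec seed; identical specs produce identical
bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    AlignmentRecord,
    DataError,
    Feature,
    FeatureSet,
    GenomeSequence,
    Hsp,
    TerminatorRecord,
    XmfaBlock,
    XmfaRow,
    reverse_complement,
)
from .orf_models import OrfCallParams, call_orfs, filter_by_start_codon
from .shinefind import SdParams, annotate_shine_dalgarno
from .spanin_finder import SpaninOptions, find_spanins

__all__ = [
    "CASSETTE",
    "SdGeneElement",
    "SpaninPairElement",
    "LipoboxOrfElement",
    "FixtureSpec",
    "FixtureTruth",
    "PlantedPair",
    "make_genome",
    "SplitGeneSpec",
    "SplitGeneFixture",
    "make_split_gene_records",
    "make_terminator_records",
    "make_xmfa_document",
]

#: Six-frame stop cassette; see module docstring.
CASSETTE = "TTTTAACCTAAAACACTAACT"

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_T11_STARTS = frozenset({"TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG"})

# G-free, non-stop codons used for planted coding sequence.  Half of them
# read as stop codons on the opposite strand, keeping reverse-frame decoys
# rare before the oracle check even runs.
_HYDROPHILIC = ("TCA", "ACT", "CCT", "TCT", "CAT", "TAC")  # S,T,P,S,H,Y
_HYDROPHOBIC = ("TTA", "ATC")  # L, I
# lipobox L-T-S-C; TCC before TGT keeps the only G out of ATG/GTG/TTG context
_LIPOBOX_CODONS = ("TTA", "ACT", "TCC", "TGT")


# ---------------------------------------------------------------------------
# element descriptors


@dataclass(frozen=True)
class SdGeneElement:
    """A plain gene with a Shine-Dalgarno motif planted upstream."""

    sd_motif: str = "AGGAGGT"
    sd_offset: int = 7  # last motif base -> first start-codon base
    n_codons: int = 35  # residues including the initiator, excluding the stop
    strand: str = "+"
    gap_before: Optional[int] = None

    def __post_init__(self):
        if self.sd_offset < 3 or self.sd_offset + len(self.sd_motif) - 1 > 24:
            raise DataError(
                f"SD motif at offset {self.sd_offset} does not fit the 3..24 window"
            )
        if self.n_codons < 30:
            raise DataError("planted genes must meet the 30-codon minimum")


@dataclass(frozen=True)
class SpaninPairElement:
    """An i-spanin/o-spanin construct: a TM-rich ORF plus a lipobox ORF.

    architecture: embedded | overlapping | separated | opposite (the last is
    a negative control: the o-ORF goes on the other strand).  separation_nt
    applies to separated/opposite; values > 50 build deliberate non-pairs.
    """

    architecture: str = "embedded"
    separation_nt: int = 20
    strand: str = "+"
    gap_before: Optional[int] = None

    def __post_init__(self):
        if self.architecture not in {"embedded", "overlapping", "separated", "opposite"}:
            raise DataError(f"unknown spanin architecture {self.architecture!r}")


@dataclass(frozen=True)
class LipoboxOrfElement:
    """A lone lipobox-bearing ORF (an o-spanin decoy with no partner)."""

    n_codons: int = 32
    strand: str = "+"
    gap_before: Optional[int] = None


Element = Union[SdGeneElement, SpaninPairElement, LipoboxOrfElement]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genome_len: int = 2000
    elements: tuple = ()
    min_spacer: int = 80
    genome_id: str = "synth"


@dataclass
class PlantedPair:
    i_span: tuple[int, int]  # 1-based inclusive genomic span
    o_span: tuple[int, int]
    strand: str
    architecture: str
    separation_nt: int


@dataclass
class FixtureTruth:
    features: FeatureSet  # planted genes + CDS + SD children
    gene_spans: set  # {(start, end, strand)}
    sd_spans: set  # {(start, end, strand)}
    pairs: list[PlantedPair]
    unpaired_roles: list[tuple]  # [(role, (start, end), strand)]


# ---------------------------------------------------------------------------
# low-level assembly helpers


def _bg(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("CT") for _ in range(n))


def _spacer(rng: random.Random, n: int) -> str:
    """n nt of non-coding filler: C/T background broken by stop cassettes so
    no background run exceeds ~46 nt."""
    if n < 10:
        return _bg(rng, n)
    parts = []
    lead = min(n, rng.randint(6, 18))
    parts.append(_bg(rng, lead))
    rem = n - lead
    while rem >= 27:
        parts.append(CASSETTE)
        rem -= 21
        b = rng.randint(6, min(20, rem))
        parts.append(_bg(rng, b))
        rem -= b
    if rem:
        parts.append(_bg(rng, rem))
    return "".join(parts)


def _upstream_clean(region: str, pos: int) -> bool:
    """True when, in the frame of ``pos``, no start codon inside ``region``
    dangles before position ``pos`` (i.e. every earlier in-frame start is
    followed by an in-frame stop before ``pos``).  Keeps the naive caller's
    first-start rule pointed at the planted ATG."""
    dangling = False
    for p in range(pos % 3, pos - 2, 3):
        codon = region[p : p + 3]
        if codon in _STOPS:
            dangling = False
        elif codon in _T11_STARTS:
            dangling = True
    return not dangling


def _codons(rng: random.Random, palette: tuple, n: int) -> list[str]:
    return [rng.choice(palette) for _ in range(n)]


def _gene_nt(rng: random.Random, n_codons: int) -> str:
    return "ATG" + "".join(_codons(rng, _HYDROPHILIC + _HYDROPHOBIC, n_codons - 1)) + "TAA"


def _o_orf_nt(rng: random.Random, n_codons: int = 32) -> str:
    """o-spanin ORF: lipobox LTSC at residues 5-8, hydrophilic elsewhere."""
    body = (
        _codons(rng, _HYDROPHILIC, 3)
        + list(_LIPOBOX_CODONS)
        + _codons(rng, _HYDROPHILIC, n_codons - 8)
    )
    return "ATG" + "".join(body) + "TAA"


def _i_head(rng: random.Random, extra: int = 10) -> str:
    """Start + 19-codon hydrophobic stretch + hydrophilic filler (no stop)."""
    return "ATG" + "".join(_codons(rng, _HYDROPHOBIC, 19) + _codons(rng, _HYDROPHILIC, extra))


def _no_stop_in_frame(s: str, phase: int, until: Optional[int] = None) -> bool:
    end = len(s) - 2 if until is None else until - 2
    return all(s[p : p + 3] not in _STOPS for p in range(phase, end, 3))


# each builder returns (region_string, rel_truth) with 0-based half-open
# spans relative to the region, on the region's forward orientation


def _build_sd_gene(rng: random.Random, el: SdGeneElement):
    gap = el.sd_offset - 1
    region = el.sd_motif.upper() + _bg(rng, gap) + _gene_nt(rng, el.n_codons)
    m = len(el.sd_motif)
    gene = (m + gap, len(region))
    return region, {"gene": [(gene, "+")], "sd": [((0, m), gene)], "pairs": [], "roles": []}


def _build_lipobox_orf(rng: random.Random, el: LipoboxOrfElement):
    region = _o_orf_nt(rng, el.n_codons)
    span = (0, len(region))
    return region, {
        "gene": [(span, "+")],
        "sd": [],
        "pairs": [],
        "roles": [("o-spanin", span)],
    }


def _build_pair(rng: random.Random, el: SpaninPairElement):
    if el.architecture == "embedded":
        for _ in range(200):
            head = _i_head(rng, extra=21)  # o begins past residue 40
            o_nt = _o_orf_nt(rng)
            shift = _bg(rng, 1)
            tail = _bg(rng, 2) + "".join(_codons(rng, _HYDROPHILIC, 3))
            coding = head + shift + o_nt + tail + "TAA"
            if len(coding) % 3:
                continue
            o_abs = len(head) + 1
            if not _no_stop_in_frame(coding, 0, until=len(coding) - 3):
                continue
            if not _upstream_clean(coding, o_abs):
                continue
            i_span = (0, len(coding))
            o_span = (o_abs, o_abs + len(o_nt))
            return coding, {
                "gene": [(i_span, "+"), (o_span, "+")],
                "sd": [],
                "pairs": [(i_span, o_span, "embedded", 0)],
                "roles": [],
            }
        raise DataError("could not compose an embedded spanin pair")

    if el.architecture == "overlapping":
        for _ in range(500):
            head = _i_head(rng, extra=rng.randint(10, 14))
            pad = _bg(rng, rng.choice([1, 2]))
            o_nt = _o_orf_nt(rng)
            region = head + pad + o_nt
            o_abs = len(head) + len(pad)
            # first i-frame stop must fall inside o's first 15 codons
            stop_at = None
            for p in range(0, len(region) - 2, 3):
                if region[p : p + 3] in _STOPS:
                    stop_at = p
                    break
            if stop_at is None:
                continue
            i_end = stop_at + 3
            if not (o_abs < i_end <= o_abs + 45) or i_end >= o_abs + len(o_nt):
                continue
            if (i_end // 3) - 1 < 30:  # i protein below the calling minimum
                continue
            if not _upstream_clean(region, o_abs):
                continue
            i_span = (0, i_end)
            o_span = (o_abs, o_abs + len(o_nt))
            return region, {
                "gene": [(i_span, "+"), (o_span, "+")],
                "sd": [],
                "pairs": [(i_span, o_span, "overlapping", 0)],
                "roles": [],
            }
        raise DataError("could not compose an overlapping spanin pair")

    # separated / opposite
    for _ in range(500):
        i_nt = _i_head(rng, extra=10) + "TAA"
        gap = _bg(rng, el.separation_nt)
        o_nt = _o_orf_nt(rng)
        o_fwd = o_nt if el.architecture == "separated" else reverse_complement(o_nt)
        region = i_nt + gap + o_fwd
        o_abs = len(i_nt) + len(gap)
        if el.architecture == "separated" and not _upstream_clean(region, o_abs):
            continue
        i_span = (0, len(i_nt))
        o_span = (o_abs, o_abs + len(o_fwd))
        if el.architecture == "separated" and el.separation_nt <= 50:
            pairs = [(i_span, o_span, "separated", el.separation_nt)]
            roles = []
        else:
            pairs = []
            roles = [("i-spanin", i_span), ("o-spanin", o_span)]
        o_rel = "+" if el.architecture == "separated" else "-"
        return region, {
            "gene": [(i_span, "+"), (o_span, o_rel)],
            "sd": [],
            "pairs": pairs,
            "roles": roles,
            "o_flipped": el.architecture == "opposite",
        }
    raise DataError("could not compose a separated spanin pair")


# ---------------------------------------------------------------------------
# genome assembly


def _place(span: tuple[int, int], off: int, region_len: int, flip: bool) -> tuple[int, int]:
    """Map a 0-based half-open region span to 1-based inclusive genome
    coordinates, mirroring when the region was reverse-complemented."""
    a, b = span
    if flip:
        a, b = region_len - b, region_len - a
    return (off + a + 1, off + b)


def _assemble(spec: FixtureSpec, rng: random.Random):
    chunks: list[str] = []
    pos = 0
    truth_features = FeatureSet()
    gene_spans: set = set()
    sd_spans: set = set()
    pairs: list[PlantedPair] = []
    roles: list[tuple] = []
    n_gene = 0

    for el in spec.elements:
        gap = el.gap_before if el.gap_before is not None else spec.min_spacer
        chunks.append(_spacer(rng, gap))
        pos += gap
        if isinstance(el, SdGeneElement):
            region, rel = _build_sd_gene(rng, el)
        elif isinstance(el, LipoboxOrfElement):
            region, rel = _build_lipobox_orf(rng, el)
        else:
            region, rel = _build_pair(rng, el)
        flip = el.strand == "-"
        placed = reverse_complement(region) if flip else region
        n = len(region)
        strand = el.strand
        for gspan, rel_strand in rel["gene"]:
            start, end = _place(gspan, pos, n, flip)
            g_strand = rel_strand if not flip else ("-" if rel_strand == "+" else "+")
            n_gene += 1
            gid = f"tgene{n_gene:03d}"
            truth_features.add(
                Feature(gid, "gene", spec.genome_id, start, end, g_strand)
            )
            truth_features.add(
                Feature(f"{gid}.cds", "CDS", spec.genome_id, start, end, g_strand,
                        phase=0, parent_id=gid)
            )
            gene_spans.add((start, end, g_strand))
        for sd_span, owner in rel["sd"]:
            start, end = _place(sd_span, pos, n, flip)
            g_start, g_end = _place(owner, pos, n, flip)
            owner_id = next(
                f.feature_id
                for f in truth_features.of_type("gene")
                if (f.start, f.end) == (g_start, g_end)
            )
            truth_features.add(
                Feature(f"{owner_id}.sd", "Shine_Dalgarno_sequence", spec.genome_id,
                        start, end, strand, parent_id=owner_id)
            )
            sd_spans.add((start, end, strand))
        for i_span, o_span, arch, sep in rel["pairs"]:
            pairs.append(
                PlantedPair(
                    i_span=_place(i_span, pos, n, flip),
                    o_span=_place(o_span, pos, n, flip),
                    strand=strand,
                    architecture=arch,
                    separation_nt=sep,
                )
            )
        for role, span in rel["roles"]:
            role_strand = strand
            if rel.get("o_flipped") and role == "o-spanin":
                role_strand = "-" if strand == "+" else "+"
            roles.append((role, _place(span, pos, n, flip), role_strand))
        chunks.append(placed)
        pos += n

    if pos + 10 > spec.genome_len:
        raise DataError(
            f"planted elements need {pos + 10} nt but genome_len is "
            f"{spec.genome_len}: elements collide with the genome end"
        )
    chunks.append(_spacer(rng, spec.genome_len - pos))
    genome = GenomeSequence(id=spec.genome_id, seq="".join(chunks))
    truth = FixtureTruth(
        features=truth_features,
        gene_spans=gene_spans,
        sd_spans=sd_spans,
        pairs=pairs,
        unpaired_roles=roles,
    )
    return genome, truth


def _verify(genome: GenomeSequence, truth: FixtureTruth, has_spanins: bool) -> bool:
    called = filter_by_start_codon(call_orfs(genome, OrfCallParams()), genome)
    spans = {(f.start, f.end, f.strand) for f in called.of_type("gene")}
    if spans != truth.gene_spans:
        return False
    annotated = annotate_shine_dalgarno(called, genome, SdParams())
    sd = {
        (f.start, f.end, f.strand)
        for f in annotated.of_type("Shine_Dalgarno_sequence")
    }
    if sd != truth.sd_spans:
        return False
    if has_spanins:
        report = find_spanins(genome)
        got = {
            (
                (p.i_candidate.orf.start, p.i_candidate.orf.end),
                (p.o_candidate.orf.start, p.o_candidate.orf.end),
                p.i_candidate.orf.strand,
                p.architecture,
                p.separation_nt,
            )
            for p in report.pairs
        }
        want = {
            (p.i_span, p.o_span, p.strand, p.architecture, p.separation_nt)
            for p in truth.pairs
        }
        if got != want:
            return False
        unpaired = {
            (c.role, (c.orf.start, c.orf.end), c.orf.strand) for c in report.unpaired
        }
        for role in truth.unpaired_roles:
            if role not in unpaired:
                return False
    return True


def make_genome(spec: FixtureSpec, max_attempts: int = 300):
    """Build a genome realizing ``spec`` plus its ground truth.

    Deterministic: a fixed spec always yields identical bytes.  Filler
    choices are resampled (deterministically) until the six-frame caller,
    S-D annotator and, when relevant, the spanin finder recover exactly the
    declared truth; an infeasible spec raises :class:`DataError`.
    """
    has_spanins = any(
        isinstance(el, (SpaninPairElement, LipoboxOrfElement)) for el in spec.elements
    )
    last_error: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = random.Random(f"{spec.seed}:{attempt}")
        try:
            genome, truth = _assemble(spec, rng)
        except DataError as exc:
            if "collide" in str(exc):
                raise
            last_error = exc
            continue
        if _verify(genome, truth, has_spanins):
            return genome, truth
    raise DataError(
        f"fixture spec (seed={spec.seed}) did not converge in {max_attempts} "
        f"attempts{f': {last_error}' if last_error else ''}"
    )


# ---------------------------------------------------------------------------
# split-gene alignment fixtures


@dataclass(frozen=True)
class SplitGeneSpec:
    seed: int = 0
    genome_len: int = 40_000
    gap_nt: int = 2_000
    across_origin: bool = False
    subject_len: int = 250
    low_identity_noise: bool = True
    opposite_strand_decoy: bool = True
    single_fragment_subject: bool = True


@dataclass
class SplitGeneFixture:
    records: list[AlignmentRecord]
    features: FeatureSet
    genome: GenomeSequence
    split_subject: str  # the subject id of the true split gene
    split_queries: list[str]
    requires_circular: bool  # detectable only with circular=True


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_split_gene_records(spec: SplitGeneSpec = SplitGeneSpec()) -> SplitGeneFixture:
    """Alignment records carrying a split-gene signature plus noise.

    Two query genes hit complementary halves of one subject protein
    (residues 1-120 and 131-250).  Noise, when enabled: an HSP below the 0.3
    identity floor, an opposite-strand fragment pair, and a subject hit by a
    single query.
    """
    rng = random.Random(f"split:{spec.seed}")
    L = spec.genome_len
    genome = GenomeSequence(id="splitfix", seq=_rand_seq(rng, L))
    fs = FeatureSet()
    if spec.across_origin:
        f1 = (200, 900)
        f2 = (L - 800, L - 50)
    else:
        f1 = (5000, 5900)
        f2 = (5901 + spec.gap_nt, 5901 + spec.gap_nt + 899)
    fs.add(Feature("q1", "CDS", "splitfix", f1[0], f1[1], "+"))
    fs.add(Feature("q2", "CDS", "splitfix", f2[0], f2[1], "+"))

    def hsp(s_lo, s_hi, ident_frac=0.9, bits=200.0):
        alen = s_hi - s_lo + 1
        return Hsp(
            q_start=1, q_end=alen, s_start=s_lo, s_end=s_hi,
            identities=int(alen * ident_frac), align_len=alen,
            evalue=1e-30, bitscore=bits,
        )

    records = [
        AlignmentRecord("q1", "sub_split", [hsp(1, 120)], subject_len=spec.subject_len),
        AlignmentRecord("q2", "sub_split", [hsp(131, 250)], subject_len=spec.subject_len),
    ]
    if spec.low_identity_noise:
        fs.add(Feature("q_low", "CDS", "splitfix", 12_000, 12_500, "+"))
        records.append(
            AlignmentRecord(
                "q_low",
                "sub_low",
                [Hsp(1, 100, 1, 100, identities=20, align_len=100,
                     evalue=1e-5, bitscore=50.0)],
            )
        )
    if spec.opposite_strand_decoy:
        fs.add(Feature("q_fwd", "CDS", "splitfix", 15_000, 15_600, "+"))
        fs.add(Feature("q_rev", "CDS", "splitfix", 16_000, 16_600, "-"))
        records.append(AlignmentRecord("q_fwd", "sub_opp", [hsp(1, 120)]))
        records.append(AlignmentRecord("q_rev", "sub_opp", [hsp(131, 250)]))
    if spec.single_fragment_subject:
        fs.add(Feature("q_solo", "CDS", "splitfix", 20_000, 20_700, "+"))
        records.append(AlignmentRecord("q_solo", "sub_single", [hsp(1, 230)]))
    return SplitGeneFixture(
        records=records,
        features=fs,
        genome=genome,
        split_subject="sub_split",
        split_queries=["q1", "q2"],
        requires_circular=spec.across_origin,
    )


# ---------------------------------------------------------------------------
# terminator battery


def make_terminator_records(seq_id: str = "synth"):
    """The 27-combination boundary battery: scores {94,95,96} x stem matches
    {4,5,6} x tail T-runs {3,4,5}.  Returns (records, expected_survivors)
    where survivors satisfy score>95, stem>=5 and T-run>=4 — four records."""
    records: list[TerminatorRecord] = []
    pos = 100
    for score in (94.0, 95.0, 96.0):
        for stem in (4, 5, 6):
            for t_run in (3, 4, 5):
                records.append(
                    TerminatorRecord(
                        seq_id=seq_id, start=pos, end=pos + 30, strand="+",
                        score=score, stem_matches=stem, tail_seq="A" + "T" * t_run + "G",
                    )
                )
                pos += 100
    expected = [
        r
        for r in records
        if r.score > 95 and r.stem_matches >= 5 and "TTTT" in r.tail_seq
    ]
    return records, expected


# ---------------------------------------------------------------------------
# XMFA document


def make_xmfa_document() -> tuple[str, dict[int, int]]:
    """A two-sequence, two-block XMFA document with a known answer: 6 of 10
    columns identical over sequences of length 10 each, i.e. a Dice percent
    identity of 2*6/(10+10) = 60%.  Returns (document, sequence lengths)."""
    doc = (
        "> 1:1-6 + seq1\n"
        "ACGTAC\n"
        "> 2:1-6 + seq2\n"
        "ACGTTT\n"
        "=\n"
        "> 1:7-10 + seq1\n"
        "GG-TA\n"
        "> 2:7-10 + seq2\n"
        "GCT-A\n"
        "=\n"
    )
    return doc, {1: 10, 2: 10}
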