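"""Shine-Dalgarno detection upstream of CDS starts.

Phages borrow the host translation machinery, so a recognizable S-D element
(E. coli consensus AGGAGGT) a few bases upstream of the start codon is strong
evidence for a gene start.  This module extracts an upstream window for each
CDS, searches it for the consensus or its sub-motifs by exact string match,
and attaches the best hit to the gene model as a ``Shine_Dalgarno_sequence``
child feature.

Conventions (fixed, documented, configurable):

* the window ``near..far`` (default 3..24) is measured in nucleotides
  upstream of the first base of the start codon;
* a match's *offset* is the distance from the last base of the motif to the
  first base of the start codon, and the motif must lie wholly inside the
  window;
* among equal-longest matches the one closest to the start codon wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import DataError, Feature, FeatureSet, GenomeSequence

__all__ = [
    "SD_CONSENSUS",
    "default_sd_candidates",
    "SdParams",
    "SdMatch",
    "upstream_window",
    "find_sd_matches",
    "best_sd_match",
    "annotate_shine_dalgarno",
]

SD_CONSENSUS = "AGGAGGT"

#: Existing child types that mean "this gene already has an RBS annotated".
RBS_TYPES = frozenset({"Shine_Dalgarno_sequence", "ribosome_entry_site"})


def default_sd_candidates(min_len: int = 4) -> list[str]:
    """The consensus plus all its contiguous substrings of length >= min_len,
    deduplicated, longest first (ties by position in the consensus)."""
    seen: list[str] = []
    for length in range(len(SD_CONSENSUS), min_len - 1, -1):
        for i in range(len(SD_CONSENSUS) - length + 1):
            sub = SD_CONSENSUS[i : i + length]
            if sub not in seen:
                seen.append(sub)
    return seen


@dataclass(frozen=True)
class SdParams:
    """Search window and candidate motifs for S-D detection."""

    window_near: int = 3
    window_far: int = 24
    candidates: tuple[str, ...] = tuple(default_sd_candidates())
    mode: str = "longest"  # longest | all

    def __post_init__(self):
        if not (1 <= self.window_near < self.window_far):
            raise DataError(
                f"need 1 <= window_near < window_far, got "
                f"{self.window_near}..{self.window_far}"
            )
        if not self.candidates:
            raise DataError("candidate motif list is empty")
        if self.mode not in {"longest", "all"}:
            raise DataError(f"mode must be 'longest' or 'all', got {self.mode!r}")
        object.__setattr__(
            self, "candidates", tuple(c.upper() for c in self.candidates)
        )


@dataclass(frozen=True)
class SdMatch:
    """One S-D motif occurrence upstream of a start codon."""

    motif: str
    offset: int  # last motif base -> first start-codon base, in nt
    start: int  # genomic span of the motif, 1-based inclusive
    end: int
    strand: str


@dataclass
class UpstreamWindow:
    """The extracted coding-strand window plus bookkeeping for coordinate
    mapping back to the genome."""

    seq: str
    far: int  # offset of the window's first base (may be < window_far at edges)
    near: int
    start_pos: int  # genomic position of the start codon's first base
    strand: str
    truncated: bool = False


def upstream_window(
    feature: Feature, genome: GenomeSequence, params: SdParams = SdParams()
) -> UpstreamWindow:
    """Extract the coding-strand sequence at offsets far..near upstream of the
    feature's start codon.

    On linear genomes the window is truncated at the sequence edge (flagged);
    on circular genomes it wraps around the origin.
    """
    L = len(genome)
    if feature.strand == "+":
        s = feature.start  # first base of the start codon
        lo = s - params.window_far
        hi = s - params.window_near
        truncated = False
        if genome.circular:
            text = "".join(genome.seq[(p - 1) % L] for p in range(lo, hi + 1))
            far = params.window_far
        else:
            lo_c = max(lo, 1)
            truncated = lo_c > lo or hi < 1
            text = genome.seq[lo_c - 1 : hi] if hi >= 1 else ""
            far = s - lo_c if text else params.window_far
        return UpstreamWindow(text, far, params.window_near, s, "+", truncated)

    s = feature.end  # first base of the start codon on the minus strand
    lo = s + params.window_near
    hi = s + params.window_far
    truncated = False
    if genome.circular:
        fwd = "".join(genome.seq[(p - 1) % L] for p in range(lo, hi + 1))
        far = params.window_far
    else:
        hi_c = min(hi, L)
        truncated = hi_c < hi or lo > L
        fwd = genome.seq[lo - 1 : hi_c] if lo <= L else ""
        far = hi_c - s if fwd else params.window_far
    from .model import reverse_complement

    return UpstreamWindow(reverse_complement(fwd), far, params.window_near, s, "-", truncated)


def _matches_in(window: UpstreamWindow, candidates: tuple[str, ...]) -> list[SdMatch]:
    out: list[SdMatch] = []
    W = len(window.seq)
    for motif in candidates:
        m = len(motif)
        for i in range(W - m + 1):
            if window.seq[i : i + m] != motif:
                continue
            j = i + m - 1  # window index of the motif's last base
            offset = window.far - j
            if offset < window.near:
                continue
            if window.strand == "+":
                g_start = window.start_pos - window.far + i
                g_end = window.start_pos - window.far + j
            else:
                g_start = window.start_pos + window.far - j
                g_end = window.start_pos + window.far - i
            out.append(SdMatch(motif, offset, g_start, g_end, window.strand))
    # deterministic: longest first, then closest to the start codon
    out.sort(key=lambda h: (-len(h.motif), h.offset, h.motif))
    return out


def find_sd_matches(
    window: UpstreamWindow, params: SdParams = SdParams()
) -> list[SdMatch]:
    """Every candidate occurrence within the window (all-mode result)."""
    return _matches_in(window, params.candidates)


def best_sd_match(
    window: UpstreamWindow, params: SdParams = SdParams()
) -> Optional[SdMatch]:
    """Longest match in the window; ties go to the smallest offset."""
    hits = _matches_in(window, params.candidates)
    return hits[0] if hits else None


def _gene_cds(fs: FeatureSet, gene: Feature) -> Optional[Feature]:
    cds = [c for c in fs.children_of(gene.feature_id) if c.so_type == "CDS"]
    if not cds:
        return None
    # the start-codon-bearing CDS part: lowest start on +, highest end on -
    if gene.strand == "-":
        return max(cds, key=lambda c: c.end)
    return min(cds, key=lambda c: c.start)


def annotate_shine_dalgarno(
    fs: FeatureSet, genome: GenomeSequence, params: SdParams = SdParams()
) -> FeatureSet:
    """Attach a Shine_Dalgarno_sequence child to every gene that has a CDS,
    lacks an RBS child, and shows a motif match in its upstream window.

    Existing features are never modified or removed; genes already carrying a
    Shine_Dalgarno_sequence or ribosome_entry_site child are skipped, so the
    operation is idempotent.
    """
    out = FeatureSet(f.copy() for f in fs)
    for gene in fs.of_type("gene"):
        if any(c.so_type in RBS_TYPES for c in fs.children_of(gene.feature_id)):
            continue
        cds = _gene_cds(fs, gene)
        if cds is None:
            continue
        if cds.seq_id != genome.id:
            raise DataError(
                f"CDS {cds.feature_id!r} references genome {cds.seq_id!r}, "
                f"not {genome.id!r}"
            )
        window = upstream_window(cds, genome, params)
        if not window.seq:
            continue
        hit = best_sd_match(window, params)
        if hit is None:
            continue
        out.add(
            Feature(
                feature_id=f"{gene.feature_id}.sd",
                so_type="Shine_Dalgarno_sequence",
                seq_id=gene.seq_id,
                start=hit.start,
                end=hit.end,
                strand=hit.strand,
                parent_id=gene.feature_id,
                attributes={"sd_motif": [hit.motif], "sd_offset": [str(hit.offset)]},
            )
        )
    return out
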