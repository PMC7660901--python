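"""Independent brute-force reference implementations used as test oracles.

These are deliberately written in a different style from the package code
(per-position scanning, explicit set membership) and never import the
implementation modules they check.
"""

from __future__ import annotations

from fractions import Fraction

STOPS = ("TAA", "TAG", "TGA")
TABLE11_STARTS = ("TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def orf_scan_oracle(seq: str, min_aa: int, all_starts: bool = False):
    """Six-frame ORF scan by walking from every start codon position.

    Returns a set of (start, end, strand) 1-based inclusive spans including
    the stop codon; one ORF per stop (the earliest start wins) unless
    all_starts.  Protein length excludes the stop codon.
    """
    L = len(seq)
    spans = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        found = {}  # (frame, stop_end) -> list of start positions
        for p in range(L - 2):
            if s[p : p + 3] not in TABLE11_STARTS:
                continue
            q = p + 3
            while q + 3 <= L:
                if s[q : q + 3] in STOPS:
                    found.setdefault((p % 3, q + 3), []).append(p)
                    break
                q += 3
        for (_frame, stop_end), ps in found.items():
            chosen = sorted(ps) if all_starts else [min(ps)]
            for p in chosen:
                n_aa = (stop_end - p) // 3 - 1
                if n_aa < min_aa:
                    continue
                if strand == "+":
                    spans.add((p + 1, stop_end, "+"))
                else:
                    spans.add((L - stop_end + 1, L - p, "-"))
    return spans


def sd_search_oracle(window: str, candidates, far: int, near: int):
    """Every candidate occurrence in the window, as (motif, offset) pairs,
    where offset counts from the motif's last base to the start codon and the
    window's first character sits at offset ``far``."""
    hits = []
    for motif in candidates:
        for i in range(len(window) - len(motif) + 1):
            if window[i : i + len(motif)] == motif:
                offset = far - (i + len(motif) - 1)
                if near <= offset:
                    hits.append((motif, offset))
    return hits


def best_sd_oracle(window: str, candidates, far: int, near: int):
    hits = sd_search_oracle(window, candidates, far, near)
    if not hits:
        return None
    return min(hits, key=lambda mo: (-len(mo[0]), mo[1], mo[0]))


_HYDRO_OK1_P1 = set("ILMFTV")
_EXCLUDED_P2 = set("REKD") | {"X"}
_P3 = set("GAS")


def lipobox_oracle(protein: str, region_end: int):
    """Position-by-position lipobox check: [ILMFTV][^REKD][GAS]C or AW[AGS]C."""
    out = []
    for i in range(len(protein) - 3):
        if i + 1 > region_end:
            break
        a, b, c, d = protein[i : i + 4]
        if d != "C":
            continue
        if a in _HYDRO_OK1_P1 and b not in _EXCLUDED_P2 and b != "*" and c in _P3:
            out.append((i + 1, protein[i : i + 4], 1))
        if a == "A" and b == "W" and c in _P3:
            out.append((i + 1, protein[i : i + 4], 2))
    return out


def dice_oracle(m: int, la: int, lb: int) -> Fraction:
    return Fraction(2 * m, la + lb)
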