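# pak — a phage-annotation toolkit

Phage genomes are compact (typically >90% coding), mosaically related, and
full of features that general prokaryotic annotation pipelines miss:
overlapping genes, lysis genes with unusual architectures, and genes split
by introns or programmed translational frameshifts.  `pak` implements the
bespoke computational stages that a careful phage annotator chains around
standard gene callers and similarity searches:

* **Shine-Dalgarno detection** — searches the window 3–24 nt upstream of
  each CDS start for the *E. coli* consensus **AGGAGGT** or any of its
  contiguous sub-motifs of length ≥ 4, and attaches the best (longest, then
  closest) match to the gene model as a `Shine_Dalgarno_sequence` child.
* **Naive ORF calling** — all six frames, NCBI translation table 11, 30 aa
  minimum, one ORF per stop codon from its first in-frame start; an explicit
  follow-up filter keeps only ORFs with a common phage start codon
  (ATG/GTG/TTG), and every CDS receives a gene parent.
* **Spanin candidate discovery** — the two-component lysis proteins are
  found by signature: transmembrane evidence (Kyte–Doolittle hydropathy,
  window 19, threshold 1.6, or externally supplied predictions) marks
  i-spanin candidates, the lipobox motifs `[ILMFTV]-[^REKD]-[GAS]-C` and
  `A-W-[AGS]-C` in the first 40 residues mark o-spanin candidates, and pairs
  must lie on the same strand within 50 nt (embedded and overlapping
  architectures count as distance 0).
* **Interrupted-gene detection** — when ≥ 2 query genes hit complementary
  regions of one database protein (HSPs with identities/length < 0.3
  discarded, ≥ 2 non-redundant HSPs, same strand, fragments within 10 kb,
  modulo the genome length for circular genomes), the gene was likely split
  by an intron, frameshift, or sequencing artifact.
* **Terminator promotion** — rho-independent terminator predictions are
  promoted only when score > 95, hairpin stem ≥ 5 matches, and the T-tail
  carries ≥ 4 consecutive T's.
* **Comparative tables** — the Dice coefficient
  `2·m / (len₁ + len₂)` over identical matches *m* drives record filtering
  (50–100% band), related-phage ranking by shared unique proteins (top 20)
  and by nucleotide Dice (top 10), and conversion of XMFA whole-genome
  alignments to pairwise percent-identity tables.

A first-class synthetic-fixture generator (`pak.fixtures`) builds seeded
genomes, gene models, alignment records, terminator batteries and XMFA
documents with known ground truth, so the whole toolkit is testable with no
downloads.

## Worked example

```python
from pak.fixtures import FixtureSpec, SpaninPairElement, LipoboxOrfElement, make_genome
from pak.spanin_finder import find_spanins

genome, truth = make_genome(FixtureSpec(
    seed=303, genome_len=3000,
    elements=(SpaninPairElement(architecture="embedded"),
              LipoboxOrfElement(gap_before=400)),
))
print(find_spanins(genome).to_tsv())
```

prints

```
i_orf	o_orf	strand	architecture	separation_nt	lipobox	tm_segments	blast_support
synth.orf0001	synth.orf0003	+	embedded	0	LTSC@5	1-29;39-71;56-75	
# unpaired o-spanin: synth.orf0005
```

One pair is reported: a 99-nt o-spanin ORF embedded in an alternate reading
frame inside the i-spanin ORF, with its lipobox (`LTSC`) at residue 5 and
the i-spanin's transmembrane segments listed.  The planted lipobox decoy
400 nt away fails the 50-nt rule and appears only as an unpaired candidate
— exactly the noise the signature approach expects a reviewer to dismiss.

More narrative scripts live in `examples/`, one per capability.

## Command line

Every stage is also a `pak` subcommand (`pak --help`):
`convert`, `validate`, `orfs`, `filter-starts`, `filter-types`,
`filter-terminators`, `shinefind`, `spanins`, `interrupted`, `dice-filter`,
`rank-proteins`, `rank-nt`, `xmfa-identity`, `fixtures`, `structural`
(ORFs → start filter → gene parents → S-D), and `reports` (Dice/ranking
tables, interrupted genes, spanins).  All subcommands are deterministic
given fixed inputs and document their defaults in `--help`; exit codes are
0 (success), 1 (usage), 2 (data/format).

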