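# Methods

This note records the models, conventions and design choices behind each
stage of the toolkit, in enough detail to reproduce or audit them.

## Coordinates and formats

All interface coordinates are GFF3: 1-based, inclusive at both ends, strand
`+`/`-`.  Internal scans use 0-based half-open indices and convert exactly
once at each function boundary.  FASTA parsing goes through Biopython;
GFF3, BLAST-tabular, XMFA and terminator tables are handled by small
purpose-built readers/writers so that serialization is deterministic
(parents before children, features ordered by `(seq_id, start, feature_id)`,
attributes in fixed order) and `write ∘ read ∘ write` is a byte-level fixed
point.  Alignment input is accepted as tabular records with a declared
column list (default: the standard 12-column `outfmt 6` layout); when no
`nident` column is declared, identity counts are reconstructed as
`round(pident/100 × length)`.  Wraparound features on circular genomes are
represented as two joined parts sharing a `wraparound` attribute rather
than as `end > genome length`, which keeps per-feature invariants checkable.

## Naive ORF calling

The caller scans all six frames.  Start codons at this stage are the
translation table's declared initiators (table 11: TTG, CTG, ATT, ATC, ATA,
ATG, GTG); the deliberate narrowing to the common phage set {ATG, GTG, TTG}
is a separate, explicit filter so that the two decisions remain visible in
the pipeline.  For each stop-to-stop segment one ORF is emitted, running
from the first in-frame start to the stop (inclusive of the stop codon — the
prokaryotic GFF3 convention, which keeps coding-density arithmetic in line
with deposited records); `all_starts=True` emits one variant per start.
The minimum length (default 30) counts residues excluding the stop.
`require_start_and_stop=False` additionally emits start-anchored ORFs that
run off the sequence end, truncated at the last full codon; the default
requires both.  Origin-spanning ORFs on genomes flagged circular are found
by re-scanning the doubled sequence and keeping spans that cross the seam
(at most one full genome length).  Every behaviour is pinned by an
independently coded per-position brute-force scan used as a test oracle.

## Shine-Dalgarno detection

Candidates default to AGGAGGT plus all its contiguous substrings of length
≥ 4 (10 motifs, longest first); the list is user-replaceable.  The window
`near..far` (default 3..24) is measured in nucleotides upstream of the
first base of the start codon, and a match's offset runs from the last
motif base to that first base; the motif must lie wholly inside the window.
These conventions are fixed and documented rather than inferred — the
upstream-window arithmetic admits more than one reading and any consistent
one is testable.  Matching is exact string matching (no mismatches, no
IUPAC expansion).  In `longest` mode, ties among equal-longest matches go
to the occurrence closest to the start codon, favouring the canonical
short spacing.  Annotation adds one `Shine_Dalgarno_sequence` child per
eligible gene; genes already owning a `Shine_Dalgarno_sequence` *or*
`ribosome_entry_site` child are skipped (upstream tools use both
spellings), which makes the operation idempotent.  Windows truncate at
linear-genome edges with a warning flag, and wrap on circular genomes.

## Spanin discovery

The pipeline is: ORF calling (table 11, ≥ 30 aa) → phage start filter →
S-D annotation → translation (an initiator GTG/TTG becomes Met) →
classification → pairing.  Transmembrane evidence uses a Kyte–Doolittle
sliding-window stand-in for an HMM predictor: window 19 residues, mean
hydropathy threshold 1.6 (the classical values), maximal runs of qualifying
windows merged into segments; the comparison carries 1e-9 slack so a mean
exactly at threshold qualifies despite rolling-sum rounding.  Externally
produced TM predictions can be supplied and bypass the predictor entirely.
Lipobox patterns are `[ILMFTV]-[any residue except R,E,K,D]-[GAS]-C` and
`A-W-[AGS]-C`, searched in the first 40 residues (lipoboxes terminate
signal peptides; the bound is configurable), `X` never matching a
constrained position.  Pair separation is the minimum genomic distance
between the two ORF intervals — containment or overlap counts as 0, so the
embedded architecture passes its own ≤ 50 nt rule by construction.  An ORF
carrying both evidence types may appear in both candidate lists but never
pairs with itself.  Protein-similarity support from a user-supplied curated
spanin database is overlaid at an e-value cutoff of 0.001.  The method is
a deliberately sensitive signature screen: false pairs are expected and
surfaced for review, so tests assert perfect recall of planted pairs, not
precision.

## Interrupted genes

Records are grouped by subject; subjects hit by ≥ 2 distinct query features
are examined.  Each query's best HSP (by bit score) defines its subject
interval.  The separation-minimum rule is a single signed inequality:
`next.s_start − prev.s_end − 1 ≥ sep_min`, applied along the subject, so a
negative `sep_min` allows bounded overlap (tolerating gene calls with wrong
starts) and a non-negative one requires separation; the default 0 allows
abutting-but-not-overlapping intervals.  Surviving fragments must share a
genomic strand, and consecutive fragments (in subject order) must lie within
`max_sep_nt` (default 10,000) measured between nearest interval ends —
modulo genome length when circular, which is what detects genes split
across the genome ends; a candidate is flagged `spans_origin` when the
shorter arc between two fragments crosses the seam.  No intron/frameshift/
artifact class labels are assigned and no boundaries are refined: those
judgements need a human with the alignments in front of them.  No e-value
threshold is applied inside the detector beyond what the upstream search
used.

## Comparative genomics

`dice_coefficient` computes `2m/(len_a+len_b)` in exact rational arithmetic
before converting to float.  For a multi-HSP record, identities are summed
after discarding subject-interval overlaps (higher bit score wins a
conflict) so identity is never counted twice; the aggregate then enters the
printed formula with both full lengths.  The Dice filter band (default
50–100%) is closed at both ends.  Protein ranking counts distinct query ids
per organism (taxid, else title, else subject id) so repeated HSPs never
inflate a score; nucleotide ranking orders subjects by aggregated Dice
percent; all ties break lexicographically for reproducibility.  XMFA
identity counts columns where both rows are present, neither is gapped, and
the letters agree case-insensitively (alignment tools emit mixed case),
summed over blocks; cells are `100 × 2m/(len_a+len_b)`, the diagonal is
fixed at 100, and pairs never co-aligned score 0.

## Terminator promotion

A prediction is promoted iff score **strictly** exceeds 95, the stem has
≥ 5 paired positions, and the tail contains ≥ 4 consecutive T's anywhere
(no offset bound is imposed on the run's position within the tail).

## The synthetic-data generator

The generator's job is to make ground truth provable, not to imitate real
phage sequence.  Between planted elements the background uses only C and T
— no codon over {C,T} is a start or stop on either strand — broken at most
every ~46 nt by a 21-nt cassette (`TTTTAACCTAAAACACTAACT`) that carries a
stop codon in all six frames and, verified exhaustively over every C/T
flank context, leaves no start codon dangling past its last in-frame stop
on either strand.  Consequently no unintended ORF of ≥ 30 codons can exist
outside planted elements.  Planted coding regions use G-free codons (the
only G's in a fixture genome are planted ATG starts, S-D motifs, and the
lipobox Cys codon TGT, always preceded by C so no ATG/GTG/TTG can form),
which also makes accidental Cys — and hence accidental lipoboxes —
impossible in filler.  Embedded and overlapping spanin constructs are
composed by constrained search (frame-shifted o-ORF inside or past the end
of the i-ORF with no i-frame stops across the insert), and every assembled
genome is re-verified: the six-frame caller, the S-D annotator and (when
relevant) the spanin finder must recover exactly the declared truth, with
filler choices resampled deterministically from the spec seed until they
do.  Fixtures therefore do **not** exercise: realistic base composition or
codon usage, near-miss S-D motifs, weak/borderline TM segments, or
overlapping real genes — passing tests demonstrate correctness of the
implemented rules, not detection power on real genomes.  The split-gene and
terminator fixtures are constructed record sets (random-sequence genome,
hand-chosen HSP intervals; the 3×3×3 boundary battery), and the XMFA
example is a hand-counted 6-identical-columns-of-10 alignment (60% Dice).

Problem sizes used by the test suite and the acceptance script — 200 random
genomes of 1–5 kb for oracle agreement, 500 planted windows, 50 planted
spanin genomes plus 2 negative controls, 6 interrupted-gene scenario
checks, the 101-point Dice grid — were chosen as the smallest sets that
exercise every rule and architecture combination while keeping runs
comfortable on one CPU.

## Known limitations

* The TM stand-in is a hydropathy heuristic, not an HMM; on real proteins
  it over-calls long hydrophobic stretches and misses marginal helices.
  External predictions are accepted for serious use.
* Origin-wrapping S-D windows on circular genomes are extracted, but an S-D
  motif itself spanning the origin cannot be represented as a single
  interval feature.
* The interrupted-gene detector reports one candidate per subject and does
  not merge evidence across homologous subjects.
* GenBank I/O, five-column submission tables and invocation of external
  predictors are out of scope by design; the toolkit consumes their text
  outputs instead.
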