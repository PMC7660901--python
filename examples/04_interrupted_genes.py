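"""Interrupted-gene detection from alignment evidence.

When two separate genes from a genome align to complementary halves of the
same database protein, the gene was probably split by an intron, a
programmed frameshift, or a sequencing artifact.  This script builds such a
record set (plus noise) and runs the detector, including the genome-end
(origin-spanning) case.
"""

from pak.fixtures import SplitGeneSpec, make_split_gene_records
from pak.interrupted_genes import (
    InterruptedParams,
    candidates_to_tsv,
    detect_interrupted,
    filter_low_identity_hsps,
)

fx = make_split_gene_records(SplitGeneSpec(seed=404))
records = filter_low_identity_hsps(fx.records)  # drops identities/length < 0.3
cands = detect_interrupted(records, fx.features, fx.genome, InterruptedParams())
print(candidates_to_tsv(cands))
# One candidate: q1+q2 hitting sub_split at residues 1-120 and 131-250,
# 2000 nt apart on the genome (within the 10 kb default window).  The
# opposite-strand and single-fragment decoys are rejected.

fx2 = make_split_gene_records(SplitGeneSpec(seed=404, across_origin=True))
rec2 = filter_low_identity_hsps(fx2.records)
circ = detect_interrupted(rec2, fx2.features, fx2.genome,
                          InterruptedParams(circular=True))
for c in circ:
    if c.subject_id == fx2.split_subject:
        print(f"origin-spanning split: gap {c.genomic_gaps_nt[0]} nt across the "
              f"genome ends (spans_origin={c.spans_origin})")
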