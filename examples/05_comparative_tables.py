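"""Dice-coefficient comparative genomics.

The Dice coefficient 2m/(len_a+len_b) scores whole-sequence relatedness:
identical matches m over both full lengths, so short high-identity hits
score low.  This script shows the arithmetic, record filtering, ranking
tables, and the XMFA -> percent-identity conversion.
"""

from pak.comparative import (
    DiceInputs,
    dice_coefficient,
    rank_nucleotide_hits,
    rows_to_tsv,
    xmfa_identity_table,
)
from pak.fixtures import make_xmfa_document
from pak.io_formats import read_xmfa
from pak.model import AlignmentRecord, Hsp

print("Dice(300 matches, 1000+1000 nt) =", dice_coefficient(DiceInputs(300, 1000, 1000)))
# 0.3: the printed closed form, 2*300/2000.


def rec(sid, m):
    hsp = Hsp(1, m, 1, m, m, m, 1e-20, 100.0)
    return AlignmentRecord("query_phage", sid, [hsp], query_len=40_000, subject_len=40_000)


rows = rank_nucleotide_hits([rec("phage_twin", 40_000), rec("phage_cousin", 12_000)])
print()
print(rows_to_tsv(rows, "dice_percent"))
# phage_twin ranks first at 100%; phage_cousin at 2*12000/80000 = 30%.

doc, lengths = make_xmfa_document()
table = xmfa_identity_table(read_xmfa(doc), lengths)
print(table)
# 6 identical columns over two 10-nt sequences: 2*6/20 = 60% off-diagonal.
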