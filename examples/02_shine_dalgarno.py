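"""Shine-Dalgarno detection upstream of a CDS.

A gene model plus its genome go in; the upstream window (3-24 nt before the
start codon) is searched for the E. coli consensus AGGAGGT or any of its
length >= 4 sub-motifs, and the best (longest, then closest) match is added
to the gene model as a Shine_Dalgarno_sequence child feature.
"""

from pak.fixtures import FixtureSpec, SdGeneElement, make_genome
from pak.io_formats import write_gff3
from pak.model import FeatureSet
from pak.shinefind import SdParams, annotate_shine_dalgarno, default_sd_candidates

print("candidate motifs (longest first):", " ".join(default_sd_candidates()))

genome, truth = make_genome(
    FixtureSpec(seed=202, genome_len=1500, elements=(SdGeneElement(sd_offset=7),))
)
# strip the truth's own SD children so the annotator has work to do
bare = FeatureSet(
    f.copy() for f in truth.features if f.so_type != "Shine_Dalgarno_sequence"
)
annotated = annotate_shine_dalgarno(bare, genome, SdParams())
(sd,) = annotated.of_type("Shine_Dalgarno_sequence")
print(f"found {sd.attributes['sd_motif'][0]} at {sd.start}..{sd.end} "
      f"({sd.strand}), {sd.attributes['sd_offset'][0]} nt before the start codon")
print()
print(write_gff3(annotated))
# The offset counts from the last motif base to the first base of the start
# codon; the planted construct used offset 7, which is what comes back.
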