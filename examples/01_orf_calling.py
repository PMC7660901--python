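"""Naive six-frame ORF calling and phage start-codon filtering.

Builds a tiny genome with one planted gene, calls every ORF of >= 30
residues on all six frames (translation table 11), then narrows to ORFs
beginning with a common phage start codon (ATG/GTG/TTG).
"""

from pak.fixtures import FixtureSpec, SdGeneElement, make_genome
from pak.orf_models import OrfCallParams, call_orfs, filter_by_start_codon

genome, truth = make_genome(
    FixtureSpec(seed=101, genome_len=1500, elements=(SdGeneElement(),))
)
print(f"genome: {genome.id}, {len(genome)} nt")

called = call_orfs(genome, OrfCallParams(min_aa_len=30, translation_table=11))
print(f"naive ORFs (any table-11 start): {len(called.of_type('gene'))}")

phage = filter_by_start_codon(called, genome)
for gene in phage.of_type("gene"):
    first = genome.subseq(gene.start, gene.end, gene.strand)[:3]
    n_aa = len(gene) // 3 - 1
    print(f"  {gene.feature_id}: {gene.start}..{gene.end} ({gene.strand}), "
          f"start codon {first}, {n_aa} aa")

# The surviving ORF is the planted gene; its span includes the stop codon,
# and the residue count excludes it.
assert {(g.start, g.end, g.strand) for g in phage.of_type("gene")} == truth.gene_spans
print("matches the planted truth.")
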