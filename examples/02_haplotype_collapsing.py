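"""Collapse identical aligned sequences into haplotypes, per species.

Identical residue strings (gaps and Ns included) collapse to one
haplotype; the counts per species mirror how taxonomic remarks report
"n sequences in k haplotypes".
"""

from barcodiag import (
    AlignedSequence, Alignment, SpeciesMap,
    collapse_haplotypes, haplotype_counts,
)

alignment = Alignment([
    AlignedSequence("a1", "ACGTAC"),
    AlignedSequence("a2", "ACGTAC"),
    AlignedSequence("a3", "ACGTAT"),   # third spA sequence, second haplotype
    AlignedSequence("b1", "TTGTAC"),
    AlignedSequence("b2", "TTGTAC"),
])
species_map = SpeciesMap(assignment={
    "a1": "spA", "a2": "spA", "a3": "spA", "b1": "spB", "b2": "spB",
})

table = collapse_haplotypes(alignment, species_map, per_species=True)
for hap in table.entries:
    print(f"{hap.id}: representative {hap.representative}, "
          f"members {';'.join(hap.members)}")

for species, (n_seq, n_hap) in haplotype_counts(table).items():
    print(f"{species}: {n_seq} sequences in {n_hap} haplotype(s)")
# Expected: spA collapses 3 sequences into 2 haplotypes, spB 2 into 1.
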