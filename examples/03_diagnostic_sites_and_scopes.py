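"""Diagnostic (apomorphic) nucleotide positions and the effect of scope.

A position is diagnostic for a species when one base is fixed in all of
its sequences and no other sequence of the reference scope could carry
that base.  Shrinking the scope (e.g. comparing only within one clade)
can only ADD diagnostics -- shown here: spA's state at column 1 is shared
with spC in the full data set but unique once the comparison is
restricted to {spA, spB}.
"""

from barcodiag import (
    AlignedSequence, Alignment, Scope, SpeciesMap,
    find_diagnostic_sites, format_diagnosis,
)

alignment = Alignment([
    AlignedSequence("a1", "ATTG"),
    AlignedSequence("a2", "ATTG"),
    AlignedSequence("b1", "CTAG"),
    AlignedSequence("b2", "CTAG"),
    AlignedSequence("c1", "AGAG"),
])
species_map = SpeciesMap(assignment={
    "a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "c1": "spC",
})

full = Scope.full(species_map)
clade = Scope.from_species("cladeAB", ["spA", "spB"])

for scope in (full, clade):
    sites = find_diagnostic_sites(alignment, species_map, "spA", scope)
    found = ", ".join(f"{s.position} ({s.state})" for s in sites) or "none"
    print(f"spA diagnostics under scope '{scope.name}': {found}")

# Near-diagnostics: tolerate one outside sequence sharing the state and
# report it by id, so the result can be phrased "shared only with c1".
sites = find_diagnostic_sites(alignment, species_map, "spA", full, max_exceptions=1)
print(format_diagnosis("spA", {"full, <=1 exception": sites}))
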