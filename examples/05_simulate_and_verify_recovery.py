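"""Generate a synthetic data set and verify the pipeline recovers its truth.

The generator plants species-unique bases at reserved columns and adds
controlled between- and within-species substitution.  evaluate_recovery
scores the diagnostic finder against the planted sites (recall/precision)
and compares the observed mean intraspecific p-distance with the
generator's closed-form expectation.
"""

from barcodiag import (
    Scope, SimulationParams,
    diagnostics_all_species, distance_matrix, evaluate_recovery,
    intraspecific_values, simulate_dataset,
)

params = SimulationParams(n_species=6, seqs_per_species=8, n_cols=659,
                          n_diag_per_species=2, f_inter=0.10, f_intra=0.01,
                          seed=4)
alignment, species_map, truth = simulate_dataset(params)
print(f"simulated {len(alignment)} sequences x {alignment.n_cols} columns; "
      f"planted {sum(len(v) for v in truth.planted.values())} diagnostic sites")

matrix = distance_matrix(alignment)
diagnostics = diagnostics_all_species(alignment, species_map, Scope.full(species_map))
report = evaluate_recovery(truth, diagnostics, alignment, species_map,
                           intraspecific_values(matrix, species_map))

print(f"planted-site recall:    {report.recall:.2f}")
print(f"precision (verified):   {report.precision:.2f}  "
      f"({report.n_accidental_verified} accidental-but-sound sites excluded)")
print(f"mean intra p-distance:  observed {report.mean_intra_observed:.4f}, "
      f"expected {report.mean_intra_expected:.4f} "
      f"(within 3 SE: {report.intra_within_tolerance})")
# Recall/precision of 1.0 and an observed mean inside the 3-SE band mean
# every stage behaves as the construction guarantees.
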