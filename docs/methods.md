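# Methods

## Data model

All computation happens in one coordinate system: a validated multiple
sequence alignment (equal-length rows over uppercase IUPAC nucleotide
codes, `-` and `?`; `U` is normalised to `T`) plus a species map assigning
every sequence id to exactly one species, optionally with a species→group
column. Columns are addressed 1-based and inclusive at every public
surface — reports, CLI, JSON — because that is how diagnostic positions
are printed and cited in taxonomic work; the 0-based internal indexing
never leaks.

`?` is treated identically to `N` throughout: both mean "no usable
observation". Nothing downstream distinguishes them.

A *scope* is a named set of species defining the comparison universe for
diagnostics. Scopes are first-class because the central subtlety of
character-based diagnosis is a scope effect: a species may have no
diagnostic position against the full data set yet several against its own
clade. The default `diagnose`/`report` runs evaluate the global scope and
every group-derived scope.

## Uncorrected p-distance

Pairwise deletion restricted to unambiguous bases: a column enters the
comparison iff both rows carry one of A/C/G/T. Ambiguity codes are
excluded rather than fractionally counted; this is the dominant
convention for "uncorrected genetic distance" in barcoding practice and
keeps both the difference count and the compared-site count exact
integers, recomputable by a naive per-column loop (and cross-checked
against exactly such a loop in the tests). A pair with zero comparable
sites yields an explicit undefined result — never a silent 0 — and such
pairs are excluded from minima/maxima with a dataset-level warning.

Percent rendering multiplies by 100 and rounds half away from zero to one
decimal, matching the precision at which such values are printed
(0.2%, 1.9%, 8.8%). Raw fractions are retained in JSON output.

Species summaries: the intraspecific range is the min/max over all
within-species pairs (NA when n < 2); the minimum interspecific distance
is the minimum over all heterospecific sequence pairs, with one
witnessing id pair retained; the nearest neighbour is the species
attaining it (ties return all tied species sorted by label); the barcode
gap is min-inter minus max-intra where both are defined.

## Haplotype collapsing

Default equality is exact column-wise identity of the normalised residue
strings, with `N` and gaps counting as ordinary characters: the criterion
is deterministic, order-independent and idempotent. A missing-tolerant
mode (two sequences equal when they agree at every column where both are
unambiguous) is available behind a flag; that relation is non-transitive,
so clusters are formed greedily in input order against each cluster's
representative, and the mode is off by default. Haplotype ids are
numbered by first-occurring member, so output is deterministic.

## Diagnostic (apomorphic) positions

Fixation is strict by default: any missing datum or ambiguity code inside
the focal species blocks it, reading "fixed in all sequences" literally.
A permissive variant (`min_observed = m`: ignore missing cells when at
least m members are observed) is flag-gated and off by default.

Outside the focal species, compatibility is conservative: an ambiguity
code whose expansion contains the candidate base counts as a violation
(an `R` could be the `A` we require), while gaps/`N`/`?` never match a
base and are tallied as `unscored_outside` so reports can state how much
of the scope was actually observed at the column. `max_exceptions = k`
tolerates up to k compatible outsiders, each reported by id, so
near-diagnostics can be phrased "shared only with one specimen of X";
this is a single general mechanism, not a special case.

Two monotonicity laws are property-tested on random data: results under a
scope are a subset of results under any sub-scope still containing the
species, and results at k are a subset of results at k+1. On alignments
up to 30×300 the finder is checked for exact agreement with an
independent exhaustive double-loop scan.

## Classification

Queries must already be in the reference coordinate system; aligning raw
fragments is deliberately out of scope because any aligner choice would
silently shift the diagnostic positions. Two classifiers are provided:

* **diagnostics**: per species, each diagnostic site scores match /
  mismatch / unscored (missing or ambiguous query symbol — unscored, not
  a mismatch). The call is the unique species with ≥ 1 scored site and no
  mismatch; several such species give "ambiguous", none "unidentifiable".
  For queries derived from reference sequences, masking columns can only
  degrade a call toward ambiguous/unidentifiable, never flip it between
  species (a wrong species can never gain a match by masking) — tested as
  a property.
* **distance**: nearest species by minimum p-distance to any reference
  sequence, accepted iff that minimum is ≤ the threshold. The default
  threshold is 0.03 (3%): in well-separated barcoding data sets the
  largest intraspecific distances (~3.4%) and smallest interspecific
  minima (~3.0%) straddle this value, so it is exposed as a parameter and
  always echoed in the report rather than trusted silently.

## Synthetic data generator

A star phylogeny: one root drawn uniformly over {A,C,G,T}, one
independent branch per species, then independent individuals. Reserved
columns (n_species × n_diag_per_species, disjoint) carry the planted
diagnostics: the focal species gets base x, all other species one common
base y ≠ x, so each planted column is diagnostic for exactly one species.
On the remaining free columns each species branch substitutes per column
with probability `f_inter`, and each individual with probability
`f_intra`; substitutions pick uniformly among the three alternative bases
(a Jukes–Cantor-like process, the simplest model that makes expectations
closed-form). Optional masking sets cells to `N`/`-` at given rates,
never at a planted column of the sequence's own species. Everything is
deterministic under the seed (byte-identical FASTA and truth).

Defaults emulate the divergence structure of a COI barcoding study of a
species complex: 8 species × 10 sequences × 659 columns, 2 planted sites
per species, `f_inter = 0.10` and `f_intra = 0.01`, giving expected
interspecific p-distances near 18% and intraspecific distances near 2% —
a clear barcode gap, with intraspecific variation inside the few-percent
range typical of such data.

What the generator does *not* emulate: tree-shaped between-species
covariance (a star phylogeny has none), rate heterogeneity across sites,
codon structure, indel evolution, and sequencing-error asymmetries.
Passing tests therefore demonstrate correctness of the computations under
a clean, known model, not robustness to every real-data pathology —
real alignments with heavy missing data or introgression still require
judgement about scope and thresholds.

Closed-form expectations: two conspecific individuals differ at a free
column with probability `2f(1−f) + (2/3)f²` (`f = f_intra`); the expected
mean intraspecific p-distance scales this by the free-column fraction.
The interspecific expectation composes four independent substitution
layers (two branches, two individuals) through the two-lineage transition
`p' = p + r(1−p) − rp/3` and adds the per-pair planted columns.
`evaluate_recovery` compares the observed mean against the closed form
using a three-standard-error band, with the SE taken as the standard
error of the mean of the observed pairwise values (within-species pairs
share sequences, so this SE is approximate; at the tested sizes the band
is far wider than the discrepancy).

Recovery scoring: recall is the fraction of planted (species, position,
state) triples found. Free columns can by chance produce genuine
species-unique fixed states — correct findings that were not planted —
so precision excludes from its denominator any non-planted site that an
independent re-check of the column confirms as sound ("verified
accidental"); what remains measures unsound output and is expected to be
exactly 1.0.

## Problem sizes

The test suite and the acceptance script run on simulated data chosen to
exercise every code path at comfortable scale: oracle equivalence on 200
random alignments up to 30×300; recovery on 6–10 species at 400–659
columns; calibration on 10 species × 5 sequences × 600 columns. The full
suite completes in well under a minute on one CPU.

## Known limitations

* Distances are computed on the alignment as given; studies that trim
  per-pair fragments can shift printed values by ≈0.1 percentage points.
* The missing-tolerant haplotype mode depends on input order (documented
  above); the default exact mode does not.
* Compound diagnostics over position pairs, distance-model corrections
  (K2P), clustering-based delimitation and tree building are out of
  scope.
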