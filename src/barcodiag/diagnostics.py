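"""Discovery of diagnostic (apomorphic) nucleotide positions.

A column is diagnostic for a species, relative to a reference scope, when
one base is *fixed* in every sequence of the species and (almost) no other
sequence in the scope is compatible with that base.  This is the classic
character-based diagnosis used in integrative taxonomy: the printed result
is a list of (alignment position, base) pairs per species.

Policy details, all chosen conservatively:

* Fixation is strict by default — any missing datum (N, ``?``, gap) or
  ambiguity code inside the focal species blocks fixation, because "present
  in all sequences" is read literally.  A permissive mode can ignore
  missing cells when at least ``min_observed`` members are observed.
* Outside the focal species, a sequence is *compatible* with the candidate
  base when it carries exactly that base or an ambiguity code whose
  expansion contains it (an R could be the A we require, so it counts
  against uniqueness).  Gaps, N and ``?`` never match a base; they are
  tallied separately as ``unscored_outside``.
* ``max_exceptions`` tolerates up to that many compatible outsiders, each
  reported by id, so a near-diagnostic site can be phrased as "shared only
  with one specimen of species X".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AMBIGUITY, BASES, Alignment, Scope, SpeciesMap

#: symbol -> set of unambiguous bases it is compatible with (empty for
#: gap/N/?: "no usable observation" never matches a base).
_COMPAT: dict[str, frozenset[str]] = {
    **{b: frozenset(b) for b in BASES},
    **AMBIGUITY,
    "N": frozenset(),
    "?": frozenset(),
    "-": frozenset(),
}


@dataclass(frozen=True)
class DiagnosticSite:
    """A diagnostic position: 1-based column, fixed base, focal species,
    the scope the uniqueness was evaluated in, any tolerated outside
    sequences compatible with the base, and how many outside sequences
    were unscored (gap/missing) at the column."""

    position: int
    state: str
    species: str
    scope: str
    exceptions: tuple[str, ...] = field(default_factory=tuple)
    unscored_outside: int = 0

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "scope": self.scope,
            "position": self.position,
            "state": self.state,
            "n_exceptions": len(self.exceptions),
            "exceptions": list(self.exceptions),
            "unscored_outside": self.unscored_outside,
        }


def fixed_state(
    alignment: Alignment,
    species_map: SpeciesMap,
    species: str,
    position: int,
    *,
    min_observed: int | None = None,
) -> str | None:
    """The base fixed in every member of a species at a 1-based column.

    Returns None unless all members carry the same unambiguous base.  With
    ``min_observed`` set, members with missing data (N/?/gap) are ignored
    provided at least that many members are observed; ambiguity codes still
    block fixation.
    """
    column = alignment.column(position)
    rows = [alignment.row_index(i) for i in species_map.members(species)]
    states = set(column[rows])
    if min_observed is not None:
        observed = [s for s in column[rows] if s not in "N?-"]
        if len(observed) < min_observed:
            return None
        states = set(observed)
    if len(states) == 1:
        state = states.pop()
        if state in BASES:
            return state
    return None


def find_diagnostic_sites(
    alignment: Alignment,
    species_map: SpeciesMap,
    species: str,
    scope: Scope,
    *,
    max_exceptions: int = 0,
    min_observed: int | None = None,
    warn_vacuous: bool = True,
) -> list[DiagnosticSite]:
    """All diagnostic sites of one species against a reference scope.

    A column qualifies when the species is fixed for a base there and at
    most ``max_exceptions`` scope sequences outside the species are
    compatible with that base.  Results are sorted by position and are
    independent of input order.  A scope containing only the focal species
    is legal — uniqueness is then vacuous and every fixed column is
    returned (with a warning unless suppressed).
    """
    scope.validate(species_map)
    if species not in scope.species_set:
        raise ValueError(f"species '{species}' is not in scope '{scope.name}'")
    if max_exceptions < 0:
        raise ValueError("max_exceptions must be >= 0")

    member_rows = np.array(
        [alignment.row_index(i) for i in species_map.members(species)]
    )
    outside_ids = [
        i for i in scope.sequence_ids(species_map)
        if species_map.species_of(i) != species and i in alignment
    ]
    outside_rows = np.array([alignment.row_index(i) for i in outside_ids], dtype=int)
    if not outside_ids and warn_vacuous:
        import warnings

        warnings.warn(
            f"scope '{scope.name}' contains no sequence outside '{species}'; "
            "uniqueness is vacuous and every fixed column is reported",
            stacklevel=2,
        )

    matrix = alignment.matrix
    sites: list[DiagnosticSite] = []
    for col in range(alignment.n_cols):
        state = _fixed_in_column(matrix[member_rows, col], min_observed)
        if state is None:
            continue
        exceptions: list[str] = []
        unscored = 0
        for k, row in enumerate(outside_rows):
            sym = matrix[row, col]
            compat = _COMPAT.get(sym, frozenset())
            if state in compat:
                exceptions.append(outside_ids[k])
                if len(exceptions) > max_exceptions:
                    break
            elif not compat:
                unscored += 1
        if len(exceptions) <= max_exceptions:
            sites.append(
                DiagnosticSite(
                    position=col + 1,
                    state=state,
                    species=species,
                    scope=scope.name,
                    exceptions=tuple(exceptions),
                    unscored_outside=unscored,
                )
            )
    return sites


def _fixed_in_column(symbols: np.ndarray, min_observed: int | None) -> str | None:
    if min_observed is not None:
        observed = symbols[~np.isin(symbols, ("N", "?", "-"))]
        if observed.size < min_observed:
            return None
        symbols = observed
    states = set(symbols.tolist())
    if len(states) == 1:
        state = states.pop()
        if state in BASES:
            return state
    return None


def diagnostics_all_species(
    alignment: Alignment,
    species_map: SpeciesMap,
    scope: Scope,
    *,
    max_exceptions: int = 0,
    min_observed: int | None = None,
) -> dict[str, list[DiagnosticSite]]:
    """Diagnostic sites for every species in a scope.

    Species without any diagnostic site map to an empty list — they are
    reported explicitly, never omitted.
    """
    scope.validate(species_map)
    return {
        species: find_diagnostic_sites(
            alignment,
            species_map,
            species,
            scope,
            max_exceptions=max_exceptions,
            min_observed=min_observed,
            warn_vacuous=False,
        )
        for species in sorted(scope.species_set)
    }


def format_diagnosis(
    species: str, sites_by_scope: dict[str, list[DiagnosticSite]]
) -> str:
    """A human-readable molecular-diagnosis block for one species.

    Mirrors how taxonomic descriptions phrase their diagnostic characters:
    "positions 300 (G) and 624 (G)", with tolerated exceptions called out.
    """
    lines = [f"Nucleotide diagnostic features — {species}"]
    for scope_name, sites in sites_by_scope.items():
        if not sites:
            lines.append(
                f"  [{scope_name}] no unique diagnostic nucleotide positions."
            )
            continue
        parts = []
        for s in sites:
            txt = f"{s.position} ({s.state})"
            if s.exceptions:
                txt += f"; shared only with {', '.join(s.exceptions)}"
            parts.append(txt)
        lines.append(f"  [{scope_name}] unique nucleotides at positions: " + ", ".join(parts))
    return "\n".join(lines)
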