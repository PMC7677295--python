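"""Assign query sequences to species by diagnostic sites or distance.

Queries must already live in the reference coordinate system (same column
count as the reference alignment): diagnostic positions are
alignment-relative, so realigning a query would silently shift them.
Aligning raw fragments is therefore out of scope — profile-align the query
to the reference first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .alignment import AMBIGUITY, BASES, AlignedSequence, Alignment, SpeciesMap
from .diagnostics import DiagnosticSite
from .distances import p_distance

#: Call labels used when no single species qualifies.
AMBIGUOUS = "ambiguous"
UNIDENTIFIABLE = "unidentifiable"


@dataclass
class SpeciesScore:
    """Per-species tally of a query against that species' diagnostic sites."""

    species: str
    matched: int
    mismatched: int
    unscored: int

    @property
    def total(self) -> int:
        return self.matched + self.mismatched

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "matched": self.matched,
            "mismatched": self.mismatched,
            "unscored": self.unscored,
        }


@dataclass
class ClassificationResult:
    query_id: str
    method: str
    call: str
    rationale: str
    scores: list[SpeciesScore] = field(default_factory=list)
    nearest_species: list[str] = field(default_factory=list)
    min_distance: float | None = None
    threshold: float | None = None
    tied_species: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "query": self.query_id,
            "method": self.method,
            "call": self.call,
            "nearest_species": self.nearest_species,
            "min_distance": self.min_distance,
            "threshold": self.threshold,
            "rationale": self.rationale,
        }


def _query_state_matches(symbol: str, state: str) -> bool | None:
    """True/False when the query symbol scores against a diagnostic base;
    None when the symbol is unscorable (gap/N/?/ambiguity)."""
    if symbol in BASES:
        return symbol == state
    return None  # ambiguity codes and missing data are unscored, not mismatches


def classify_by_diagnostics(
    query: AlignedSequence,
    diagnostics: Mapping[str, list[DiagnosticSite]],
    *,
    n_cols: int | None = None,
) -> ClassificationResult:
    """Call the unique species whose diagnostic sites the query matches.

    For each species every diagnostic site is scored: match (query carries
    exactly the diagnostic base), mismatch (a different unambiguous base),
    or unscored (missing or ambiguous query symbol).  A species qualifies
    when it has at least one scored site and no mismatch; exactly one
    qualifying species is called, several give "ambiguous", none give
    "unidentifiable".
    """
    if n_cols is not None and len(query) != n_cols:
        raise ValueError(
            f"query '{query.id}' has length {len(query)} but the reference "
            f"alignment has {n_cols} columns; profile-align the query first"
        )
    scores: list[SpeciesScore] = []
    for species in sorted(diagnostics):
        matched = mismatched = unscored = 0
        for site in diagnostics[species]:
            if site.position > len(query):
                raise ValueError(
                    f"diagnostic position {site.position} beyond query length {len(query)}"
                )
            verdict = _query_state_matches(query.residues[site.position - 1], site.state)
            if verdict is None:
                unscored += 1
            elif verdict:
                matched += 1
            else:
                mismatched += 1
        scores.append(SpeciesScore(species, matched, mismatched, unscored))

    qualifying = [s for s in scores if s.total > 0 and s.mismatched == 0 and s.matched > 0]
    if len(qualifying) == 1:
        win = qualifying[0]
        call = win.species
        rationale = (
            f"matched all {win.matched} scored diagnostic site(s) of {win.species}"
        )
    elif len(qualifying) > 1:
        call = AMBIGUOUS
        rationale = "multiple species fully matched: " + ", ".join(
            s.species for s in qualifying
        )
    else:
        call = UNIDENTIFIABLE
        scored_any = any(s.total > 0 for s in scores)
        rationale = (
            "no species fully matched its scored diagnostic sites"
            if scored_any
            else "no diagnostic site could be scored (query missing/ambiguous there)"
        )
    return ClassificationResult(
        query_id=query.id,
        method="diagnostics",
        call=call,
        rationale=rationale,
        scores=scores,
        tied_species=[s.species for s in qualifying] if len(qualifying) > 1 else [],
    )


def classify_by_distance(
    query: AlignedSequence,
    alignment: Alignment,
    species_map: SpeciesMap,
    *,
    threshold: float = 0.03,
) -> ClassificationResult:
    """Nearest-neighbour call: the species of the closest reference
    sequence, accepted only when that minimum p-distance is at or below
    the threshold (default 3%, the conventional barcoding cut-off;
    always configurable and always reported)."""
    if len(query) != alignment.n_cols:
        raise ValueError(
            f"query '{query.id}' has length {len(query)} but the reference "
            f"alignment has {alignment.n_cols} columns; profile-align the query first"
        )
    best: dict[str, float] = {}
    for ref in alignment:
        d = p_distance(query, ref)
        if not d.defined:
            continue
        sp = species_map.species_of(ref.id)
        if sp not in best or d.value < best[sp]:
            best[sp] = d.value
    if not best:
        return ClassificationResult(
            query_id=query.id,
            method="distance",
            call=UNIDENTIFIABLE,
            rationale="no comparable sites with any reference sequence",
            threshold=threshold,
        )
    min_d = min(best.values())
    nearest = sorted(sp for sp, d in best.items() if d == min_d)
    if min_d > threshold:
        call = UNIDENTIFIABLE
        rationale = (
            f"minimum distance {min_d:.4f} to {nearest[0]} exceeds threshold {threshold}"
        )
    elif len(nearest) > 1:
        call = AMBIGUOUS
        rationale = "query equidistant from: " + ", ".join(nearest)
    else:
        call = nearest[0]
        rationale = f"nearest species {nearest[0]} at distance {min_d:.4f} <= {threshold}"
    return ClassificationResult(
        query_id=query.id,
        method="distance",
        call=call,
        rationale=rationale,
        nearest_species=nearest,
        min_distance=min_d,
        threshold=threshold,
        tied_species=nearest if len(nearest) > 1 else [],
    )
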