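"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive per-column loops over plain
strings — no numpy, no shared code with the package — so that agreement
with them is a genuine cross-check of the vectorised implementations.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from barcodiag.alignment import AlignedSequence, Alignment, SpeciesMap

BASES = "ACGT"
AMBIG_EXPANSION = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


def naive_p_distance(a: str, b: str) -> tuple[int, int]:
    """(differences, compared_sites) by direct column-by-column counting."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            comp += 1
            if x != y:
                diff += 1
    return diff, comp


def naive_diagnostic_sites(
    residues: dict[str, str],
    species_of: dict[str, str],
    species: str,
    scope_species: set[str],
    max_exceptions: int = 0,
) -> list[tuple[int, str]]:
    """Exhaustive double-loop scan for diagnostic (position, state) pairs."""
    members = [i for i, sp in species_of.items() if sp == species]
    outside = [
        i for i, sp in species_of.items()
        if sp != species and sp in scope_species
    ]
    n_cols = len(next(iter(residues.values())))
    sites = []
    for col in range(n_cols):
        states = {residues[i][col] for i in members}
        if len(states) != 1:
            continue
        state = states.pop()
        if state not in BASES:
            continue
        n_compatible = 0
        for i in outside:
            sym = residues[i][col]
            if sym == state or state in AMBIG_EXPANSION.get(sym, ""):
                n_compatible += 1
        if n_compatible <= max_exceptions:
            sites.append((col + 1, state))
    return sites


def random_alignment(
    rng: random.Random,
    n_seqs: int,
    n_cols: int,
    *,
    alphabet: str = BASES + "RYN-?",
    n_species: int | None = None,
) -> tuple[Alignment, SpeciesMap]:
    """A random alignment with a random species partition (every species
    non-empty)."""
    seqs = [
        AlignedSequence(
            id=f"s{i}", residues="".join(rng.choice(alphabet) for _ in range(n_cols))
        )
        for i in range(n_seqs)
    ]
    if n_species is None:
        n_species = rng.randint(1, max(1, n_seqs // 2))
    n_species = min(n_species, n_seqs)
    labels = [f"sp{j}" for j in range(n_species)]
    assignment = {}
    for i, seq in enumerate(seqs):
        assignment[seq.id] = labels[i] if i < n_species else rng.choice(labels)
    return Alignment(seqs), SpeciesMap(assignment=assignment)


@pytest.fixture
def toy_alignment() -> Alignment:
    """Three species; spA fixed 'A' at column 1 (unique), spB fixed 'G' at
    column 2 (unique), spC polymorphic everywhere it could matter."""
    return Alignment([
        AlignedSequence("a1", "ACGTAC"),
        AlignedSequence("a2", "ACGTAT"),
        AlignedSequence("b1", "CGGTAC"),
        AlignedSequence("b2", "CGGTAC"),
        AlignedSequence("c1", "CCGTAC"),
        AlignedSequence("c2", "TCTTAC"),
    ])


@pytest.fixture
def toy_species_map() -> SpeciesMap:
    return SpeciesMap(assignment={
        "a1": "spA", "a2": "spA",
        "b1": "spB", "b2": "spB",
        "c1": "spC", "c2": "spC",
    })
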