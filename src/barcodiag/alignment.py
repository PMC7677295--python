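"""Core data model: aligned sequences, alignments, species maps and scopes.

The package works on a fixed coordinate system: a multiple sequence
alignment whose columns are addressed 1-based and inclusive, the way
diagnostic positions are conventionally printed in taxonomic
descriptions.  Internally columns are 0-based numpy indices; the 1-based
convention is applied at every public boundary and never leaks inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

#: Unambiguous nucleotide states.
BASES = frozenset("ACGT")

#: Expansion of IUPAC ambiguity codes to the unambiguous bases they admit.
#: ``N`` is deliberately absent: together with ``?`` and ``-`` it is treated
#: as "no usable observation" everywhere downstream.
AMBIGUITY = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
}

#: Symbols carrying no usable observation at a column.
MISSING = frozenset("N?-")

#: Every character a validated alignment may contain.
ALPHABET = BASES | set(AMBIGUITY) | MISSING


class AlignmentError(ValueError):
    """Raised when an input violates an alignment invariant."""


def normalise_residues(raw: str) -> str:
    """Uppercase a residue string and map RNA ``U`` onto ``T``.

    ``?`` is kept as-is here; downstream logic treats it exactly like ``N``.
    """
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: an identifier plus its residue string."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length aligned sequences.

    Parameters
    ----------
    sequences
        Aligned rows; ids must be unique and residues already normalised
        (uppercase, ``U`` mapped to ``T``).  Use :func:`barcodiag.io.read_alignment`
        to build a validated instance from FASTA.
    """

    def __init__(self, sequences: Iterable[AlignedSequence]):
        self.sequences: list[AlignedSequence] = list(sequences)
        if not self.sequences:
            raise AlignmentError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offender = max(self.sequences, key=lambda s: abs(len(s) - len(self.sequences[0])))
            raise AlignmentError(
                f"ragged alignment: sequence '{offender.id}' has length "
                f"{len(offender)}, expected {len(self.sequences[0])}"
            )
        self.n_cols: int = lengths.pop()
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise AlignmentError(f"duplicate sequence id '{dup}'")
        for seq in self.sequences:
            bad = set(seq.residues) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(seq.residues) if c in bad)
                raise AlignmentError(
                    f"illegal character '{seq.residues[col]}' in sequence "
                    f"'{seq.id}' at column {col + 1}"
                )
        self._index = {s.id: k for k, s in enumerate(self.sequences)}
        self._matrix: np.ndarray | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        return self.sequences[self._index[seq_id]]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def row_index(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id '{seq_id}'") from None

    @property
    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, n_cols), dtype '<U1'.

        Built lazily and cached; treat as read-only.
        """
        if self._matrix is None:
            self._matrix = np.array(
                [list(s.residues) for s in self.sequences], dtype="<U1"
            )
        return self._matrix

    def column(self, position: int) -> np.ndarray:
        """Residues of all sequences at a 1-based column position."""
        if not 1 <= position <= self.n_cols:
            raise AlignmentError(
                f"position {position} outside alignment columns 1..{self.n_cols}"
            )
        return self.matrix[:, position - 1]


@dataclass
class SpeciesMap:
    """Assignment of every sequence id to exactly one species label.

    An optional grouping maps species labels onto higher-level group labels
    (clades such as "GroupA"); when present it partitions the species and is
    the natural source of restricted reference scopes.
    """

    assignment: dict[str, str]
    grouping: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise AlignmentError("species map is empty")
        if self.grouping is not None:
            unknown = set(self.grouping) - set(self.assignment.values())
            if unknown:
                raise AlignmentError(
                    f"grouping names unknown species: {sorted(unknown)}"
                )

    @property
    def species(self) -> list[str]:
        """Species labels in first-occurrence order."""
        out: list[str] = []
        seen: set[str] = set()
        for sp in self.assignment.values():
            if sp not in seen:
                seen.add(sp)
                out.append(sp)
        return out

    def members(self, species: str) -> list[str]:
        ids = [i for i, sp in self.assignment.items() if sp == species]
        if not ids:
            raise KeyError(f"unknown species '{species}'")
        return ids

    def species_of(self, seq_id: str) -> str:
        try:
            return self.assignment[seq_id]
        except KeyError:
            raise KeyError(f"sequence '{seq_id}' absent from species map") from None

    def groups(self) -> dict[str, list[str]]:
        """Group label -> species labels; empty dict when no grouping."""
        if self.grouping is None:
            return {}
        out: dict[str, list[str]] = {}
        for sp, grp in self.grouping.items():
            out.setdefault(grp, []).append(sp)
        return out


@dataclass(frozen=True)
class Scope:
    """A named reference universe: the species whose sequences a diagnostic
    state must be unique against.

    The same species can carry different diagnostics under different scopes
    (none against the full data set, several against a single clade), so
    scopes are explicit, named objects rather than an implicit "everything".
    """

    name: str
    species_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.species_set:
            raise AlignmentError(f"scope '{self.name}' has an empty species set")

    @classmethod
    def from_species(cls, name: str, species: Iterable[str]) -> "Scope":
        return cls(name=name, species_set=frozenset(species))

    @classmethod
    def full(cls, species_map: SpeciesMap, name: str = "all") -> "Scope":
        return cls(name=name, species_set=frozenset(species_map.species))

    def validate(self, species_map: SpeciesMap) -> None:
        unknown = self.species_set - set(species_map.species)
        if unknown:
            raise AlignmentError(
                f"scope '{self.name}' names species absent from the species map: "
                f"{sorted(unknown)}"
            )

    def sequence_ids(self, species_map: SpeciesMap) -> list[str]:
        """All sequence ids whose species belongs to the scope, in map order."""
        return [i for i, sp in species_map.assignment.items() if sp in self.species_set]


def scopes_from_grouping(species_map: SpeciesMap) -> list[Scope]:
    """One scope per group label defined in the species map's grouping."""
    return [
        Scope.from_species(grp, species)
        for grp, species in species_map.groups().items()
    ]
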