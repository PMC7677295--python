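"""Uncorrected p-distances and the species-level summaries built on them.

The distance of record is the uncorrected (p-) distance under pairwise
deletion: for a pair of aligned sequences, a column is *compared* iff both
rows carry an unambiguous base (A, C, G or T); the distance is the number
of compared columns at which the bases differ, divided by the number of
compared columns.  Ambiguity codes, N, ``?`` and gaps are excluded from the
comparison entirely, which keeps both counts integer-exact and
reproducible.  No substitution-model correction is applied.

Printed percentages follow barcoding convention: multiply by 100 and round
half away from zero to one decimal place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from .alignment import AlignedSequence, Alignment, Scope, SpeciesMap

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def percent(fraction: float | None, decimals: int = 1) -> float | None:
    """Render a fraction as a percentage rounded half away from zero.

    ``percent(0.01949) == 1.9``; ``percent(0.115) == 11.5``.  Returns None
    for an undefined (None/NaN) input.
    """
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return None
    q = Decimal(1).scaleb(-decimals)
    scaled = Decimal(repr(fraction)).scaleb(2)  # exact x100, no float error
    return float(scaled.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PDistanceValue:
    """An uncorrected pairwise distance with its exact integer counts.

    ``value`` is ``differences / compared_sites`` and is None when no
    column is comparable — an explicit "no comparable sites" outcome, never
    a silent zero.
    """

    differences: int
    compared_sites: int

    @property
    def value(self) -> float | None:
        if self.compared_sites == 0:
            return None
        return self.differences / self.compared_sites

    @property
    def defined(self) -> bool:
        return self.compared_sites > 0


def encode(residues: str) -> np.ndarray:
    """Map a residue string to int8 codes: A,C,G,T -> 0..3, anything else -> -1."""
    out = np.full(len(residues), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[np.frombuffer(residues.encode(), dtype="S1") == base.encode()] = code
    return out


def p_distance(a: AlignedSequence, b: AlignedSequence) -> PDistanceValue:
    """Uncorrected p-distance between two equal-length aligned sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences '{a.id}' ({len(a)}) and '{b.id}' ({len(b)}) differ in length"
        )
    ca, cb = encode(a.residues), encode(b.residues)
    both = (ca >= 0) & (cb >= 0)
    compared = int(both.sum())
    differences = int(((ca != cb) & both).sum())
    return PDistanceValue(differences=differences, compared_sites=compared)


class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances over an alignment.

    Holds the exact integer counts; ``values`` exposes the fractional
    distances with NaN marking pairs that share no comparable site.
    """

    def __init__(self, ids: list[str], differences: np.ndarray, compared: np.ndarray):
        self.ids = ids
        self.differences = differences
        self.compared = compared
        self._index = {i: k for k, i in enumerate(ids)}

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(
                self.compared > 0, self.differences / np.maximum(self.compared, 1), np.nan
            )
        np.fill_diagonal(vals, 0.0)
        return vals

    def pair(self, id_a: str, id_b: str) -> PDistanceValue:
        i, j = self._index[id_a], self._index[id_b]
        return PDistanceValue(
            differences=int(self.differences[i, j]),
            compared_sites=int(self.compared[i, j]),
        )

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Pairs of distinct sequences sharing no comparable site."""
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.compared[i, j] == 0:
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise p-distances, computed by vectorised column masking."""
    if len(alignment) < 2:
        raise ValueError("distance matrix requires at least two sequences")
    codes = np.stack([encode(s.residues) for s in alignment])
    valid = codes >= 0
    n = len(alignment)
    differences = np.zeros((n, n), dtype=np.int64)
    compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        compared[i, i + 1 :] = both.sum(axis=1)
        differences[i, i + 1 :] = diff.sum(axis=1)
    compared += compared.T
    differences += differences.T
    np.fill_diagonal(compared, valid.sum(axis=1))
    matrix = DistanceMatrix(alignment.ids, differences, compared)
    bad = matrix.undefined_pairs()
    if bad:
        warnings.warn(
            f"{len(bad)} sequence pair(s) share no comparable site and have "
            f"undefined distance, e.g. {bad[0]}",
            stacklevel=2,
        )
    return matrix


def intraspecific_summary(
    matrix: DistanceMatrix, species_map: SpeciesMap, species: str
) -> tuple[float | None, float | None, int]:
    """(min, max, n) of within-species pairwise distances.

    Returns (None, None, n) when the species has fewer than two sequences
    or when every within-species pair is undefined.
    """
    members = [i for i in species_map.members(species) if i in matrix._index]
    n = len(members)
    if n < 2:
        return None, None, n
    vals = []
    for a in range(n):
        for b in range(a + 1, n):
            d = matrix.pair(members[a], members[b])
            if d.defined:
                vals.append(d.value)
    if not vals:
        return None, None, n
    return min(vals), max(vals), n


def interspecific_minima(
    matrix: DistanceMatrix, species_map: SpeciesMap, scope: Scope
) -> dict[tuple[str, str], tuple[float, tuple[str, str]]]:
    """Minimum distance per unordered species pair within a scope.

    Maps each species pair (sorted labels) to its minimum heterospecific
    distance together with one witnessing pair of sequence ids.  Pairs with
    every distance undefined are omitted.
    """
    scope.validate(species_map)
    in_scope = sorted(scope.species_set)
    if len(in_scope) < 2:
        raise ValueError(f"scope '{scope.name}' holds fewer than two species")
    members = {
        sp: [i for i in species_map.members(sp) if i in matrix._index]
        for sp in in_scope
    }
    out: dict[tuple[str, str], tuple[float, tuple[str, str]]] = {}
    for a_idx in range(len(in_scope)):
        for b_idx in range(a_idx + 1, len(in_scope)):
            sp_a, sp_b = in_scope[a_idx], in_scope[b_idx]
            best: tuple[float, tuple[str, str]] | None = None
            for ia in members[sp_a]:
                for ib in members[sp_b]:
                    d = matrix.pair(ia, ib)
                    if d.defined and (best is None or d.value < best[0]):
                        best = (d.value, (ia, ib))
            if best is not None:
                out[(sp_a, sp_b)] = best
    return out


def nearest_neighbor(
    minima: Mapping[tuple[str, str], tuple[float, tuple[str, str]]], species: str
) -> tuple[list[str], float]:
    """The heterospecific species at the smallest pair minimum.

    Ties return every tied species, sorted by label; the distance is the
    shared minimum.
    """
    candidates: dict[str, float] = {}
    for (sp_a, sp_b), (dist, _) in minima.items():
        if species == sp_a:
            candidates[sp_b] = min(dist, candidates.get(sp_b, math.inf))
        elif species == sp_b:
            candidates[sp_a] = min(dist, candidates.get(sp_a, math.inf))
    if not candidates:
        raise KeyError(f"species '{species}' participates in no defined pair")
    best = min(candidates.values())
    tied = sorted(sp for sp, d in candidates.items() if d == best)
    return tied, best


@dataclass
class SpeciesDistanceSummary:
    """The per-species row of a barcode-gap table.

    ``gap`` is the minimum interspecific distance minus the maximum
    intraspecific distance; positive means the species' own variation is
    cleanly separated from its nearest neighbour (a "barcode gap").
    """

    species: str
    n_sequences: int
    intra_min: float | None
    intra_max: float | None
    nearest_species: list[str]
    min_inter: float | None
    gap: float | None

    def as_row(self, *, as_percent: bool = True) -> dict:
        conv = percent if as_percent else (lambda v: v)
        return {
            "species": self.species,
            "n_sequences": self.n_sequences,
            "intra_min": conv(self.intra_min),
            "intra_max": conv(self.intra_max),
            "nearest_species": self.nearest_species,
            "min_inter": conv(self.min_inter),
            "gap": conv(self.gap),
        }


def barcode_gap_table(
    alignment: Alignment,
    species_map: SpeciesMap,
    scope: Scope | None = None,
    matrix: DistanceMatrix | None = None,
) -> list[SpeciesDistanceSummary]:
    """One summary row per species in scope: n, intra range, nearest
    neighbour, minimum interspecific distance, barcode gap."""
    if scope is None:
        scope = Scope.full(species_map)
    if matrix is None:
        matrix = distance_matrix(alignment)
    minima = interspecific_minima(matrix, species_map, scope)
    rows = []
    for species in sorted(scope.species_set):
        intra_min, intra_max, n = intraspecific_summary(matrix, species_map, species)
        try:
            nearest, min_inter = nearest_neighbor(minima, species)
        except KeyError:
            nearest, min_inter = [], None
        gap = None
        if min_inter is not None and intra_max is not None:
            gap = min_inter - intra_max
        rows.append(
            SpeciesDistanceSummary(
                species=species,
                n_sequences=n,
                intra_min=intra_min,
                intra_max=intra_max,
                nearest_species=nearest,
                min_inter=min_inter,
                gap=gap,
            )
        )
    return rows


def write_matrix_tsv(matrix: DistanceMatrix, path) -> None:
    """Square distance matrix as TSV: ids as header row and first column."""
    vals = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.ids) + "\n")
        for i, seq_id in enumerate(matrix.ids):
            cells = [
                "NA" if math.isnan(vals[i, j]) else repr(float(vals[i, j]))
                for j in range(len(matrix.ids))
            ]
            fh.write(seq_id + "\t" + "\t".join(cells) + "\n")


def write_matrix_phylip(matrix: DistanceMatrix, path) -> None:
    """Square distance matrix in relaxed PHYLIP format (NaN written as -1)."""
    vals = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, seq_id in enumerate(matrix.ids):
            cells = [
                "-1" if math.isnan(vals[i, j]) else f"{vals[i, j]:.6f}"
                for j in range(len(matrix.ids))
            ]
            fh.write(seq_id + "  " + "  ".join(cells) + "\n")
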