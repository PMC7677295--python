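"""Collapse identical aligned sequences into haplotypes.

Two equality rules are available:

* ``exact`` (default): column-wise identity of the normalised residue
  strings, with gaps, Ns and ambiguity codes treated as ordinary
  characters.  Deterministic and order-independent.
* ``missing_tolerant``: two sequences are compatible when they agree at
  every column where both carry an unambiguous base.  This relation is not
  transitive, so clusters are formed greedily in input order: each
  sequence joins the first existing haplotype whose *representative* it is
  compatible with.  Use with that caveat in mind.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import Alignment, SpeciesMap
from .distances import encode


@dataclass
class Haplotype:
    id: str
    representative: str
    members: list[str]
    species: str | None = None


@dataclass
class HaplotypeTable:
    entries: list[Haplotype]

    def counts(self) -> dict[str | None, tuple[int, int]]:
        """species -> (n_sequences, n_haplotypes)."""
        out: dict[str | None, tuple[int, int]] = {}
        for hap in self.entries:
            n_seq, n_hap = out.get(hap.species, (0, 0))
            out[hap.species] = (n_seq + len(hap.members), n_hap + 1)
        return out

    @property
    def n_haplotypes(self) -> int:
        return len(self.entries)

    def as_rows(self) -> list[dict]:
        return [
            {
                "haplotype_id": h.id,
                "species": h.species,
                "representative": h.representative,
                "n_members": len(h.members),
                "members": h.members,
            }
            for h in self.entries
        ]


def _compatible(a: str, b: str) -> bool:
    ca, cb = encode(a), encode(b)
    both = (ca >= 0) & (cb >= 0)
    return bool(((ca == cb) | ~both).all())


def collapse_haplotypes(
    alignment: Alignment,
    species_map: SpeciesMap | None = None,
    *,
    per_species: bool = True,
    missing_tolerant: bool = False,
) -> HaplotypeTable:
    """Group the alignment's sequences into haplotypes.

    With ``per_species`` (requires a species map) collapsing runs within
    each species independently and every haplotype carries its species
    label.  Haplotype ids are deterministic, numbered in order of the first
    occurring member (``H1``, ``H2``, ... or ``<species>.H1``, ...).
    """
    if per_species and species_map is None:
        raise ValueError("per-species collapsing requires a species map")

    groups: list[tuple[str | None, list[str]]]
    if per_species:
        assert species_map is not None
        groups = [(sp, species_map.members(sp)) for sp in species_map.species]
        known = {i for _, ids in groups for i in ids}
        groups = [(sp, [i for i in ids if i in alignment]) for sp, ids in groups]
        unknown = [i for i in alignment.ids if i not in known]
        if unknown:
            raise ValueError(
                f"alignment ids without species assignment: {unknown[:5]}"
            )
    else:
        groups = [(None, alignment.ids)]

    entries: list[Haplotype] = []
    for species, ids in groups:
        clusters: list[Haplotype] = []
        index: dict[str, Haplotype] = {}
        for seq_id in ids:
            residues = alignment[seq_id].residues
            target: Haplotype | None = None
            if missing_tolerant:
                for hap in clusters:
                    if _compatible(residues, alignment[hap.representative].residues):
                        target = hap
                        break
            else:
                target = index.get(residues)
            if target is None:
                prefix = f"{species}.H" if species is not None else "H"
                target = Haplotype(
                    id=f"{prefix}{len(clusters) + 1}",
                    representative=seq_id,
                    members=[],
                    species=species,
                )
                clusters.append(target)
                if not missing_tolerant:
                    index[residues] = target
            target.members.append(seq_id)
        entries.extend(clusters)
    return HaplotypeTable(entries=entries)


def haplotype_counts(table: HaplotypeTable) -> dict[str, tuple[int, int]]:
    """species -> (n_sequences, n_haplotypes) from a per-species table."""
    counts = table.counts()
    if None in counts:
        raise ValueError("haplotype table was not built per species")
    return {sp: c for sp, c in counts.items() if sp is not None}
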