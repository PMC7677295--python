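"""Reading and writing: aligned FASTA, species-map TSV, result reports."""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

from Bio import SeqIO

from . import __version__
from .alignment import (
    AlignedSequence,
    Alignment,
    AlignmentError,
    SpeciesMap,
    normalise_residues,
)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into a validated :class:`Alignment`.

    Residues are uppercased and RNA ``U`` is mapped to ``T``.  Ragged rows,
    characters outside the IUPAC nucleotide alphabet (plus ``-`` and ``?``)
    and duplicate ids raise :class:`AlignmentError` naming the offender.
    """
    path = Path(path)
    records = [
        AlignedSequence(id=rec.id, residues=normalise_residues(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA, one record per line pair, preserving order."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in alignment:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def read_species_map(
    path: str | Path,
    alignment: Alignment | None = None,
    *,
    header: bool = False,
    strict: bool = True,
) -> SpeciesMap:
    """Read a sequence -> species (-> group) assignment from a 2/3-column TSV.

    Parameters
    ----------
    alignment
        When given, ids are reconciled against it: in strict mode the map
        must cover exactly the alignment's ids; in lenient mode uncovered
        alignment ids and unknown map ids each produce a warning and the
        map is restricted to the intersection.
    header
        Skip the first row.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    grouping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (2, 3):
                raise AlignmentError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(row)}"
                )
            seq_id, species = row[0].strip(), row[1].strip()
            if not seq_id or not species:
                raise AlignmentError(f"{path}:{lineno}: empty id or species label")
            if seq_id in assignment:
                if assignment[seq_id] != species:
                    raise AlignmentError(
                        f"{path}:{lineno}: sequence '{seq_id}' mapped to both "
                        f"'{assignment[seq_id]}' and '{species}'"
                    )
                raise AlignmentError(f"{path}:{lineno}: duplicate row for '{seq_id}'")
            assignment[seq_id] = species
            if len(row) == 3 and row[2].strip():
                group = row[2].strip()
                if species in grouping and grouping[species] != group:
                    raise AlignmentError(
                        f"{path}:{lineno}: species '{species}' assigned to both "
                        f"groups '{grouping[species]}' and '{group}'"
                    )
                grouping[species] = group

    if alignment is not None:
        aln_ids = set(alignment.ids)
        map_ids = set(assignment)
        extra = map_ids - aln_ids
        missing = aln_ids - map_ids
        if strict:
            if extra:
                raise AlignmentError(
                    f"species map names ids absent from the alignment: {sorted(extra)[:5]}"
                )
            if missing:
                raise AlignmentError(
                    f"alignment ids missing from the species map: {sorted(missing)[:5]}"
                )
        else:
            if extra:
                warnings.warn(
                    f"ignoring {len(extra)} species-map ids absent from the alignment",
                    stacklevel=2,
                )
                assignment = {i: s for i, s in assignment.items() if i in aln_ids}
            if missing:
                warnings.warn(
                    f"{len(missing)} alignment ids lack a species assignment",
                    stacklevel=2,
                )
    kept_species = set(assignment.values())
    grouping = {sp: g for sp, g in grouping.items() if sp in kept_species}
    return SpeciesMap(assignment=assignment, grouping=grouping or None)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for seq_id, species in species_map.assignment.items():
            row = [seq_id, species]
            if species_map.grouping and species in species_map.grouping:
                row.append(species_map.grouping[species])
            writer.writerow(row)


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for report provenance blocks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _metadata(
    inputs: Mapping[str, str | Path] | None,
    parameters: Mapping[str, Any] | None,
    seed: int | None,
) -> dict[str, Any]:
    meta: dict[str, Any] = {"tool": "barcodiag", "version": __version__}
    if inputs:
        meta["input_digests"] = {
            str(name): file_digest(p) for name, p in inputs.items()
        }
    if parameters:
        meta["parameters"] = dict(parameters)
    if seed is not None:
        meta["seed"] = seed
    return meta


def emit_report(
    rows: Sequence[Mapping[str, Any]],
    path: str | Path,
    *,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
    inputs: Mapping[str, str | Path] | None = None,
    parameters: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    """Write a result table as TSV or JSON.

    TSV output is a plain header + rows.  JSON output wraps the rows in an
    object carrying a metadata block (tool version, SHA-256 digests of the
    inputs, parameters, seed) so every report is self-describing.
    An empty row set still yields a valid file (header only / empty list).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        if columns is None:
            columns = list(rows[0].keys()) if rows else []
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for row in rows:
                writer.writerow([_render(row.get(c)) for c in columns])
    elif fmt == "json":
        payload = {
            "metadata": _metadata(inputs, parameters, seed),
            "rows": [dict(r) for r in rows],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format '{format}' (expected tsv or json)")


def _render(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    return str(value)


def _json_default(value: Any):
    import numpy as np

    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    raise TypeError(f"not JSON serialisable: {type(value)!r}")
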