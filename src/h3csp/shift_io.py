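"""Chemical-shift table I/O and the pipeline's central data model.

A :class:`ShiftTable` holds one experimental condition's per-residue backbone
shifts (amide 1H and 15N, 13CA, 13CB and the carbonyl, stored under the
nucleus label ``C``) together with the protein sequence and its author
numbering offset.  Readers exist for the BMRB NMR-STAR v3 assigned-chemical-
shift loop and for a plain TSV dialect; writers round-trip both, and an
exporter emits the TALOS shift-input table.

Residue numbering is author numbering throughout (histone convention, matching
the H3 chains of nucleosome crystal structures); nothing is renumbered on
import.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqUtils import seq1, seq3

NUCLEI = ("H", "N", "CA", "CB", "C")

# Atom-name synonyms accepted on input; everything else is ignored.
_ATOM_ALIASES = {
    "H": "H",
    "HN": "H",
    "N": "N",
    "CA": "CA",
    "CB": "CB",
    "C": "C",
    "CO": "C",
}


class ShiftFormatError(ValueError):
    """Raised when an input file violates the expected shift-table format."""


class AmbiguityError(ValueError):
    """Raised when an NMR-STAR file holds several shift lists and no selector
    was given."""


@dataclass
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts for one condition.

    Parameters
    ----------
    condition_label
        Free-text label, e.g. ``"60bp"``.
    sequence
        One-letter amino-acid string; ``X`` marks positions whose type is
        unknown (gaps in a reconstructed sequence).
    offset
        Author residue number of ``sequence[0]``.
    shifts
        Mapping ``(residue_number, nucleus) -> shift (ppm)``.
    """

    condition_label: str
    sequence: str
    offset: int = 1
    shifts: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- sequence bookkeeping ------------------------------------------------

    def residue_type(self, residue_number: int) -> str | None:
        """One-letter code at an author residue number, or None outside the
        sequence / at gap positions."""
        i = residue_number - self.offset
        if 0 <= i < len(self.sequence):
            aa = self.sequence[i]
            return None if aa == "X" else aa
        return None

    @property
    def residue_numbers(self) -> list[int]:
        return sorted({rn for rn, _ in self.shifts})

    def nuclei_at(self, residue_number: int) -> set[str]:
        return {nuc for rn, nuc in self.shifts if rn == residue_number}

    def get(self, residue_number: int, nucleus: str) -> float | None:
        return self.shifts.get((residue_number, nucleus))

    def validate(self) -> None:
        for (rn, nuc), val in self.shifts.items():
            if nuc not in NUCLEI:
                raise ShiftFormatError(f"unknown nucleus label {nuc!r} at residue {rn}")
            if not math.isfinite(val):
                raise ShiftFormatError(f"non-finite shift for residue {rn} {nuc}")
            aa = self.residue_type(rn)
            if aa == "P" and nuc in ("H", "N"):
                raise ShiftFormatError(
                    f"proline residue {rn} cannot carry an amide {nuc} shift"
                )

    def iter_records(self) -> Iterator[tuple[int, str, str, float]]:
        """Yield (residue_number, residue_type, nucleus, value) sorted by
        residue then by canonical nucleus order."""
        order = {n: i for i, n in enumerate(NUCLEI)}
        for (rn, nuc) in sorted(self.shifts, key=lambda k: (k[0], order[k[1]])):
            aa = self.residue_type(rn) or "X"
            yield rn, aa, nuc, self.shifts[(rn, nuc)]

    def with_offsets(self, per_nucleus_offset: dict[str, float]) -> "ShiftTable":
        """Return a copy with a uniform per-nucleus referencing offset added
        (e.g. to reconcile differently referenced depositions)."""
        shifted = {
            (rn, nuc): v + per_nucleus_offset.get(nuc, 0.0)
            for (rn, nuc), v in self.shifts.items()
        }
        return ShiftTable(self.condition_label, self.sequence, self.offset, shifted)


@dataclass
class IntensityTable:
    """Raw per-residue peak intensities for one condition (arbitrary units,
    strictly positive)."""

    condition_label: str
    intensities: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rn, v in self.intensities.items():
            if not (math.isfinite(v) and v > 0):
                raise ShiftFormatError(f"nonpositive intensity at residue {rn}")


# ---------------------------------------------------------------------------
# construction from row records (shared by all readers)
# ---------------------------------------------------------------------------

def _table_from_rows(
    rows: Iterable[tuple[int, str, str, float]],
    condition_label: str,
) -> ShiftTable:
    """Build a ShiftTable from (residue_number, one-letter type, nucleus,
    value) rows, reconstructing the sequence from the residue types."""
    types: dict[int, str] = {}
    shifts: dict[tuple[int, str], float] = {}
    for rn, aa, nuc, val in rows:
        prev = types.get(rn)
        if prev is not None and prev != aa:
            raise ShiftFormatError(
                f"residue {rn} listed with conflicting types {prev!r} and {aa!r}"
            )
        types[rn] = aa
        key = (rn, nuc)
        if key in shifts:
            raise ShiftFormatError(f"duplicate shift for residue {rn} nucleus {nuc}")
        shifts[key] = val
    if types:
        offset = min(types)
        seq = "".join(types.get(i, "X") for i in range(offset, max(types) + 1))
    else:
        offset, seq = 1, ""
    return ShiftTable(condition_label, seq, offset, shifts)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["residue_number", "residue_type", "nucleus", "shift_ppm"]


def read_shift_tsv(path: str | Path, condition_label: str | None = None) -> ShiftTable:
    """Read the plain TSV dialect (header: residue_number, residue_type,
    nucleus, shift_ppm)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ShiftFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != _TSV_COLUMNS:
        raise ShiftFormatError(f"{path}: expected header {_TSV_COLUMNS}, got {header}")
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ShiftFormatError(f"{path}: malformed row {ln!r}")
        rn_s, aa, atom, val_s = parts
        nuc = _ATOM_ALIASES.get(atom.upper())
        if nuc is None:
            raise ShiftFormatError(f"{path}: unknown nucleus label {atom!r}")
        try:
            rn, val = int(rn_s), float(val_s)
        except ValueError as e:
            raise ShiftFormatError(f"{path}: non-numeric field in row {ln!r}") from e
        rows.append((rn, aa.upper(), nuc, val))
    label = condition_label if condition_label is not None else path.stem
    return _table_from_rows(rows, label)


def write_shift_tsv(table: ShiftTable, path: str | Path) -> None:
    """Write the TSV dialect (3 decimal places, diff-stable)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for rn, aa, nuc, val in table.iter_records():
        lines.append(f"{rn}\t{aa}\t{nuc}\t{val:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_intensity_tsv(path: str | Path, condition_label: str | None = None) -> IntensityTable:
    """Read a per-residue intensity TSV (header: residue_number, intensity)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0].split("\t") != ["residue_number", "intensity"]:
        raise ShiftFormatError(f"{path}: expected header residue_number<TAB>intensity")
    out: dict[int, float] = {}
    for ln in lines[1:]:
        rn_s, val_s = ln.split("\t")
        rn = int(rn_s)
        if rn in out:
            raise ShiftFormatError(f"{path}: duplicate residue {rn}")
        out[rn] = float(val_s)
    label = condition_label if condition_label is not None else path.stem
    return IntensityTable(label, out)


def write_intensity_tsv(table: IntensityTable, path: str | Path) -> None:
    lines = ["residue_number\tintensity"]
    for rn in sorted(table.intensities):
        lines.append(f"{rn}\t{table.intensities[rn]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NMR-STAR v3 (BMRB assigned chemical shift loop)
# ---------------------------------------------------------------------------
#
# The deposition dialect is a flat `_Atom_chem_shift` loop inside an
# assigned_chemical_shifts saveframe.  We parse exactly that: STAR tokenizing
# of the loop region, no nested frames or multiline values (the shift loops
# in backbone depositions use neither).

_STAR_TAGS = {
    "seq": "_Atom_chem_shift.Seq_ID",
    "auth_seq": "_Atom_chem_shift.Auth_seq_ID",
    "comp": "_Atom_chem_shift.Comp_ID",
    "atom": "_Atom_chem_shift.Atom_ID",
    "val": "_Atom_chem_shift.Val",
    "entity": "_Atom_chem_shift.Entity_ID",
}


def _star_loops(text: str) -> list[tuple[list[str], list[str]]]:
    """Return (tags, tokens) for every loop in a STAR file."""
    tokens: list[str] = []
    for ln in text.splitlines():
        ln = ln.split("#", 1)[0] if not ln.lstrip().startswith("#") else ""
        tokens.extend(ln.split())
    loops = []
    i = 0
    while i < len(tokens):
        if tokens[i] == "loop_":
            i += 1
            tags = []
            while i < len(tokens) and tokens[i].startswith("_"):
                tags.append(tokens[i])
                i += 1
            data = []
            while i < len(tokens) and tokens[i] != "stop_":
                data.append(tokens[i])
                i += 1
            loops.append((tags, data))
        i += 1
    return loops


def read_nmrstar(
    path: str | Path,
    entity_selector: str | None = None,
    condition_label: str | None = None,
) -> ShiftTable:
    """Read a ShiftTable from an NMR-STAR v3 file.

    Atom names are mapped H/HN->H, N->N, CA->CA, CB->CB, C/CO->C; all other
    atoms are ignored.  Author numbering (``Auth_seq_ID``) is used when
    present, the plain ``Seq_ID`` otherwise.  ``entity_selector`` picks one
    Entity_ID when the loop spans several entities.
    """
    path = Path(path)
    text = path.read_text()
    shift_loops = [
        (tags, data)
        for tags, data in _star_loops(text)
        if any(t.startswith("_Atom_chem_shift.") for t in tags)
    ]
    if not shift_loops:
        raise ShiftFormatError(f"{path}: no assigned-chemical-shift loop found")
    if len(shift_loops) > 1 and entity_selector is None:
        raise AmbiguityError(
            f"{path}: {len(shift_loops)} shift loops present; pass entity_selector"
        )
    tags, data = shift_loops[0]
    ncol = len(tags)
    if ncol == 0 or len(data) % ncol != 0:
        raise ShiftFormatError(f"{path}: ragged shift loop")
    col = {t: i for i, t in enumerate(tags)}

    def _get(row: list[str], key: str) -> str | None:
        idx = col.get(_STAR_TAGS[key])
        if idx is None:
            return None
        v = row[idx]
        return None if v in (".", "?") else v

    if _STAR_TAGS["comp"] not in col or _STAR_TAGS["atom"] not in col or _STAR_TAGS["val"] not in col:
        raise ShiftFormatError(f"{path}: shift loop lacks Comp_ID/Atom_ID/Val tags")

    entities = set()
    rows = []
    for r in range(0, len(data), ncol):
        row = data[r : r + ncol]
        ent = _get(row, "entity")
        if ent is not None:
            entities.add(ent)
        if entity_selector is not None and ent is not None and ent != str(entity_selector):
            continue
        atom = _get(row, "atom")
        nuc = _ATOM_ALIASES.get((atom or "").upper())
        if nuc is None:
            continue
        rn_s = _get(row, "auth_seq") or _get(row, "seq")
        comp = _get(row, "comp")
        val_s = _get(row, "val")
        if rn_s is None or comp is None or val_s is None:
            raise ShiftFormatError(f"{path}: incomplete shift row {row}")
        aa = comp if len(comp) == 1 else seq1(comp.capitalize())
        if aa in ("", "X") and len(comp) == 3:
            raise ShiftFormatError(f"{path}: unknown residue type {comp!r}")
        try:
            rows.append((int(rn_s), aa.upper(), nuc, float(val_s)))
        except ValueError as e:
            raise ShiftFormatError(f"{path}: non-numeric shift row {row}") from e
    if entity_selector is None and len(entities) > 1:
        raise AmbiguityError(
            f"{path}: entities {sorted(entities)} present; pass entity_selector"
        )
    label = condition_label if condition_label is not None else path.stem
    return _table_from_rows(rows, label)


def write_nmrstar(table: ShiftTable, path: str | Path) -> None:
    """Write a minimal NMR-STAR v3 file with one assigned-chemical-shift loop
    (readable back by :func:`read_nmrstar`)."""
    element = {"H": "H", "N": "N", "CA": "C", "CB": "C", "C": "C"}
    lines = [
        f"data_{_star_safe(table.condition_label)}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.ID            1",
        "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Entity_ID",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Auth_seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Atom_type",
        "      _Atom_chem_shift.Val",
        "",
    ]
    for i, (rn, aa, nuc, val) in enumerate(table.iter_records(), start=1):
        comp = seq3(aa).upper() if aa != "X" else "UNK"
        lines.append(
            f"      {i:<5d} 1 {rn:<4d} {rn:<4d} {comp:<4s} {nuc:<3s} "
            f"{element[nuc]:<2s} {val:.3f}"
        )
    lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines))


def _star_safe(label: str) -> str:
    safe = "".join(c if c.isalnum() or c in "_-" else "_" for c in label)
    return safe or "shifts"


# ---------------------------------------------------------------------------
# TALOS shift-input export
# ---------------------------------------------------------------------------

def export_talos_input(table: ShiftTable, path: str | Path) -> int:
    """Write the TALOS shift-table input dialect; returns the number of data
    rows written (= number of shifts in the table).

    Atom names follow the TALOS convention (HN, N, CA, CB, C); prolines carry
    no HN row because the table holds no amide shifts for them.
    """
    talos_atom = {"H": "HN", "N": "N", "CA": "CA", "CB": "CB", "C": "C"}
    seq = table.sequence
    lines = []
    for i in range(0, len(seq), 10):
        lines.append(f"DATA SEQUENCE {seq[i:i+10]}")
    lines += [
        "",
        "VARS   RESID RESNAME ATOMNAME SHIFT",
        "FORMAT %4d   %1s     %4s      %8.3f",
        "",
    ]
    n = 0
    for rn, aa, nuc, val in table.iter_records():
        lines.append(f"{rn:4d} {aa:>1s} {talos_atom[nuc]:>4s} {val:8.3f}")
        n += 1
    if table.offset != 1:
        lines.insert(0, f"DATA FIRST_RESID {table.offset}")
    Path(path).write_text("\n".join(lines) + "\n")
    return n


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta_sequence(path: str | Path) -> str:
    """Read the first record of a FASTA file as a one-letter string."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise ShiftFormatError(f"{path}: no FASTA record")
    return str(rec.seq).upper()
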