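"""Project per-residue perturbation values onto a coordinate file.

Writes per-residue scalars (combined shift differences, or integer category
codes) into the B-factor column of a PDB file so molecular viewers can color
the structure by perturbation.  Both H3 copies of the octamer receive the
same values when both chains are selected, since the NMR data do not
distinguish the two copies.

Only the temperature-factor field (columns 61-66) of ATOM/HETATM records on
the selected chains is rewritten; every other byte of the file is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .csp import CspProfile

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_CODES = {
    "incomplete": 0,
    "below": 1,
    "significant": 2,
    "pronounced": 3,
}

# Representable range of the fixed-column %6.2f B-factor field.
_BMIN, _BMAX = -99.99, 999.99


class PdbFormatError(ValueError):
    """Raised for files without parseable ATOM/HETATM records."""


@dataclass
class StructureMapSpec:
    pdb_path: str | Path
    chain_ids: list[str]
    value_source: str = "delta_combined"  # or "category_code"
    missing_value_fill: float = 0.0
    category_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_CODES)
    )

    def __post_init__(self) -> None:
        if self.value_source not in ("delta_combined", "category_code"):
            raise ValueError(f"unknown value_source {self.value_source!r}")
        codes = list(self.category_codes.values())
        if len(codes) != len(set(codes)):
            raise ValueError("category codes must be distinct")


def _residue_values(
    source: CspProfile | Mapping[int, str] | Mapping[int, float],
    spec: StructureMapSpec,
) -> dict[int, float]:
    if isinstance(source, CspProfile):
        if spec.value_source != "delta_combined":
            raise ValueError("a CspProfile maps via value_source='delta_combined'")
        return {
            r.residue_number: r.delta_combined
            for r in source.records
            if r.delta_combined is not None
        }
    values: dict[int, float] = {}
    for rn, v in source.items():
        if isinstance(v, str):
            if spec.value_source != "category_code":
                raise ValueError(
                    "a classification map requires value_source='category_code'"
                )
            values[rn] = float(spec.category_codes[v])
        else:
            values[rn] = float(v)
    return values


def write_bfactor_map(
    source: CspProfile | Mapping[int, str] | Mapping[int, float],
    spec: StructureMapSpec,
    out: str | Path,
) -> tuple[int, int]:
    """Rewrite B-factors on the selected chains; returns (n_mapped,
    n_unmatched).

    ``n_mapped`` counts source residues found on at least one selected chain,
    ``n_unmatched`` those found on none.  Residues of the selected chains
    absent from the source get ``missing_value_fill``; other chains are left
    untouched byte for byte.
    """
    values = _residue_values(source, spec)
    text = Path(spec.pdb_path).read_text()
    lines = text.splitlines(keepends=True)

    chains = set(spec.chain_ids)
    seen_chains: set[str] = set()
    matched: set[int] = set()
    out_lines = []
    n_atoms = 0
    for ln in lines:
        rec = ln[:6]
        if rec in ("ATOM  ", "HETATM") and len(ln.rstrip("\n")) >= 66:
            n_atoms += 1
            chain = ln[21]
            seen_chains.add(chain)
            if chain in chains:
                try:
                    resseq = int(ln[22:26])
                except ValueError as e:
                    raise PdbFormatError(f"bad residue number field: {ln!r}") from e
                if resseq in values:
                    b = values[resseq]
                    matched.add(resseq)
                else:
                    b = spec.missing_value_fill
                if not (_BMIN <= b <= _BMAX):
                    logger.warning(
                        "B-factor %.3f at residue %d clipped to field range", b, resseq
                    )
                    b = min(max(b, _BMIN), _BMAX)
                ln = ln[:60] + f"{b:6.2f}" + ln[66:]
        out_lines.append(ln)

    if n_atoms == 0:
        raise PdbFormatError(f"{spec.pdb_path}: no ATOM/HETATM records")
    missing_chains = chains - seen_chains
    if missing_chains:
        raise PdbFormatError(
            f"{spec.pdb_path}: chains {sorted(missing_chains)} not present"
        )
    if not matched:
        raise PdbFormatError(
            f"no source residues matched on chains {sorted(chains)}"
        )
    Path(out).write_text("".join(out_lines))
    return len(matched), len(set(values) - matched)


def read_bfactors(path: str | Path, chain_id: str) -> dict[int, float]:
    """Per-residue B-factor of the first atom of each residue on one chain
    (convenience for checking written maps)."""
    out: dict[int, float] = {}
    for ln in Path(path).read_text().splitlines():
        if ln[:6] in ("ATOM  ", "HETATM") and len(ln) >= 66 and ln[21] == chain_id:
            rn = int(ln[22:26])
            out.setdefault(rn, float(ln[60:66]))
    return out
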