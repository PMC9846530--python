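"""Assignment-completeness accounting and relative peak-intensity profiles.

The completeness statistics mirror how assignment coverage is reported for
amide-detected experiments: over a residue range, prolines (which lack the
amide proton) are excluded from both numerator and denominator, and a residue
counts as assigned when its amide H and N shifts are present (configurable to
require CA as well).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .shift_io import IntensityTable, ShiftTable


@dataclass
class AssignmentStats:
    range_start: int
    range_end: int
    n_residues: int
    n_proline: int
    n_non_proline: int
    assigned: set[int] = field(default_factory=set)
    unassigned_non_proline: set[int] = field(default_factory=set)

    @property
    def n_assigned(self) -> int:
        return self.n_non_proline - len(self.unassigned_non_proline)

    def summary(self) -> str:
        return (
            f"{self.n_assigned} out of {self.n_non_proline} non-proline residues "
            f"assigned in range {self.range_start}-{self.range_end}"
        )


def assignment_stats(
    sequence: str,
    range_start: int,
    range_end: int,
    assigned: Iterable[int],
    offset: int = 1,
) -> AssignmentStats:
    """Count assigned vs assignable residues over an inclusive range.

    Prolines never count as assigned or assignable; membership of a proline in
    ``assigned`` is ignored.
    """
    if range_start > range_end:
        raise ValueError("range_start must not exceed range_end")
    lo, hi = offset, offset + len(sequence) - 1
    if range_start < lo or range_end > hi:
        raise ValueError(
            f"range {range_start}-{range_end} outside sequence ({lo}-{hi})"
        )
    assigned = set(assigned)
    if not assigned <= set(range(range_start, range_end + 1)):
        raise ValueError("assigned set contains residues outside the range")
    prolines = {
        rn
        for rn in range(range_start, range_end + 1)
        if sequence[rn - offset] == "P"
    }
    non_pro = set(range(range_start, range_end + 1)) - prolines
    assigned_np = assigned & non_pro
    return AssignmentStats(
        range_start=range_start,
        range_end=range_end,
        n_residues=range_end - range_start + 1,
        n_proline=len(prolines),
        n_non_proline=len(non_pro),
        assigned=assigned_np,
        unassigned_non_proline=non_pro - assigned_np,
    )


def assigned_residues(
    table: ShiftTable, require: Sequence[str] = ("H", "N")
) -> set[int]:
    """Residues whose shift set contains every nucleus in ``require``
    (amide-detected definition by default; prolines can never qualify under
    it)."""
    need = set(require)
    return {rn for rn in table.residue_numbers if need <= table.nuclei_at(rn)}


@dataclass
class IntensityProfile:
    """Per-residue intensities normalized into (0, 1]."""

    condition_label: str
    records: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.records:
            top = max(v for _, v in self.records)
            if abs(top - 1.0) > 1e-12:
                raise ValueError("relative intensities must be anchored at 1")

    def as_dict(self) -> dict[int, float]:
        return dict(self.records)


def intensity_profile(raw: IntensityTable, anchor: str = "max") -> IntensityProfile:
    """Normalize raw intensities to relative ones.

    ``anchor='max'`` (default) divides by the maximum so the strongest peak is
    exactly 1; ``anchor='mean'`` divides by the mean and then rescales the
    maximum to 1 (the two coincide up to a constant; the stored profile is
    always max-anchored so profiles are mutually comparable).
    """
    if not raw.intensities:
        raise ValueError("intensity table is empty")
    if anchor not in ("max", "mean"):
        raise ValueError("anchor must be 'max' or 'mean'")
    top = max(raw.intensities.values())
    records = [(rn, v / top) for rn, v in sorted(raw.intensities.items())]
    return IntensityProfile(raw.condition_label, records)


def compare_profiles(
    a: IntensityProfile, b: IntensityProfile
) -> tuple[int, float, float]:
    """(shared_n, RMSD, Pearson r) over residues present in both profiles."""
    da, db = a.as_dict(), b.as_dict()
    shared = sorted(set(da) & set(db))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared residues (need >= 3)")
    va = np.array([da[rn] for rn in shared])
    vb = np.array([db[rn] for rn in shared])
    rmsd = float(np.sqrt(np.mean((va - vb) ** 2)))
    r = float(stats.pearsonr(va, vb).statistic)
    return len(shared), rmsd, r
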