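"""Weighted combined chemical-shift differences between two conditions.

For each residue with amide 1H, 15N and 13CA shifts available in both
conditions, the combined perturbation is the weighted Euclidean norm

    ddelta = sqrt(dHN^2 + alpha * dN^2 + beta * dCA^2)

with beta = 0.3 and alpha = 0.14 for all residues except glycine, where
alpha = 0.2.  The per-nucleus weights compensate for the different chemical-
shift dispersions of the three nuclei.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .shift_io import ShiftTable


@dataclass(frozen=True)
class CspWeights:
    """Weights of the combined shift difference."""

    alpha_default: float = 0.14
    alpha_glycine: float = 0.2
    beta: float = 0.3

    def __post_init__(self) -> None:
        if min(self.alpha_default, self.alpha_glycine, self.beta) <= 0:
            raise ValueError("CSP weights must be positive")

    def alpha(self, residue_type: str) -> float:
        return self.alpha_glycine if residue_type == "G" else self.alpha_default


DEFAULT_WEIGHTS = CspWeights()


def combined_delta(
    d_hn: float,
    d_n: float,
    d_ca: float,
    residue_type: str = "A",
    weights: CspWeights = DEFAULT_WEIGHTS,
) -> float:
    """Combined chemical-shift difference (ppm) from the three per-nucleus
    differences; invariant under sign flips of any input."""
    a = weights.alpha(residue_type)
    return math.sqrt(d_hn * d_hn + a * d_n * d_n + weights.beta * d_ca * d_ca)


@dataclass
class CspRecord:
    """Per-residue nucleus-wise differences for one condition pair.

    ``delta_combined`` is present iff all three nuclei were available in both
    conditions (``complete``); partial records keep whatever differences exist
    but are excluded from combined summaries.
    """

    residue_number: int
    residue_type: str
    d_hn: float | None = None
    d_n: float | None = None
    d_ca: float | None = None
    delta_combined: float | None = None

    @property
    def complete(self) -> bool:
        return self.delta_combined is not None


@dataclass
class CspProfile:
    """Ordered per-residue CSP records for one pair of conditions."""

    pair_label: tuple[str, str]
    weights: CspWeights
    records: list[CspRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.residue_number for r in self.records]
        if len(nums) != len(set(nums)):
            raise ValueError("duplicate residue numbers in profile")
        self.records.sort(key=lambda r: r.residue_number)

    def complete_records(self) -> list[CspRecord]:
        return [r for r in self.records if r.complete]

    def get(self, residue_number: int) -> CspRecord | None:
        for r in self.records:
            if r.residue_number == residue_number:
                return r
        return None

    def to_frame(self):
        """Profile as a pandas DataFrame (one row per residue)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_number": [r.residue_number for r in self.records],
                "residue_type": [r.residue_type for r in self.records],
                "d_hn": [r.d_hn for r in self.records],
                "d_n": [r.d_n for r in self.records],
                "d_ca": [r.d_ca for r in self.records],
                "delta_combined": [r.delta_combined for r in self.records],
                "complete": [r.complete for r in self.records],
            }
        )

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            if header_comment:
                for ln in header_comment.splitlines():
                    fh.write(f"# {ln}\n")
            fh.write(f"# pair: {self.pair_label[0]} - {self.pair_label[1]}\n")
            df.to_csv(fh, index=False, float_format="%.6f")


def _check_sequences(a: ShiftTable, b: ShiftTable, residues: Iterable[int]) -> None:
    for rn in residues:
        ta, tb = a.residue_type(rn), b.residue_type(rn)
        if ta is not None and tb is not None and ta != tb:
            raise ValueError(
                f"sequence disagreement at residue {rn}: {ta!r} vs {tb!r} "
                f"({a.condition_label} vs {b.condition_label})"
            )


def pairwise_profile(
    a: ShiftTable,
    b: ShiftTable,
    weights: CspWeights = DEFAULT_WEIGHTS,
) -> CspProfile:
    """Per-residue differences (a - b) and combined delta for one pair.

    A record appears for every residue carrying at least one of H, N, CA in
    either table; each per-nucleus difference is populated only where that
    nucleus exists in both tables, and the combined delta only when all three
    do.
    """
    relevant = ("H", "N", "CA")
    residues = sorted(
        {rn for rn, nuc in a.shifts if nuc in relevant}
        | {rn for rn, nuc in b.shifts if nuc in relevant}
    )
    _check_sequences(a, b, residues)
    records = []
    for rn in residues:
        aa = a.residue_type(rn) or b.residue_type(rn) or "X"
        diffs = {}
        for nuc in relevant:
            va, vb = a.get(rn, nuc), b.get(rn, nuc)
            if va is not None and vb is not None:
                diffs[nuc] = va - vb
        rec = CspRecord(
            residue_number=rn,
            residue_type=aa,
            d_hn=diffs.get("H"),
            d_n=diffs.get("N"),
            d_ca=diffs.get("CA"),
        )
        if len(diffs) == 3:
            rec.delta_combined = combined_delta(
                diffs["H"], diffs["N"], diffs["CA"], aa, weights
            )
        records.append(rec)
    return CspProfile((a.condition_label, b.condition_label), weights, records)


def mean_abs_nucleus_diff(
    a: ShiftTable,
    b: ShiftTable,
    nucleus: str,
    ddof: int = 1,
) -> tuple[float, float, int] | None:
    """Mean and sample SD of |delta| for one nucleus over residues carrying it
    in both tables; None when no residue qualifies.

    The SD uses the n-1 denominator by default (``ddof=0`` for population SD)
    and is NaN for a single residue.
    """
    shared = sorted(
        {rn for rn, nuc in a.shifts if nuc == nucleus}
        & {rn for rn, nuc in b.shifts if nuc == nucleus}
    )
    _check_sequences(a, b, shared)
    if not shared:
        return None
    diffs = np.array([abs(a.get(rn, nucleus) - b.get(rn, nucleus)) for rn in shared])
    sd = float(np.std(diffs, ddof=ddof)) if len(diffs) > ddof else float("nan")
    return float(np.mean(diffs)), sd, len(diffs)


def mean_combined_delta(
    profile: CspProfile, ddof: int = 1
) -> tuple[float, float, int]:
    """Mean and sample SD of the combined delta over complete records."""
    vals = np.array([r.delta_combined for r in profile.complete_records()])
    if vals.size == 0:
        raise ValueError("profile has no complete records")
    sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else float("nan")
    return float(np.mean(vals)), sd, int(vals.size)
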