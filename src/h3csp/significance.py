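"""Data-driven significance thresholds for combined shift differences.

Thresholds are derived from the profile itself: the mean and SD of the
combined delta are computed over the subset of residues whose individual
delta is below a trim cutoff (0.1 ppm by default, strict inequality), and
significance levels are set at mean + k * SD for k = 2.5 and 5.  Residues
are then classified as ``below``, ``significant`` (>= lower threshold) or
``pronounced`` (>= upper threshold); residues lacking a combined delta are
``incomplete``.

The trim is single-pass at a fixed cutoff; the iterative re-trimming variant
common in solution-state CSP work (repeatedly discarding values more than
``iter_k`` SDs above the mean until stable) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .csp import CspProfile

CATEGORIES = ("incomplete", "below", "significant", "pronounced")
DEFAULT_TRIM_CUTOFF = 0.1
DEFAULT_K_VALUES = (2.5, 5.0)
# Absolute fallback levels (ppm) selectable instead of the data-driven ones.
DEFAULT_ABSOLUTE_THRESHOLDS = (0.10, 0.15)


@dataclass
class ThresholdResult:
    """Trimmed-subset statistics, derived cutoffs and per-residue classes."""

    trim_cutoff: float
    subset_mean: float
    subset_sd: float
    subset_n: int
    k_values: tuple[float, ...]
    thresholds: tuple[float, ...]
    classification: dict[int, str] = field(default_factory=dict)
    pair_label: tuple[str, str] | None = None

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.classification.values():
            out[cat] += 1
        return out


def _classify_value(delta: float | None, thresholds: Sequence[float]) -> str:
    """Boundary convention: thresholds are category floors (lower bound
    inclusive)."""
    if delta is None:
        return "incomplete"
    if len(thresholds) >= 2 and delta >= thresholds[1]:
        return "pronounced"
    if delta >= thresholds[0]:
        return "significant"
    return "below"


def derive_thresholds(
    profile: CspProfile | Sequence[CspProfile],
    trim_cutoff: float = DEFAULT_TRIM_CUTOFF,
    k_values: Sequence[float] = DEFAULT_K_VALUES,
    ddof: int = 1,
    iterative: bool = False,
    iter_k: float = 3.0,
    max_iter: int = 50,
) -> ThresholdResult:
    """Derive significance thresholds from one profile (or from several,
    pooling their complete records).

    The subset is the complete records with delta strictly below
    ``trim_cutoff``; thresholds are ``mean + k * sd`` for each ``k``.  SD uses
    the sample (n-1) estimator by default.  With ``iterative=True`` the subset
    is further re-trimmed at mean + ``iter_k`` * sd until stable.
    """
    profiles = [profile] if isinstance(profile, CspProfile) else list(profile)
    classify_on = profiles[0]
    values = np.array(
        [r.delta_combined for p in profiles for r in p.complete_records()]
    )
    subset = values[values < trim_cutoff]
    if subset.size < 3:
        raise ValueError(
            f"only {subset.size} residues below trim cutoff {trim_cutoff} ppm; "
            "increase trim_cutoff"
        )
    if iterative:
        for _ in range(max_iter):
            m, s = float(np.mean(subset)), float(np.std(subset, ddof=ddof))
            kept = subset[subset <= m + iter_k * s]
            if kept.size == subset.size or kept.size < 3:
                break
            subset = kept
    mean = float(np.mean(subset))
    sd = float(np.std(subset, ddof=ddof))
    ks = tuple(float(k) for k in k_values)
    thresholds = tuple(mean + k * sd for k in ks)
    result = ThresholdResult(
        trim_cutoff=trim_cutoff,
        subset_mean=mean,
        subset_sd=sd,
        subset_n=int(subset.size),
        k_values=ks,
        thresholds=thresholds,
        pair_label=classify_on.pair_label,
    )
    result.classification = classify(classify_on, result)
    return result


def absolute_thresholds(
    profile: CspProfile,
    levels: Sequence[float] = DEFAULT_ABSOLUTE_THRESHOLDS,
) -> ThresholdResult:
    """Fixed absolute cutoff levels (ppm) instead of the data-driven ones;
    subset statistics are reported as NaN."""
    result = ThresholdResult(
        trim_cutoff=float("nan"),
        subset_mean=float("nan"),
        subset_sd=float("nan"),
        subset_n=0,
        k_values=(),
        thresholds=tuple(float(x) for x in levels),
        pair_label=profile.pair_label,
    )
    result.classification = classify(profile, result)
    return result


def classify(profile: CspProfile, thresholds: ThresholdResult) -> dict[int, str]:
    """Deterministic per-residue category using the floor convention."""
    return {
        r.residue_number: _classify_value(r.delta_combined, thresholds.thresholds)
        for r in profile.records
    }


def classification_to_csv(
    profile: CspProfile,
    result: ThresholdResult,
    path,
    header_comment: str | None = None,
) -> None:
    """Write residue_number, delta_combined, category with a metadata block
    (cutoff, k, mean, sd, thresholds) as header comments."""
    lines = []
    if header_comment:
        lines += [f"# {ln}" for ln in header_comment.splitlines()]
    lines += [
        f"# pair: {result.pair_label[0]} - {result.pair_label[1]}"
        if result.pair_label
        else "# pair: (unspecified)",
        f"# trim_cutoff_ppm: {result.trim_cutoff}",
        f"# k_values: {list(result.k_values)}",
        f"# subset_mean_ppm: {result.subset_mean:.6f}",
        f"# subset_sd_ppm: {result.subset_sd:.6f}",
        f"# subset_n: {result.subset_n}",
        "# thresholds_ppm: " + ", ".join(f"{t:.6f}" for t in result.thresholds),
        "residue_number,delta_combined,category",
    ]
    for r in profile.records:
        d = "" if r.delta_combined is None else f"{r.delta_combined:.6f}"
        lines.append(f"{r.residue_number},{d},{result.classification[r.residue_number]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
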