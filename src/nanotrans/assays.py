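"""Assay post-processing: viability normalisation, qPCR fold change, Welch test.

alamarBlue fluorescence is normalised to untreated (negative-control) wells,
which define 100% viability.  qPCR cycle thresholds are reduced with the
2^-ddCT method against a reference gene and an untreated control, with a
two-fold change as the upregulation threshold.  Group comparisons use
Welch's unequal-variance t-test with the conventional star categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlateReadings",
    "QpcrRecord",
    "ViabilityResult",
    "WelchResult",
    "viability_percent",
    "relative_quantification",
    "upregulation_flag",
    "welch_test",
    "star_category",
]


@dataclass
class PlateReadings:
    """Fluorescence values per well for one condition set."""

    treated: np.ndarray
    negative_control: np.ndarray
    positive_control: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.treated = np.asarray(self.treated, dtype=float)
        self.negative_control = np.asarray(self.negative_control, dtype=float)
        if self.positive_control is not None:
            self.positive_control = np.asarray(self.positive_control, dtype=float)
        for name in ("treated", "negative_control"):
            arr = getattr(self, name)
            if arr.size < 3:
                raise ValueError(f"{name}: need >= 3 wells")
            if np.any(arr < 0):
                raise ValueError(f"{name}: fluorescence must be >= 0")


@dataclass(frozen=True)
class ViabilityResult:
    percent: float
    sd_percent: float


def viability_percent(readings: PlateReadings) -> ViabilityResult:
    """Viability as percent of the negative control, with well-level SD.

    The SD propagates the replicate-well variability of both the treated and
    the control wells through the ratio (first-order, independent groups).
    """
    control_mean = readings.negative_control.mean()
    if control_mean <= 0:
        raise ValueError("negative-control mean must be positive")
    treated_mean = readings.treated.mean()
    ratio = treated_mean / control_mean
    rel_var = 0.0
    if treated_mean > 0:
        rel_var += (readings.treated.std(ddof=1) / treated_mean) ** 2
    rel_var += (readings.negative_control.std(ddof=1) / control_mean) ** 2
    return ViabilityResult(percent=100.0 * ratio,
                           sd_percent=100.0 * ratio * math.sqrt(rel_var))


@dataclass
class QpcrRecord:
    """Cycle thresholds for a target and reference gene, sample vs control.

    Replicate CTs are averaged before forming dCT.
    """

    sample_target_ct: Sequence[float]
    sample_reference_ct: Sequence[float]
    control_target_ct: Sequence[float]
    control_reference_ct: Sequence[float]

    def __post_init__(self) -> None:
        for name in ("sample_target_ct", "sample_reference_ct",
                     "control_target_ct", "control_reference_ct"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                raise ValueError(f"{name}: missing CT values")
            if np.any((arr <= 0) | (arr >= 45)):
                raise ValueError(f"{name}: CT values must lie in (0, 45)")
            setattr(self, name, arr)


def relative_quantification(record: QpcrRecord) -> float:
    """Fold change RQ = 2^-ddCT.

    dCT = CT_target - CT_reference per condition; ddCT is the sample dCT
    minus the control dCT.  RQ is invariant to any constant shift applied to
    all CTs.
    """
    dct_sample = record.sample_target_ct.mean() - record.sample_reference_ct.mean()
    dct_control = record.control_target_ct.mean() - record.control_reference_ct.mean()
    return float(2.0 ** -(dct_sample - dct_control))


def upregulation_flag(rq: float, threshold: float = 2.0) -> bool:
    """True when the fold change reaches the two-fold effect threshold."""
    if rq < 0:
        raise ValueError("RQ must be >= 0")
    return rq >= threshold


def star_category(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001 (strict)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class WelchResult:
    p_value: float
    statistic: float
    df: float
    stars: str


def welch_test(a, b) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Degenerate input (both groups constant) gives p = 1 for equal means and
    p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return WelchResult(p_value=p, statistic=float("inf") if p == 0 else 0.0,
                           df=float(a.size + b.size - 2), stars=star_category(p))
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = float(res.pvalue)
    return WelchResult(p_value=p, statistic=float(res.statistic), df=float(df),
                       stars=star_category(p))
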