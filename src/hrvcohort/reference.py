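"""Reference ranges, classification, tertiles, and distribution summaries.

A reference range for a marker is the 5th-95th percentile interval of its
distribution in the healthy/at-risk subgroup of the cohort (heart-failure
stage 0/A, excluding long-standing untreated diabetes and degenerative or
structural neurological disorders). Values of other subjects are classified
as below / inside / above this range; the bounds themselves count as inside.

The quantile convention throughout is linear interpolation between order
statistics at position p*(n-1) (numpy's default), recorded in output
metadata so downstream users can reproduce the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceRange",
    "percentile",
    "derive_reference_range",
    "classify_against_range",
    "tertile_cutpoints",
    "assign_tertiles",
    "distribution_summary",
    "healthy_mask",
    "reference_group_size",
    "QUANTILE_CONVENTION",
]

QUANTILE_CONVENTION = "linear interpolation at position p*(n-1)"


@dataclass
class ReferenceRange:
    marker: str
    lower: float
    upper: float
    lower_p: float = 0.05
    upper_p: float = 0.95
    n_reference: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def percentile(values, p: float) -> float:
    """Quantile by linear interpolation between order statistics.

    ``p`` is a fraction in [0, 1]; the value is interpolated at (0-based)
    position p*(n-1) of the sorted sample.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(np.quantile(values, p, method="linear"))


def derive_reference_range(
    cohort_markers: pd.DataFrame,
    healthy: np.ndarray,
    marker: str,
    lower_p: float = 0.05,
    upper_p: float = 0.95,
    min_reference_n: int = 20,
) -> ReferenceRange:
    """Percentile bounds of a marker among the healthy subgroup.

    Missing marker values are skipped. Refuses to derive a range from fewer
    than ``min_reference_n`` non-missing reference values.
    """
    healthy = np.asarray(healthy, dtype=bool)
    if len(healthy) != len(cohort_markers):
        raise ValueError("healthy mask length must match the cohort table")
    vals = pd.to_numeric(cohort_markers.loc[healthy, marker], errors="coerce").dropna()
    if len(vals) < min_reference_n:
        raise ValueError(
            f"reference group for {marker!r} has only {len(vals)} non-missing "
            f"values (floor {min_reference_n})"
        )
    return ReferenceRange(
        marker=marker,
        lower=percentile(vals.to_numpy(), lower_p),
        upper=percentile(vals.to_numpy(), upper_p),
        lower_p=lower_p,
        upper_p=upper_p,
        n_reference=int(len(vals)),
    )


def classify_against_range(value: float, rng: ReferenceRange) -> str | None:
    """'below' | 'inside' | 'above'; None for a missing value (propagated)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value < rng.lower:
        return "below"
    if value > rng.upper:
        return "above"
    return "inside"


def tertile_cutpoints(values) -> tuple[float, float]:
    """1/3 and 2/3 quantiles under the package quantile convention."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise ValueError("tertiles need at least 3 non-missing values")
    return percentile(values, 1.0 / 3.0), percentile(values, 2.0 / 3.0)


def assign_tertiles(values, cutpoints: tuple[float, float] | None = None):
    """Assign 'lowest' (<= t1), 'middle' (> t1 and <= t2), 'highest' (> t2).

    Missing values map to None. With tied cutpoints everything at or below
    them is 'lowest'.
    """
    arr = np.asarray(values, dtype=float)
    if cutpoints is None:
        cutpoints = tertile_cutpoints(arr)
    t1, t2 = cutpoints
    out = np.empty(arr.shape, dtype=object)
    for i, v in enumerate(arr):
        if np.isnan(v):
            out[i] = None
        elif v <= t1:
            out[i] = "lowest"
        elif v <= t2:
            out[i] = "middle"
        else:
            out[i] = "highest"
    return out


def distribution_summary(values, rng: ReferenceRange | None = None) -> dict:
    """Median, quartiles, 5th/95th percentiles, and out-of-range rates.

    When a reference range is supplied the counts and percentages of values
    strictly below its lower bound and strictly above its upper bound are
    included; below + above always equals outside.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    out = {
        "n": int(arr.size),
        "median": percentile(arr, 0.5),
        "q1": percentile(arr, 0.25),
        "q3": percentile(arr, 0.75),
        "p5": percentile(arr, 0.05),
        "p95": percentile(arr, 0.95),
    }
    if rng is not None:
        below = int(np.sum(arr < rng.lower))
        above = int(np.sum(arr > rng.upper))
        out.update(
            n_below=below,
            n_above=above,
            n_outside=below + above,
            pct_below=100.0 * below / arr.size,
            pct_above=100.0 * above / arr.size,
            pct_outside=100.0 * (below + above) / arr.size,
        )
    return out


def healthy_mask(
    covariates: pd.DataFrame,
    stage_col: str = "hf_stage",
    healthy_stages: tuple[str, ...] = ("0", "A"),
    longstanding_diabetes_col: str = "diabetes_10y_untreated",
    neuro_col: str = "neuro_disorder",
) -> np.ndarray:
    """Reference-group membership from cohort covariates.

    Healthy or at risk of heart failure (stage 0/A), excluding participants
    with diabetes diagnosed >= 10 years ago without dietary treatment and
    participants with degenerative or structural neurological disorders.
    """
    stage = covariates[stage_col].astype(str).str.upper()
    mask = stage.isin([s.upper() for s in healthy_stages])
    if longstanding_diabetes_col in covariates:
        mask &= ~covariates[longstanding_diabetes_col].astype(bool)
    if neuro_col in covariates:
        mask &= ~covariates[neuro_col].astype(bool)
    return mask.to_numpy()


def reference_group_size(
    analysis_n: int, exclusion_counts: dict[str, int]
) -> int:
    """Sample-flow arithmetic: analysis sample minus the exclusion counts.

    The exclusions are disjoint groups (heart-failure stages B and C/D,
    long-standing untreated diabetes, neurological disorders); the remainder
    is the reference-group size.
    """
    n = analysis_n - sum(exclusion_counts.values())
    if n < 0:
        raise ValueError("exclusions exceed the analysis sample")
    return n
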