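"""Affine cross-compartment calibration of aggregate expression profiles.

Two renal compartments hybridised and normalised separately can differ by a
systematic affine shift (a difference in base expression plus a difference
in dynamic range).  The calibration estimates that shift by sorting both
aggregate profiles by one compartment's expression level, fitting an
ordinary-least-squares line to each sorted profile against the shared rank
abscissa, and combining the two fitted lines into an adjustment map

    slope     = slope_glom / slope_tub      (dynamic-range ratio)
    intercept = intercept_glom - intercept_tub   (base-expression offset)

The procedure is run twice — once sorted by each compartment — and the two
adjustment maps are averaged componentwise into the final map, which is then
applied to the tubulointerstitial profile before subtraction.

The abscissa is the shared 1-based rank after sorting.  Absolute fitted
slopes depend on that choice of x-units, but the two derived adjustment
quantities (slope ratio and intercept difference) are invariant to any
common positive rescaling of the abscissa, so the calibration itself is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "LinearMap",
    "CalibrationPass",
    "CalibrationResult",
    "aggregate_profile",
    "sorted_line_fit",
    "adjustment_factors",
    "symmetric_calibration",
    "apply_map",
]


@dataclass(frozen=True)
class LinearMap:
    """An affine map v -> slope * v + intercept on the log2 scale."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError(f"non-finite linear map: {self}")

    def __call__(self, x):
        return self.slope * x + self.intercept

    def inverted(self) -> "LinearMap":
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a linear map with zero slope")
        return LinearMap(slope=1.0 / self.slope, intercept=-self.intercept / self.slope)


@dataclass(frozen=True)
class CalibrationPass:
    """Fits and adjustment from one sort order."""

    fit_glom: LinearMap
    fit_tub: LinearMap
    adjustment: LinearMap


@dataclass(frozen=True)
class CalibrationResult:
    """Both symmetric passes plus their componentwise-mean final map."""

    pass1: CalibrationPass  # sorted by tubulointerstitium
    pass2: CalibrationPass  # sorted by glomerulus
    final_map: LinearMap


def aggregate_profile(matrix: ExpressionMatrix) -> pd.Series:
    """Per-probeset arithmetic mean across all samples of one compartment."""
    if matrix.shape[1] < 1:
        raise ValueError("cannot aggregate a matrix with no samples")
    profile = matrix.data.mean(axis=1)
    profile.name = matrix.compartment_label
    return profile


def _check_shared_index(profile_glom: pd.Series, profile_tub: pd.Series) -> None:
    if set(profile_glom.index) != set(profile_tub.index):
        diff = set(profile_glom.index) ^ set(profile_tub.index)
        raise ValueError(f"profiles cover different probesets; symmetric difference: {sorted(diff)[:10]}")


def _ols(x: np.ndarray, y: np.ndarray) -> LinearMap:
    fit = stats.linregress(x, y)
    return LinearMap(slope=float(fit.slope), intercept=float(fit.intercept))


def sorted_line_fit(
    profile_glom: pd.Series,
    profile_tub: pd.Series,
    sort_by: Literal["tub", "glom"],
) -> tuple[LinearMap, LinearMap]:
    """Reorder both profiles by ascending value of one compartment and fit an
    OLS line to each against the shared 1-based rank.

    Ties in the sort key are broken by probeset ID (stable, deterministic).
    Returns ``(fit_glom, fit_tub)``.
    """
    _check_shared_index(profile_glom, profile_tub)
    if len(profile_glom) < 2:
        raise ValueError("sorted line fit needs at least 2 probesets")
    if sort_by not in ("tub", "glom"):
        raise ValueError(f"sort_by must be 'tub' or 'glom', got {sort_by!r}")

    df = pd.DataFrame({"glom": profile_glom, "tub": profile_tub.reindex(profile_glom.index)})
    key = "tub" if sort_by == "tub" else "glom"
    # sort_index first, then a stable sort on the key -> ties broken by ID
    df = df.sort_index(kind="mergesort").sort_values(key, kind="mergesort")
    x = np.arange(1, len(df) + 1, dtype=float)
    return _ols(x, df["glom"].to_numpy()), _ols(x, df["tub"].to_numpy())


def adjustment_factors(fit_glom: LinearMap, fit_tub: LinearMap) -> LinearMap:
    """Adjustment map calibrating the tubulointerstitial profile onto the
    glomerular one: slope ratio and intercept difference of the two fits."""
    if fit_tub.slope == 0:
        raise ZeroDivisionError("tubulointerstitial fit has zero slope; adjustment undefined")
    return LinearMap(
        slope=fit_glom.slope / fit_tub.slope,
        intercept=fit_glom.intercept - fit_tub.intercept,
    )


def symmetric_calibration(profile_glom: pd.Series, profile_tub: pd.Series) -> CalibrationResult:
    """Run the sorted-line-fit calibration in both sort orders and average
    the two adjustment maps componentwise into the final map."""
    fits1 = sorted_line_fit(profile_glom, profile_tub, sort_by="tub")
    fits2 = sorted_line_fit(profile_glom, profile_tub, sort_by="glom")
    pass1 = CalibrationPass(*fits1, adjustment=adjustment_factors(*fits1))
    pass2 = CalibrationPass(*fits2, adjustment=adjustment_factors(*fits2))
    final = LinearMap(
        slope=(pass1.adjustment.slope + pass2.adjustment.slope) / 2.0,
        intercept=(pass1.adjustment.intercept + pass2.adjustment.intercept) / 2.0,
    )
    return CalibrationResult(pass1=pass1, pass2=pass2, final_map=final)


def apply_map(linear_map: LinearMap, profile: pd.Series) -> pd.Series:
    """Apply an affine map elementwise; probeset order is preserved."""
    return linear_map.slope * profile + linear_map.intercept
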