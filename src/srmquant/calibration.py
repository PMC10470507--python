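"""Matrix-matched standard-addition calibration.

Quantification of trace analytes in seawater or culture media suffers matrix
effects (ion suppression), so calibration curves are built by spiking known
amounts of authentic standard into a QC pool of the very samples being
measured, per matrix grouping. The x-intercept magnitude of the fitted line
estimates the pool's endogenous amount; the slope converts sample peak areas
to on-column amounts.

Thiamin peaks may additionally be normalized to the co-eluting 13C-labelled
heavy internal standard -- but only when doing so actually reduces replicate
variability on the QC pool, which is decided empirically here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidCurveError, InvalidDesignError, InvalidInputError

__all__ = [
    "CalCurve",
    "NormalizationDecision",
    "AmountResult",
    "decide_is_normalization",
    "fit_standard_addition",
    "response_to_amount",
]


@dataclass(frozen=True)
class CalCurve:
    """Fitted standard-addition line for one compound in one matrix group."""

    compound: str
    matrix_group: str
    slope: float            # response units per fmol
    intercept: float        # response units
    r_squared: float
    residual_sd: float
    endogenous_fmol: float  # intercept / slope, clamped at 0
    used_is_normalization: bool = False
    valid: bool = True


@dataclass(frozen=True)
class NormalizationDecision:
    """Whether dividing by the internal-standard area reduces QC-pool RSD."""

    compound: str
    rsd_raw: float
    rsd_normalized: float
    normalize: bool


def _rsd(values: np.ndarray) -> float:
    m = float(np.mean(values))
    if m == 0:
        return math.inf
    return float(np.std(values, ddof=1)) / abs(m)


def decide_is_normalization(
    qc_replicate_areas: Sequence[float],
    qc_replicate_is_areas: Sequence[float],
    compound: str = "",
) -> NormalizationDecision:
    """Normalize to the heavy internal standard only if it reduces variability.

    Compares the relative standard deviation of raw QC-pool replicate areas
    with that of area/IS-area ratios; normalization is adopted only when the
    ratio RSD is strictly smaller (a 1e-9 relative guard keeps the
    mathematically-equal constant-divisor case from flipping on rounding).
    With fewer than 3 replicates no decision is possible and normalization is
    declined with a warning.
    """
    areas = np.asarray(qc_replicate_areas, dtype=float)
    is_areas = np.asarray(qc_replicate_is_areas, dtype=float)
    if areas.shape != is_areas.shape:
        raise InvalidInputError("analyte and IS replicate lists must align")
    if areas.size < 3:
        warnings.warn(
            f"only {areas.size} QC replicates; defaulting to no IS normalization",
            stacklevel=2,
        )
        return NormalizationDecision(compound, math.nan, math.nan, False)
    rsd_raw = _rsd(areas)
    rsd_norm = _rsd(areas / is_areas)
    normalize = rsd_norm < rsd_raw * (1.0 - 1e-9)
    return NormalizationDecision(compound, rsd_raw, rsd_norm, normalize)


def fit_standard_addition(
    added_fmol: Sequence[float],
    responses: Sequence[float],
    compound: str = "",
    matrix_group: str = "",
    used_is_normalization: bool = False,
    weighting: str = "none",
) -> CalCurve:
    """Ordinary least squares of response on added standard amount.

    Duplicate injections enter as individual points. Requires at least three
    distinct addition levels including zero. The endogenous amount of the
    calibration matrix is ``intercept / slope`` (x-intercept magnitude),
    clamped at zero; a non-positive slope flags the curve invalid and
    downstream quantification refuses it. ``weighting='1/x'`` applies inverse
    amount weights (zero-level points get the smallest non-zero weight).
    """
    x = np.asarray(added_fmol, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("added_fmol and responses must align")
    levels = np.unique(x)
    if levels.size < 3:
        raise InvalidDesignError("need >=3 distinct addition levels")
    if 0.0 not in levels:
        raise InvalidDesignError("addition levels must include 0")

    if weighting == "1/x":
        w = 1.0 / np.where(x > 0, x, np.min(x[x > 0]))
        slope, intercept = _wls(x, y, w)
        fitted = intercept + slope * x
        ss_res = float(np.sum(w * (y - fitted) ** 2) / np.mean(w))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    elif weighting == "none":
        with np.errstate(invalid="ignore"):
            fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2 if np.isfinite(fit.rvalue) else math.nan
        fitted = intercept + slope * x
        ss_res = float(np.sum((y - fitted) ** 2))
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    dof = x.size - 2
    residual_sd = math.sqrt(ss_res / dof) if dof > 0 else math.nan
    valid = slope > 0
    endogenous = max(intercept / slope, 0.0) if valid else math.nan
    return CalCurve(
        compound=compound,
        matrix_group=matrix_group,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        residual_sd=residual_sd,
        endogenous_fmol=endogenous,
        used_is_normalization=used_is_normalization,
        valid=valid,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = np.sum(w)
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    slope = float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))
    return slope, float(ym - slope * xm)


class AmountResult(NamedTuple):
    """On-column amount from one response, with a below-blank flag."""

    fmol: float
    below_blank: bool


def response_to_amount(
    response: float, curve: CalCurve, blank_response: float = 0.0
) -> AmountResult:
    """Convert a summed peak area (response) to an on-column amount.

    Default (slope-only) mode: ``fmol = response / slope``; the QC pool's
    endogenous level is a property of the pool, not of the sample, so it is
    not subtracted. Passing ``blank_response`` switches to blank-subtraction
    mode ``(response - blank) / slope``. Results at or below zero clamp to 0
    and are flagged below-blank.
    """
    if not curve.valid:
        raise InvalidCurveError(
            f"calibration curve for {curve.compound or '?'} is flagged invalid"
        )
    raw = (response - blank_response) / curve.slope
    return AmountResult(fmol=max(raw, 0.0), below_blank=raw <= 0.0)
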