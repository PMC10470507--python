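"""Peak integration for SRM chromatograms.

A triple-quadrupole instrument run in selected-reaction-monitoring mode records,
for every monitored precursor->fragment transition, an intensity-versus-time
trace. This module turns those raw traces into baseline-corrected peak areas,
estimates signal-to-noise, picks the quantifier transition for each compound,
and sums areas over the chosen fragments -- the "summed peak area" that feeds
calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidWindowError

__all__ = [
    "TraceSet",
    "IntegrationWindow",
    "PeakArea",
    "integrate_peak",
    "integrate_all",
    "signal_to_noise",
    "select_quantifier_transitions",
    "summed_area",
]

#: relative tolerance for "uniform grid" validation
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class TraceSet:
    """Per-transition intensity traces for one compound in one injection.

    All fragment traces share a single strictly increasing, uniform time grid
    (minutes). ``intensities[k]`` is the trace of the k-th monitored fragment.
    """

    injection_id: str
    compound: str
    time: np.ndarray
    intensities: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", t)
        if t.ndim != 1 or t.size < 2:
            raise InvalidInputError("time grid needs at least two points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidInputError("time grid must be strictly increasing")
        if np.max(dt) - np.min(dt) > _GRID_RTOL * np.mean(dt):
            raise InvalidInputError("time grid must be uniform")
        ys = tuple(np.asarray(y, dtype=float) for y in self.intensities)
        if not ys:
            raise InvalidInputError("at least one fragment trace required")
        for y in ys:
            if y.shape != t.shape:
                raise InvalidInputError("every trace must share the time grid")
        object.__setattr__(self, "intensities", ys)

    @property
    def n_fragments(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class IntegrationWindow:
    """Retention-time window around the expected peak apex (minutes)."""

    center: float
    half_width: float = 0.2

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise InvalidInputError("half_width must be positive")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass
class PeakArea:
    """One integrated transition: area in intensity*minutes plus apex metadata."""

    injection_id: str
    compound: str
    fragment_index: int
    area: float
    apex_time: float
    apex_intensity: float
    snr: float = math.nan


def _window_mask(trace: TraceSet, window: IntegrationWindow) -> np.ndarray:
    t = trace.time
    if window.lo < t[0] or window.hi > t[-1]:
        raise InvalidWindowError(
            f"window [{window.lo:.3f}, {window.hi:.3f}] min outside trace span "
            f"[{t[0]:.3f}, {t[-1]:.3f}] min"
        )
    mask = (t >= window.lo) & (t <= window.hi)
    if mask.sum() < 3:
        raise InvalidWindowError("window holds fewer than 3 sample points")
    return mask


def _baseline_corrected(trace: TraceSet, window: IntegrationWindow, fragment_index: int):
    """Return (t_win, residual) after subtracting the edge-to-edge linear baseline."""
    mask = _window_mask(trace, window)
    t = trace.time[mask]
    y = trace.intensities[fragment_index][mask]
    # linear baseline interpolated between the first and last in-window points
    baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    return t, y - baseline


def integrate_peak(
    trace: TraceSet, window: IntegrationWindow, fragment_index: int = 0
) -> PeakArea:
    """Integrate one fragment transition over the window.

    A linear baseline interpolated between the window-edge intensities is
    subtracted; the residual is integrated by the trapezoidal rule. A negative
    residual integral clamps to zero so downstream amounts stay non-negative.
    The apex is the maximum of the baseline-corrected signal.
    """
    t, resid = _baseline_corrected(trace, window, fragment_index)
    area = float(np.trapezoid(resid, t))
    area = max(area, 0.0)
    i = int(np.argmax(resid))
    return PeakArea(
        injection_id=trace.injection_id,
        compound=trace.compound,
        fragment_index=fragment_index,
        area=area,
        apex_time=float(t[i]),
        apex_intensity=float(resid[i]),
    )


def integrate_all(
    trace: TraceSet, window: IntegrationWindow, with_snr: bool = False
) -> list[PeakArea]:
    """Integrate every fragment of a trace set; optionally attach S/N."""
    out = []
    for k in range(trace.n_fragments):
        pa = integrate_peak(trace, window, k)
        if with_snr:
            pa.snr = signal_to_noise(trace, window, k)
        out.append(pa)
    return out


def signal_to_noise(
    trace: TraceSet, window: IntegrationWindow, fragment_index: int = 0
) -> float:
    """Apex-over-noise S/N with a robust (MAD-based) noise estimate.

    Noise is estimated from points outside the window: 1.4826 x the median
    absolute deviation of out-of-window intensities about their median. The
    numerator is the baseline-corrected apex inside the window. When the noise
    estimate is exactly zero (synthetic noise-free data) returns ``inf``.
    """
    mask = _window_mask(trace, window)
    outside = trace.intensities[fragment_index][~mask]
    if outside.size < 20:
        raise InvalidInputError("need >=20 points outside the window for a noise estimate")
    resid_out = outside - np.median(outside)
    noise = 1.4826 * float(np.median(np.abs(resid_out)))
    _, resid_in = _baseline_corrected(trace, window, fragment_index)
    apex = float(np.max(resid_in))
    if noise == 0.0:
        return math.inf
    return apex / noise


def select_quantifier_transitions(
    cal_areas: pd.DataFrame, blank_areas: pd.DataFrame | None
) -> dict[str, int]:
    """Choose the quantifier fragment per compound from calibration + blank data.

    ``cal_areas`` needs columns ``compound, fragment_index, level_fmol, area,
    snr`` (one row per calibration injection x fragment); ``blank_areas`` needs
    ``compound, fragment_index, area``. Each fragment is scored as

        score = mean(snr over calibration injections) / (1 + interference)

    with interference = mean blank area / mean area at the lowest non-zero
    calibration level. The top-scoring fragment becomes the quantifier; ties
    break deterministically toward the lower fragment index. All fragments
    remain available for identity checks downstream. Without blanks the score
    degrades to S/N only (a warning is emitted).
    """
    required = {"compound", "fragment_index", "level_fmol", "area", "snr"}
    if not required.issubset(cal_areas.columns):
        raise InvalidInputError(f"cal_areas must have columns {sorted(required)}")
    have_blanks = blank_areas is not None and len(blank_areas) > 0
    if not have_blanks:
        warnings.warn(
            "no blank injections provided; quantifier selection falls back to "
            "S/N-only scoring",
            stacklevel=2,
        )

    chosen: dict[str, int] = {}
    for compound, grp in cal_areas.groupby("compound", sort=True):
        nonzero = grp[grp["level_fmol"] > 0]
        low_level = nonzero["level_fmol"].min() if len(nonzero) else math.nan
        scores: list[tuple[float, int]] = []
        for frag, fgrp in grp.groupby("fragment_index", sort=True):
            snr = fgrp["snr"].replace(math.inf, np.nan)
            mean_snr = float(snr.mean()) if snr.notna().any() else math.inf
            interference = 0.0
            if have_blanks and len(nonzero):
                b = blank_areas[
                    (blank_areas["compound"] == compound)
                    & (blank_areas["fragment_index"] == frag)
                ]["area"]
                low = fgrp[fgrp["level_fmol"] == low_level]["area"].mean()
                if len(b) and low > 0:
                    interference = float(b.mean()) / float(low)
            scores.append((mean_snr / (1.0 + interference), int(frag)))
        # highest score wins; ties -> lowest fragment_index
        scores.sort(key=lambda s: (-s[0], s[1]))
        chosen[str(compound)] = scores[0][1]
    return chosen


def summed_area(areas: Sequence[PeakArea]) -> float:
    """Sum peak areas over the chosen fragments of a single injection/compound."""
    if not areas:
        raise InvalidInputError("no areas to sum")
    keys = {(a.injection_id, a.compound) for a in areas}
    if len(keys) > 1:
        raise InvalidInputError(f"areas mix injections/compounds: {sorted(keys)}")
    return float(sum(a.area for a in areas))
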