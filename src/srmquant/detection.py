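"""Detection limits, sub-LOQ acceptance, and spike recovery.

What may be reported from a targeted assay is governed by blank-derived
limits of detection and quantification, a four-criterion acceptance rule for
peaks falling between LOD and LOQ, and percent-recovery estimates from
spiked/unspiked sample pairs that correct all reported concentrations for
extraction losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .chromatography import PeakArea
from .errors import InvalidInputError, MissingStandardError

__all__ = [
    "Thresholds",
    "SubLoqEvaluation",
    "RecoveryEstimate",
    "DetectionStatus",
    "compute_lod_loq",
    "evaluate_subloq",
    "percent_recovery",
    "classify_detection",
]

#: fragments whose areas differ by less than this relative amount are treated
#: as order-compatible in the intensity-order criterion (ties are logged by
#: callers that care)
ORDER_TIE_REL = 0.05

#: recovery outside these bounds (percent) is flagged suspect
RECOVERY_SUSPECT_BOUNDS = (10.0, 150.0)


class DetectionStatus(IntEnum):
    """Reportability of a measured concentration, ordered by confidence."""

    nd = 0               # below limit of detection
    nq = 1               # between LOD and LOQ, failed sub-LOQ acceptance
    reported_subloq = 2  # between LOD and LOQ, passed all four criteria
    quantified = 3       # at or above limit of quantification

    def __str__(self) -> str:  # render as the table string, not the number
        return self.name


@dataclass(frozen=True)
class Thresholds:
    """Blank-derived LOD/LOQ for one compound in one matrix group.

    ``lod``/``loq`` are expressed in in-sample concentration units when a
    volume chain is supplied to :func:`compute_lod_loq`, otherwise in the
    blank amount units. ``blank_mean``/``blank_sd`` stay in amount units.
    """

    compound: str
    matrix_group: str
    lod: float
    loq: float
    blank_mean: float
    blank_sd: float
    n_blanks: int

    def __post_init__(self) -> None:
        if self.n_blanks < 3:
            raise InvalidInputError("thresholds require >=3 blank determinations")
        if not (0.0 <= self.lod <= self.loq):
            raise InvalidInputError("need 0 <= lod <= loq")


def compute_lod_loq(
    blank_amounts: Sequence[float],
    chain: "VolumeChain | None" = None,
    compound: str = "",
    matrix_group: str = "",
) -> Thresholds:
    """Blank-based LOD/LOQ: mean + 3*sd and mean + 10*sd of blank amounts.

    ``blank_amounts`` are per-blank-determination amounts (fmol on column).
    With a volume chain the limits are converted to in-sample concentration
    (pM); without one they remain on the amount scale. Negative formula
    outcomes (possible when the blank mean is negative) clamp to zero.
    """
    x = np.asarray(blank_amounts, dtype=float)
    if x.size < 3:
        raise InvalidInputError("need >=3 blank determinations")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    lod = max(mean + 3.0 * sd, 0.0)
    loq = max(mean + 10.0 * sd, 0.0)
    if chain is not None:
        from .quantify import on_column_to_sample_conc  # deferred: avoids module cycle

        lod = on_column_to_sample_conc(lod, chain)
        loq = on_column_to_sample_conc(loq, chain)
    return Thresholds(
        compound=compound,
        matrix_group=matrix_group,
        lod=lod,
        loq=loq,
        blank_mean=mean,
        blank_sd=sd,
        n_blanks=int(x.size),
    )


@dataclass(frozen=True)
class SubLoqEvaluation:
    """Outcome of the four-criterion acceptance rule for a sub-LOQ peak.

    accepted is the conjunction of all four flags: (i) retention time matches
    the authentic standard within tolerance, (ii) at least two daughter
    fragments show co-occurring peaks, (iii) fragment intensities rank in the
    same order as the standard, (iv) the summed area is at least twice the
    average blank area in the window.
    """

    rt_match: bool
    two_fragments_cooccur: bool
    intensity_order_match: bool
    area_exceeds_2x_blank: bool

    @property
    def accepted(self) -> bool:
        return (
            self.rt_match
            and self.two_fragments_cooccur
            and self.intensity_order_match
            and self.area_exceeds_2x_blank
        )


def evaluate_subloq(
    candidate: Sequence[PeakArea],
    standard: Sequence[PeakArea],
    blank_mean_area: float,
    rt_tolerance: float = 0.2,
) -> SubLoqEvaluation:
    """Apply the four sub-LOQ acceptance criteria to one injection's peaks.

    ``candidate`` holds the injection's per-fragment areas for one compound,
    ``standard`` the authentic standard's per-fragment areas (>=2 fragments),
    matched by ``fragment_index``. The retention-time criterion anchors on the
    standard's most intense fragment.
    """
    std = {p.fragment_index: p for p in standard}
    if len(std) < 2:
        raise MissingStandardError("authentic standard must provide >=2 fragments")
    cand = {p.fragment_index: p for p in candidate}

    # (i) retention time within tolerance of the standard's top fragment
    anchor = min(std, key=lambda k: (-std[k].area, k))
    rt_match = (
        anchor in cand
        and abs(cand[anchor].apex_time - std[anchor].apex_time) <= rt_tolerance
    )

    # (ii) >=2 fragments present with co-occurring apexes
    present = [p for p in cand.values() if p.area > 0]
    two_cooccur = any(
        abs(a.apex_time - b.apex_time) <= rt_tolerance
        for i, a in enumerate(present)
        for b in present[i + 1 :]
    )

    # (iii) fragment areas rank in the standard's order; near-equal candidate
    # areas (within ORDER_TIE_REL relative) are order-compatible
    order = sorted(std, key=lambda k: (-std[k].area, k))
    order_match = True
    for hi, lo in zip(order, order[1:]):
        a = cand[hi].area if hi in cand else 0.0
        b = cand[lo].area if lo in cand else 0.0
        if a < b and (b - a) > ORDER_TIE_REL * max(a, b, 1e-300):
            order_match = False
            break

    # (iv) summed candidate area at least twice the mean blank area
    total = sum(p.area for p in cand.values())
    area_ok = total >= 2.0 * blank_mean_area

    return SubLoqEvaluation(
        rt_match=bool(rt_match),
        two_fragments_cooccur=bool(two_cooccur),
        intensity_order_match=bool(order_match),
        area_exceeds_2x_blank=bool(area_ok),
    )


@dataclass(frozen=True)
class RecoveryEstimate:
    """Percent recovery from a spiked/unspiked sample pair."""

    compound: str
    matrix_group: str
    spike_amount: float
    endogenous: float
    measured_spiked: float
    percent_recovery: float
    suspect: bool
    asserted: bool = False  # True when no spike pair existed and a literature
    #                         rate (e.g. 50% for FAMP) was asserted instead


def percent_recovery(
    measured_spiked: float,
    endogenous: float,
    spike_amount: float,
    compound: str = "",
    matrix_group: str = "",
) -> RecoveryEstimate:
    """Recovery = 100 * (measured_spiked - endogenous) / spike_amount.

    The endogenous concentration measured in the unspiked sample is subtracted
    before dividing by the known spike. Values outside [10%, 150%] are flagged
    suspect but still returned.
    """
    if spike_amount <= 0:
        raise InvalidInputError("spike_amount must be positive")
    pct = 100.0 * (measured_spiked - endogenous) / spike_amount
    lo, hi = RECOVERY_SUSPECT_BOUNDS
    return RecoveryEstimate(
        compound=compound,
        matrix_group=matrix_group,
        spike_amount=spike_amount,
        endogenous=endogenous,
        measured_spiked=measured_spiked,
        percent_recovery=pct,
        suspect=not (lo <= pct <= hi),
    )


def assert_recovery(
    percent: float, compound: str = "", matrix_group: str = ""
) -> RecoveryEstimate:
    """Assert a recovery rate without a spike pair (flagged ``asserted``)."""
    if percent <= 0:
        raise InvalidInputError("asserted recovery must be positive")
    lo, hi = RECOVERY_SUSPECT_BOUNDS
    return RecoveryEstimate(
        compound=compound,
        matrix_group=matrix_group,
        spike_amount=math.nan,
        endogenous=math.nan,
        measured_spiked=math.nan,
        percent_recovery=percent,
        suspect=not (lo <= percent <= hi),
        asserted=True,
    )


def classify_detection(
    conc: float,
    thresholds: Thresholds,
    subloq: SubLoqEvaluation | None = None,
) -> DetectionStatus:
    """Classify a concentration against LOD/LOQ and the sub-LOQ rule.

    >= LOQ: quantified. In [LOD, LOQ): reported_subloq when the four-criterion
    evaluation accepted the peak, else nq. < LOD: nd.
    """
    if conc >= thresholds.loq:
        return DetectionStatus.quantified
    if conc >= thresholds.lod:
        if subloq is not None and subloq.accepted:
            return DetectionStatus.reported_subloq
        return DetectionStatus.nq
    return DetectionStatus.nd
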