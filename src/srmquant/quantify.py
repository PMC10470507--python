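"""On-column amounts to recovery-corrected in-sample concentrations.

The volume chain (sample volume -> SPE -> resuspension -> injection) inverts
the sampling arithmetic: an on-column amount maps back to an in-sample
concentration, which is then corrected for the percent recovery of the
extraction method and classified against the detection thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalCurve, response_to_amount
from .detection import DetectionStatus, SubLoqEvaluation, Thresholds, classify_detection
from .errors import InvalidInputError

__all__ = [
    "VolumeChain",
    "QuantResult",
    "on_column_to_sample_conc",
    "apply_recovery",
    "quantify_sample",
]


@dataclass(frozen=True)
class VolumeChain:
    """Volumes linking the original sample to what lands on column."""

    sample_volume_ml: float
    resuspension_volume_ul: float
    injection_volume_ul: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.sample_volume_ml,
            self.resuspension_volume_ul,
            self.injection_volume_ul,
            self.dilution_factor,
        ) <= 0:
            raise InvalidInputError("all volume-chain entries must be positive")
        if self.injection_volume_ul > self.resuspension_volume_ul:
            raise InvalidInputError("cannot inject more than the resuspension volume")


def on_column_to_sample_conc(fmol: float, chain: VolumeChain) -> float:
    """In-sample concentration (pM) from an on-column amount (fmol).

        conc[pM] = fmol * (resuspension / injection) * dilution / volume[mL]

    (fmol per mL is exactly pM). This is the inverse of the extraction
    sampling chain at 100% extraction efficiency; recovery correction accounts
    for the efficiency separately.
    """
    if fmol < 0:
        raise InvalidInputError("fmol must be non-negative")
    return (
        fmol
        * (chain.resuspension_volume_ul / chain.injection_volume_ul)
        * chain.dilution_factor
        / chain.sample_volume_ml
    )


def apply_recovery(conc: float, recovery_percent: float) -> float:
    """Correct a concentration for percent recovery: conc * 100 / recovery."""
    if not (0.0 < recovery_percent <= 200.0):
        raise InvalidInputError("recovery_percent must lie in (0, 200]")
    return conc * 100.0 / recovery_percent


@dataclass
class QuantResult:
    """Final per-sample, per-compound quantification record."""

    sample_id: str
    compound: str
    on_column_fmol: float
    conc_uncorrected: float
    recovery_used: float
    conc_corrected: float
    status: DetectionStatus | None
    injection_replicates: int
    replicate_sd: float


def quantify_sample(
    sample_id: str,
    compound: str,
    injection_responses: Sequence[float],
    curve: CalCurve,
    chain: VolumeChain,
    recovery_percent: float = 100.0,
    thresholds: Thresholds | None = None,
    subloq: SubLoqEvaluation | None = None,
    classify_on_corrected: bool = True,
) -> QuantResult:
    """Assemble one sample's result from its replicate injection responses.

    Replicate injections are averaged on the amount scale (responses may be
    IS-normalized, so areas are not directly averageable), converted through
    the volume chain, recovery-corrected, and classified. ``replicate_sd`` is
    the sample standard deviation of the corrected per-injection
    concentrations (NaN with a single injection).
    """
    if not injection_responses:
        raise InvalidInputError("need at least one injection response")
    amounts = [response_to_amount(r, curve).fmol for r in injection_responses]
    concs = np.array([on_column_to_sample_conc(a, chain) for a in amounts])
    corrected = np.array([apply_recovery(c, recovery_percent) for c in concs])
    mean_fmol = float(np.mean(amounts))
    conc_unc = float(np.mean(concs))
    conc_cor = float(np.mean(corrected))
    rep_sd = float(np.std(corrected, ddof=1)) if corrected.size > 1 else math.nan
    status = None
    if thresholds is not None:
        basis = conc_cor if classify_on_corrected else conc_unc
        status = classify_detection(basis, thresholds, subloq)
    return QuantResult(
        sample_id=sample_id,
        compound=compound,
        on_column_fmol=mean_fmol,
        conc_uncorrected=conc_unc,
        recovery_used=recovery_percent,
        conc_corrected=conc_cor,
        status=status,
        injection_replicates=len(injection_responses),
        replicate_sd=rep_sd,
    )
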