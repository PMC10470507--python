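"""End-to-end composition: batch traces in, quantified concentrations out.

Glue that runs the full assay on a (simulated or loaded) batch: integrate
every transition in its retention-time window, pick quantifier transitions
against the blanks, decide internal-standard normalization on the QC pool,
fit the matrix-matched standard-addition curves, derive blank-based LOD/LOQ,
evaluate sub-LOQ candidates, and assemble recovery-corrected per-sample
results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .calibration import (
    CalCurve,
    NormalizationDecision,
    decide_is_normalization,
    fit_standard_addition,
    response_to_amount,
)
from .chromatography import (
    IntegrationWindow,
    PeakArea,
    integrate_all,
    select_quantifier_transitions,
)
from .detection import (
    Thresholds,
    compute_lod_loq,
    evaluate_subloq,
    percent_recovery,
)
from .errors import InvalidInputError
from .quantify import QuantResult, VolumeChain, quantify_sample
from .synthetic import Batch, ROLE_ANALYTE, ROLE_INTERNAL_STANDARD

__all__ = [
    "integrate_batch",
    "BatchCalibration",
    "calibrate_batch",
    "batch_thresholds",
    "quantify_batch",
    "measure_recovery",
]


def integrate_batch(batch: Batch, half_width: float = 0.2) -> pd.DataFrame:
    """Integrate every (injection, compound, fragment) of a batch.

    Windows are centered on each compound's panel retention time. Returns one
    row per transition with area, apex and S/N, joined with the ground-truth
    ledger columns (sample_id, sample_type, level_index, added_fmol).
    """
    specs = batch.panel_by_name()
    rows = []
    for tr in batch.traces:
        window = IntegrationWindow(specs[tr.compound].retention_time, half_width)
        for pa in integrate_all(tr, window, with_snr=True):
            rows.append(
                {
                    "injection_id": pa.injection_id,
                    "compound": pa.compound,
                    "fragment_index": pa.fragment_index,
                    "area": pa.area,
                    "apex_time": pa.apex_time,
                    "apex_intensity": pa.apex_intensity,
                    "snr": pa.snr,
                }
            )
    areas = pd.DataFrame(rows)
    key = ["injection_id", "compound"]
    meta = batch.ledger[key + ["sample_id", "sample_type", "level_index", "added_fmol"]]
    return areas.merge(meta, on=key, how="left", validate="many_to_one")


@dataclass
class BatchCalibration:
    """Everything needed to turn a summed area into an amount."""

    quantifiers: dict[str, int]
    curves: dict[str, CalCurve]
    normalization: dict[str, NormalizationDecision]
    is_compound: str | None
    matrix_group: str


def _injection_response(
    areas: pd.DataFrame,
    injection_id: str,
    compound: str,
    cal: "BatchCalibration",
) -> float:
    sel = areas[
        (areas["injection_id"] == injection_id)
        & (areas["compound"] == compound)
        & (areas["fragment_index"] == cal.quantifiers[compound])
    ]
    resp = float(sel["area"].sum())
    decision = cal.normalization.get(compound)
    if decision is not None and decision.normalize and cal.is_compound:
        is_sel = areas[
            (areas["injection_id"] == injection_id)
            & (areas["compound"] == cal.is_compound)
            & (areas["fragment_index"] == cal.quantifiers[cal.is_compound])
        ]
        is_area = float(is_sel["area"].sum())
        if is_area <= 0:
            raise InvalidInputError(
                f"internal-standard area is zero in injection {injection_id}"
            )
        resp /= is_area
    return resp


def calibrate_batch(
    batch: Batch, areas: pd.DataFrame, matrix_group: str = "batch"
) -> BatchCalibration:
    """Quantifier selection, IS-normalization decision, standard-addition fits."""
    analytes = [c.name for c in batch.panel if c.role == ROLE_ANALYTE]
    is_names = [c.name for c in batch.panel if c.role == ROLE_INTERNAL_STANDARD]
    is_compound = is_names[0] if is_names else None

    cal_rows = areas[areas["sample_type"] == "calibration"]
    blank_rows = areas[areas["sample_type"] == "medium_blank"]
    if cal_rows.empty:
        raise InvalidInputError("batch has no calibration injections")
    quantifiers = select_quantifier_transitions(
        cal_rows.rename(columns={"added_fmol": "level_fmol"})[
            ["compound", "fragment_index", "level_fmol", "area", "snr"]
        ],
        blank_rows[["compound", "fragment_index", "area"]] if len(blank_rows) else None,
    )
    for name in is_names:  # IS quantifier: most intense fragment by convention
        if name not in quantifiers:
            quantifiers[name] = 0

    # IS-normalization decision from unspiked QC-pool replicate injections
    normalization: dict[str, NormalizationDecision] = {}
    qc_rows = areas[areas["sample_type"] == "qc_pool"]
    if is_compound is not None and not qc_rows.empty:
        qc_injections = sorted(qc_rows["injection_id"].unique())
        if len(qc_injections) >= 3:
            is_areas = [
                float(
                    qc_rows[
                        (qc_rows["injection_id"] == inj)
                        & (qc_rows["compound"] == is_compound)
                        & (qc_rows["fragment_index"] == quantifiers[is_compound])
                    ]["area"].sum()
                )
                for inj in qc_injections
            ]
            for compound in analytes:
                raw = [
                    float(
                        qc_rows[
                            (qc_rows["injection_id"] == inj)
                            & (qc_rows["compound"] == compound)
                            & (qc_rows["fragment_index"] == quantifiers[compound])
                        ]["area"].sum()
                    )
                    for inj in qc_injections
                ]
                normalization[compound] = decide_is_normalization(
                    raw, is_areas, compound=compound
                )

    cal = BatchCalibration(
        quantifiers=quantifiers,
        curves={},
        normalization=normalization,
        is_compound=is_compound,
        matrix_group=matrix_group,
    )
    for compound in analytes:
        rows = cal_rows[cal_rows["compound"] == compound]
        added, resp = [], []
        for inj, grp in rows.groupby("injection_id", sort=True):
            added.append(float(grp["added_fmol"].iloc[0]))
            resp.append(_injection_response(areas, str(inj), compound, cal))
        decision = cal.normalization.get(compound)
        cal.curves[compound] = fit_standard_addition(
            added,
            resp,
            compound=compound,
            matrix_group=matrix_group,
            used_is_normalization=bool(decision and decision.normalize),
        )
    return cal


def batch_thresholds(
    batch: Batch,
    areas: pd.DataFrame,
    cal: BatchCalibration,
    chain: VolumeChain | None = None,
) -> dict[str, Thresholds]:
    """Blank-based LOD/LOQ per compound, on the in-sample concentration scale."""
    blanks = areas[areas["sample_type"] == "medium_blank"]
    if blanks.empty:
        raise InvalidInputError("batch has no blank injections")
    out = {}
    for compound, curve in cal.curves.items():
        if not curve.valid:
            continue
        amounts = [
            response_to_amount(
                _injection_response(areas, str(inj), compound, cal), curve
            ).fmol
            for inj in sorted(blanks["injection_id"].unique())
        ]
        out[compound] = compute_lod_loq(
            amounts, chain=chain, compound=compound, matrix_group=cal.matrix_group
        )
    return out


def measure_recovery(
    results_unspiked: Mapping[str, float],
    results_spiked: Mapping[str, float],
    spikes_pm: Mapping[str, float],
    matrix_group: str = "batch",
) -> dict[str, float]:
    """Percent recovery per compound from uncorrected spike-pair concentrations."""
    out = {}
    for compound, spike in spikes_pm.items():
        est = percent_recovery(
            results_spiked[compound],
            results_unspiked[compound],
            spike,
            compound=compound,
            matrix_group=matrix_group,
        )
        out[compound] = est.percent_recovery
    return out


def _standard_peakareas(
    areas: pd.DataFrame, compound: str
) -> list[PeakArea]:
    """Mean per-fragment areas/apexes of the top calibration level, as the
    authentic-standard reference for sub-LOQ identity checks."""
    cal = areas[(areas["sample_type"] == "calibration") & (areas["compound"] == compound)]
    top = cal[cal["added_fmol"] == cal["added_fmol"].max()]
    out = []
    for frag, grp in top.groupby("fragment_index", sort=True):
        out.append(
            PeakArea(
                injection_id="standard",
                compound=compound,
                fragment_index=int(frag),
                area=float(grp["area"].mean()),
                apex_time=float(grp["apex_time"].mean()),
                apex_intensity=float(grp["apex_intensity"].mean()),
            )
        )
    return out


def quantify_batch(
    batch: Batch,
    areas: pd.DataFrame | None = None,
    recoveries: Mapping[str, float] | None = None,
    matrix_group: str = "batch",
    classify: bool = True,
    classify_on_corrected: bool = True,
) -> tuple[list[QuantResult], BatchCalibration]:
    """Quantify every non-calibration, non-blank, non-pool sample in a batch.

    ``recoveries`` maps compound to percent recovery (default 100%). Detection
    status is classified against blank-derived thresholds computed per
    sample's own volume chain; sub-LOQ candidates are evaluated against the
    top calibration level as the authentic standard.
    """
    if areas is None:
        areas = integrate_batch(batch)
    cal = calibrate_batch(batch, areas, matrix_group=matrix_group)
    recoveries = dict(recoveries or {})
    analytes = [c.name for c in batch.panel if c.role == ROLE_ANALYTE]
    blanks = areas[areas["sample_type"] == "medium_blank"]

    results: list[QuantResult] = []
    for sample in batch.design.samples:
        if sample.sample_type in ("qc_pool", "calibration", "medium_blank"):
            continue
        chain = VolumeChain(
            sample_volume_ml=sample.sample_volume_ml,
            resuspension_volume_ul=sample.resuspension_volume_ul,
            injection_volume_ul=batch.design.injection_volume_ul,
        )
        srows = areas[areas["sample_id"] == sample.sample_id]
        injections = sorted(srows["injection_id"].unique())
        for compound in analytes:
            curve = cal.curves[compound]
            if not curve.valid:
                continue
            responses = [
                _injection_response(areas, str(inj), compound, cal)
                for inj in injections
            ]
            thresholds = None
            subloq = None
            if classify and len(blanks):
                blank_amounts = [
                    response_to_amount(
                        _injection_response(areas, str(inj), compound, cal), curve
                    ).fmol
                    for inj in sorted(blanks["injection_id"].unique())
                ]
                if len(blank_amounts) >= 3:
                    thresholds = compute_lod_loq(
                        blank_amounts, chain=chain, compound=compound,
                        matrix_group=matrix_group,
                    )
                    standard = _standard_peakareas(areas, compound)
                    first = srows[
                        (srows["injection_id"] == injections[0])
                        & (srows["compound"] == compound)
                    ]
                    candidate = [
                        PeakArea(
                            injection_id=str(injections[0]),
                            compound=compound,
                            fragment_index=int(r.fragment_index),
                            area=float(r.area),
                            apex_time=float(r.apex_time),
                            apex_intensity=float(r.apex_intensity),
                        )
                        for r in first.itertuples()
                    ]
                    blank_mean = float(
                        blanks[blanks["compound"] == compound]
                        .groupby("injection_id")["area"]
                        .sum()
                        .mean()
                    )
                    subloq = evaluate_subloq(candidate, standard, blank_mean)
            results.append(
                quantify_sample(
                    sample.sample_id,
                    compound,
                    responses,
                    curve,
                    chain,
                    recovery_percent=recoveries.get(compound, 100.0),
                    thresholds=thresholds,
                    subloq=subloq,
                    classify_on_corrected=classify_on_corrected,
                )
            )
    return results, cal
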