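"""Tabular and mzML I/O.

Traces, ground-truth ledgers, peak-area tables, calibration summaries and
reports all travel as plain CSV (long format for traces); batch designs are
YAML or JSON documents. SRM chromatograms stored in mzML are read through
pyteomics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalCurve
from .chromatography import TraceSet
from .errors import InvalidInputError
from .quantify import QuantResult
from .synthetic import Batch, BatchDesign, CompoundSpec, SampleDesign

__all__ = [
    "traces_to_frame",
    "tracesets_from_frame",
    "write_traces_csv",
    "read_traces_csv",
    "write_ledger_csv",
    "panel_to_frame",
    "panel_from_frame",
    "write_panel_csv",
    "read_panel_csv",
    "read_batch_design",
    "curves_to_frame",
    "results_to_frame",
    "read_mzml_chromatograms",
]

TRACE_COLUMNS = ["injection_id", "compound", "fragment_index", "time_min", "intensity"]


def traces_to_frame(traces: Iterable[TraceSet]) -> pd.DataFrame:
    """Long-format trace table: one row per (injection, compound, fragment, t)."""
    parts = []
    for tr in traces:
        for k, y in enumerate(tr.intensities):
            parts.append(
                pd.DataFrame(
                    {
                        "injection_id": tr.injection_id,
                        "compound": tr.compound,
                        "fragment_index": k,
                        "time_min": tr.time,
                        "intensity": y,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def tracesets_from_frame(frame: pd.DataFrame) -> list[TraceSet]:
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"trace table missing columns {sorted(missing)}")
    out = []
    for (inj, comp), grp in frame.groupby(["injection_id", "compound"], sort=True):
        frags = sorted(grp["fragment_index"].unique())
        first = grp[grp["fragment_index"] == frags[0]].sort_values("time_min")
        time = first["time_min"].to_numpy()
        ys = []
        for k in frags:
            g = grp[grp["fragment_index"] == k].sort_values("time_min")
            ys.append(g["intensity"].to_numpy())
        out.append(TraceSet(str(inj), str(comp), time, tuple(ys)))
    return out


def write_traces_csv(traces: Iterable[TraceSet], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.12g")


def read_traces_csv(path: str | Path) -> list[TraceSet]:
    return tracesets_from_frame(pd.read_csv(path))


def write_ledger_csv(batch: Batch, path: str | Path) -> None:
    batch.ledger.to_csv(path, index=False, float_format="%.10g")


def panel_to_frame(panel: Sequence[CompoundSpec]) -> pd.DataFrame:
    rows = []
    for c in panel:
        for k, (mz, rel) in enumerate(zip(c.fragment_mzs, c.fragment_rel_intensities)):
            rows.append(
                {
                    "name": c.name,
                    "precursor_mz": c.precursor_mz,
                    "fragment_index": k,
                    "fragment_mz": mz,
                    "rel_intensity": rel,
                    "retention_time": c.retention_time,
                    "peak_sigma": c.peak_sigma,
                    "role": c.role,
                }
            )
    return pd.DataFrame(rows)


def panel_from_frame(frame: pd.DataFrame) -> tuple[CompoundSpec, ...]:
    specs = []
    for name, grp in frame.groupby("name", sort=False):
        grp = grp.sort_values("fragment_index")
        specs.append(
            CompoundSpec(
                name=str(name),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                fragment_mzs=tuple(grp["fragment_mz"]),
                fragment_rel_intensities=tuple(grp["rel_intensity"]),
                retention_time=float(grp["retention_time"].iloc[0]),
                peak_sigma=float(grp["peak_sigma"].iloc[0]),
                role=str(grp["role"].iloc[0]),
            )
        )
    return tuple(specs)


def write_panel_csv(panel: Sequence[CompoundSpec], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> tuple[CompoundSpec, ...]:
    return panel_from_frame(pd.read_csv(path))


def read_batch_design(path: str | Path) -> BatchDesign:
    """Build a BatchDesign from a YAML or JSON config document.

    Expected structure::

        samples:
          - sample_id: spent_A
            sample_type: spent_medium
            true_concentrations_pm: {FAMP: 57000}
            sample_volume_ml: 14
            extraction_efficiency: 0.5
            resuspension_volume_ul: 100
            spikes_pm: {B1_13C: 75}
        calibration_levels_fmol: {HET: [0, 5, 10, 50]}   # optional
        injections_per_level: 2
        noise_sd: 5.0
        seed: 17
    """
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    samples = tuple(SampleDesign(**s) for s in doc.pop("samples"))
    return BatchDesign(samples=samples, **doc)


def curves_to_frame(curves: Mapping[str, CalCurve] | Iterable[CalCurve]) -> pd.DataFrame:
    items = curves.values() if isinstance(curves, Mapping) else curves
    return pd.DataFrame(
        [
            {
                "compound": c.compound,
                "matrix_group": c.matrix_group,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "residual_sd": c.residual_sd,
                "endogenous_fmol": c.endogenous_fmol,
                "used_is_normalization": c.used_is_normalization,
                "valid": c.valid,
            }
            for c in items
        ]
    )


def results_to_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "compound": r.compound,
                "on_column_fmol": r.on_column_fmol,
                "conc_uncorrected_pM": r.conc_uncorrected,
                "recovery_used_percent": r.recovery_used,
                "conc_corrected_pM": r.conc_corrected,
                "status": str(r.status) if r.status is not None else "",
                "injection_replicates": r.injection_replicates,
                "replicate_sd_pM": r.replicate_sd,
            }
            for r in results
        ]
    )


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> tuple[np.ndarray | None, str | None, str | None]:
    """Decode one mzML <binaryDataArray>: (values, array kind, time unit)."""
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    kind = None
    unit = None
    for cv in elem.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":  # 32-bit float
            dtype = np.float32
        elif acc == "MS:1000574":  # zlib compression
            compressed = True
        elif acc == "MS:1000595":
            kind, unit = "time", cv.get("unitName")
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = elem.find(f"{_MZML_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return None, kind, unit
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64), kind, unit


def read_mzml_chromatograms(path: str | Path) -> list[TraceSet]:
    """Read SRM chromatograms from an mzML file into TraceSets.

    Minimal chromatogram-level mzML reader (64/32-bit float arrays, optional
    zlib compression). Each chromatogram becomes a single-fragment TraceSet
    whose compound field carries the chromatogram id (typically
    "SRM SIC Q1=... Q3=..."); mapping ids onto a compound panel is left to
    the caller. Times recorded in seconds are converted to minutes.
    """
    from lxml import etree

    out = []
    stem = Path(path).stem
    tree = etree.parse(str(path))
    for chrom in tree.iter(f"{_MZML_NS}chromatogram"):
        cid = chrom.get("id", "chromatogram")
        t = y = None
        for arr in chrom.iter(f"{_MZML_NS}binaryDataArray"):
            values, kind, unit = _decode_binary_array(arr)
            if values is None:
                continue
            if kind == "time":
                t = values / 60.0 if unit and "second" in unit else values
            elif kind == "intensity":
                y = values
        if t is None or y is None or t.size < 2:
            continue
        out.append(TraceSet(stem, str(cid), t, (y,)))
    return out
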