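"""Synthetic SRM batch generator with known ground truth.

Every downstream stage of the pipeline (integration, calibration, detection,
quantification, reporting) is verified by parameter recovery against batches
produced here: Gaussian peaks per fragment transition, additive baseline and
point noise, optional multiplicative amplitude jitter, duplicate injections,
matrix-matched calibration-spike series on a QC pool, spiked/unspiked recovery
pairs, and blanks.

The compound roster covers thiamin (vitamin B1), its pyrimidine vitamers
(HMP, AmMP, FAMP), the thiazole vitamers (cHET, HET) and a 13C-labelled heavy
B1 internal standard. The m/z and retention-time constants are invented
fixture values chosen only to be mutually distinct and physically plausible;
override them by building your own ``CompoundSpec`` panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import TraceSet
from .errors import InvalidInputError

__all__ = [
    "CompoundSpec",
    "SampleDesign",
    "BatchDesign",
    "Batch",
    "ROLE_ANALYTE",
    "ROLE_INTERNAL_STANDARD",
    "DEFAULT_LEVELS_FMOL",
    "HET_LEVELS_FMOL",
    "RESPONSE_GAIN",
    "RUN_MINUTES",
    "GRID_STEP_MINUTES",
    "make_default_panel",
    "simulate_extraction",
    "simulate_traces",
    "make_qc_pool",
    "simulate_batch",
]

ROLE_ANALYTE = "analyte"
ROLE_INTERNAL_STANDARD = "heavy_internal_standard"

SAMPLE_TYPES = frozenset(
    {
        "environmental_dissolved",
        "spent_medium",
        "medium_blank",
        "particulate",
        "qc_pool",
        "calibration",
    }
)

#: standard-addition spike levels, fmol on column (HET is run at a lower range)
DEFAULT_LEVELS_FMOL: tuple[float, ...] = (0.0, 25.0, 50.0, 250.0)
HET_LEVELS_FMOL: tuple[float, ...] = (0.0, 5.0, 10.0, 50.0)

#: instrument response gain, peak-apex intensity units per fmol on column.
#: Arbitrary: no real instrument is being reproduced, only a linear response.
RESPONSE_GAIN = 1000.0

#: chromatographic run length and sampling interval (12-min run, 0.5-s scans)
RUN_MINUTES = 12.0
GRID_STEP_MINUTES = 0.5 / 60.0


@dataclass(frozen=True)
class CompoundSpec:
    """One targeted analyte (or the heavy internal standard).

    ``fragment_rel_intensities`` are the expected relative contributions of
    each monitored fragment transition to the total response; they must be
    strictly positive and sum to 1. Analytes carry at least two fragments so
    the sub-LOQ co-occurrence criterion is checkable.
    """

    name: str
    precursor_mz: float
    fragment_mzs: tuple[float, ...]
    fragment_rel_intensities: tuple[float, ...]
    retention_time: float
    peak_sigma: float
    role: str = ROLE_ANALYTE

    def __post_init__(self) -> None:
        if self.role not in (ROLE_ANALYTE, ROLE_INTERNAL_STANDARD):
            raise InvalidInputError(f"unknown role {self.role!r}")
        rel = tuple(float(x) for x in self.fragment_rel_intensities)
        mzs = tuple(float(x) for x in self.fragment_mzs)
        object.__setattr__(self, "fragment_rel_intensities", rel)
        object.__setattr__(self, "fragment_mzs", mzs)
        if len(rel) != len(mzs):
            raise InvalidInputError("fragment lists must have equal length")
        if self.role == ROLE_ANALYTE and len(mzs) < 2:
            raise InvalidInputError("analytes need >=2 fragment transitions")
        if any(r <= 0 for r in rel):
            raise InvalidInputError("fragment_rel_intensities must be strictly positive")
        if abs(sum(rel) - 1.0) > 1e-9:
            raise InvalidInputError("fragment_rel_intensities must sum to 1")
        if not (0.0 < self.retention_time < RUN_MINUTES):
            raise InvalidInputError("retention_time must lie within the gradient span")
        if self.peak_sigma <= 0:
            raise InvalidInputError("peak_sigma must be positive")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_mzs)


def make_default_panel() -> tuple[CompoundSpec, ...]:
    """Deterministic 7-compound panel: 6 analytes plus heavy B1.

    The heavy internal standard co-elutes exactly with B1, as an isotope label
    does not shift retention. All m/z and retention values are invented.
    """
    return (
        CompoundSpec("B1", 265.1, (122.1, 144.0), (0.70, 0.30), 5.60, 0.05),
        CompoundSpec("HMP", 140.1, (123.0, 81.1), (0.60, 0.40), 2.80, 0.05),
        CompoundSpec("AmMP", 139.1, (122.1, 95.0), (0.65, 0.35), 2.20, 0.05),
        CompoundSpec("FAMP", 167.1, (150.0, 122.1, 81.1), (0.55, 0.30, 0.15), 3.40, 0.05),
        CompoundSpec("cHET", 188.0, (144.0, 126.0), (0.60, 0.40), 6.50, 0.05),
        CompoundSpec("HET", 144.0, (126.0, 112.1), (0.70, 0.30), 7.20, 0.05),
        CompoundSpec(
            "B1_13C", 269.1, (126.1, 148.0), (0.70, 0.30), 5.60, 0.05,
            role=ROLE_INTERNAL_STANDARD,
        ),
    )


def _vial_fmol_per_ul(
    concentration_pm: float,
    sample_volume_ml: float,
    efficiency: float,
    resuspension_volume_ul: float,
) -> float:
    # pM x mL = 1e-12 mol/L x 1e-3 L = 1e-15 mol = fmol
    return concentration_pm * sample_volume_ml * efficiency / resuspension_volume_ul


def simulate_extraction(
    concentration_pm: float,
    sample_volume_ml: float,
    efficiency: float,
    resuspension_volume_ul: float,
    injection_volume_ul: float,
) -> float:
    """On-column amount (fmol) after SPE extraction and injection.

    A sample at ``concentration_pm`` is extracted from ``sample_volume_ml``
    with scalar efficiency, dried, resuspended in ``resuspension_volume_ul``,
    and ``injection_volume_ul`` of the vial is injected:

        fmol = conc[pM] * volume[mL] * efficiency * (injection / resuspension)
    """
    if concentration_pm < 0:
        raise InvalidInputError("concentration must be non-negative")
    if sample_volume_ml <= 0 or resuspension_volume_ul <= 0 or injection_volume_ul <= 0:
        raise InvalidInputError("volumes must be strictly positive")
    if not (0.0 < efficiency <= 1.0):
        raise InvalidInputError("efficiency must lie in (0, 1]")
    return (
        _vial_fmol_per_ul(
            concentration_pm, sample_volume_ml, efficiency, resuspension_volume_ul
        )
        * injection_volume_ul
    )


@dataclass(frozen=True)
class SampleDesign:
    """Ground-truth description of one physical sample.

    ``true_concentrations_pm`` and ``spikes_pm`` are per-compound in-sample
    concentrations (pM); spikes include the heavy internal standard.
    ``extraction_efficiency`` is a scalar applied to every compound or a
    per-compound mapping. QC pools are constructed with :func:`make_qc_pool`,
    never specified directly: they carry post-extraction vial concentrations
    in ``vial_fmol_per_ul`` instead of in-sample concentrations.
    """

    sample_id: str
    sample_type: str
    true_concentrations_pm: Mapping[str, float] = field(default_factory=dict)
    sample_volume_ml: float = 20.0
    extraction_efficiency: Mapping[str, float] | float = 1.0
    resuspension_volume_ul: float = 100.0
    spikes_pm: Mapping[str, float] = field(default_factory=dict)
    vial_fmol_per_ul: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise InvalidInputError(f"unknown sample_type {self.sample_type!r}")
        if self.sample_volume_ml <= 0 or self.resuspension_volume_ul <= 0:
            raise InvalidInputError("volumes must be strictly positive")
        effs = (
            self.extraction_efficiency.values()
            if isinstance(self.extraction_efficiency, Mapping)
            else [self.extraction_efficiency]
        )
        if any(not (0.0 < e <= 1.0) for e in effs):
            raise InvalidInputError("extraction efficiencies must lie in (0, 1]")
        if any(c < 0 for c in self.true_concentrations_pm.values()):
            raise InvalidInputError("concentrations must be non-negative")

    def efficiency_for(self, compound: str) -> float:
        if isinstance(self.extraction_efficiency, Mapping):
            return float(self.extraction_efficiency.get(compound, 1.0))
        return float(self.extraction_efficiency)

    def compounds(self) -> set[str]:
        if self.vial_fmol_per_ul is not None:
            return set(self.vial_fmol_per_ul)
        return set(self.true_concentrations_pm) | set(self.spikes_pm)

    def vial_concentration(self, compound: str) -> float:
        """Post-extraction vial concentration, fmol per µL."""
        if self.vial_fmol_per_ul is not None:
            return float(self.vial_fmol_per_ul.get(compound, 0.0))
        total_pm = self.true_concentrations_pm.get(compound, 0.0) + self.spikes_pm.get(
            compound, 0.0
        )
        return _vial_fmol_per_ul(
            total_pm,
            self.sample_volume_ml,
            self.efficiency_for(compound),
            self.resuspension_volume_ul,
        )

    def on_column_fmol(self, compound: str, injection_volume_ul: float) -> float:
        return self.vial_concentration(compound) * injection_volume_ul


def make_qc_pool(samples: Sequence[SampleDesign], pool_id: str = "qc_pool") -> SampleDesign:
    """Pool equal portions of each sample of one matrix grouping.

    The pool's vial concentration per compound is the arithmetic mean of the
    member samples' post-extraction vial concentrations.
    """
    if not samples:
        raise InvalidInputError("cannot pool zero samples")
    types = {s.sample_type for s in samples}
    if len(types) > 1:
        raise InvalidInputError(f"cannot pool mixed matrix groups: {sorted(types)}")
    compounds = set().union(*(s.compounds() for s in samples))
    vial = {
        c: float(np.mean([s.vial_concentration(c) for s in samples])) for c in compounds
    }
    return SampleDesign(
        sample_id=pool_id,
        sample_type="qc_pool",
        vial_fmol_per_ul=vial,
    )


@dataclass(frozen=True)
class BatchDesign:
    """One simulated acquisition batch.

    ``noise_sd`` is additive i.i.d. Gaussian noise per time point and
    ``baseline_level`` a constant offset (both in intensity units; defaults are
    arbitrary instrument-scale choices). ``area_noise_cv`` adds independent
    multiplicative amplitude jitter per (injection, compound); ``injection_cv``
    adds common-mode jitter shared by all compounds of one injection,
    emulating injection-volume variability that internal-standard
    normalization can cancel.
    """

    samples: tuple[SampleDesign, ...]
    calibration_levels_fmol: Mapping[str, Sequence[float]] | None = None
    injections_per_level: int = 2
    injection_volume_ul: float = 5.0
    noise_sd: float = 5.0
    baseline_level: float = 20.0
    area_noise_cv: float = 0.0
    injection_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.injections_per_level < 1:
            raise InvalidInputError("injections_per_level must be >= 1")
        if self.injection_volume_ul <= 0:
            raise InvalidInputError("injection_volume must be positive")
        if self.noise_sd < 0 or self.baseline_level < 0:
            raise InvalidInputError("noise_sd and baseline_level must be >= 0")
        if self.calibration_levels_fmol is not None:
            for name, levels in self.calibration_levels_fmol.items():
                if any(l < 0 for l in levels):
                    raise InvalidInputError(f"negative calibration level for {name}")
                if 0.0 not in [float(l) for l in levels]:
                    raise InvalidInputError(f"calibration levels for {name} must include 0")

    def levels_for(self, compound: str) -> tuple[float, ...]:
        if self.calibration_levels_fmol is not None and compound in self.calibration_levels_fmol:
            return tuple(float(l) for l in self.calibration_levels_fmol[compound])
        return HET_LEVELS_FMOL if compound == "HET" else DEFAULT_LEVELS_FMOL


def simulate_traces(
    compound: CompoundSpec,
    on_column_fmol: float,
    design: BatchDesign,
    seed: int,
    injection_id: str = "inj0",
    scale: float = 1.0,
) -> TraceSet:
    """Simulate the SRM traces of one compound in one injection.

    Per fragment transition k:

        intensity(t) = G * fmol * rel_k * scale * exp(-(t - RT)^2 / (2 sigma^2))
                       + baseline + N(0, noise_sd)

    on a uniform grid covering the 12-min run. Identical arguments give
    identical traces.
    """
    if on_column_fmol < 0:
        raise InvalidInputError("on_column_fmol must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, round(RUN_MINUTES / GRID_STEP_MINUTES) + 1) * GRID_STEP_MINUTES
    shape = np.exp(-((t - compound.retention_time) ** 2) / (2.0 * compound.peak_sigma**2))
    traces = []
    for rel in compound.fragment_rel_intensities:
        amplitude = RESPONSE_GAIN * on_column_fmol * rel * scale
        y = amplitude * shape + design.baseline_level
        if design.noise_sd > 0:
            y = y + rng.normal(0.0, design.noise_sd, size=t.size)
        traces.append(y)
    return TraceSet(
        injection_id=injection_id,
        compound=compound.name,
        time=t,
        intensities=tuple(traces),
    )


@dataclass
class Batch:
    """Simulated traces plus the ground-truth ledger that generated them."""

    traces: list[TraceSet]
    ledger: pd.DataFrame
    design: BatchDesign
    panel: tuple[CompoundSpec, ...]

    def panel_by_name(self) -> dict[str, CompoundSpec]:
        return {c.name: c for c in self.panel}


def _injection_plan(design: BatchDesign, panel: Sequence[CompoundSpec]):
    """Yield (injection_id, sample, level_index) in a fixed deterministic order.

    level_index is None for plain sample injections and 0..n-1 for the
    standard-addition series run on each QC pool.
    """
    for sample in design.samples:
        for k in range(design.injections_per_level):
            yield f"{sample.sample_id}_inj{k}", sample, None
        if sample.sample_type in ("qc_pool", "calibration"):
            n_levels = len(design.levels_for(panel[0].name))
            for li in range(n_levels):
                for k in range(design.injections_per_level):
                    yield f"{sample.sample_id}_cal{li}_inj{k}", sample, li


def simulate_batch(
    design: BatchDesign, panel: Sequence[CompoundSpec] | None = None
) -> Batch:
    """Simulate a full batch: samples, QC-pool calibration series, duplicates.

    Every sample in the design is injected ``injections_per_level`` times. For
    each QC-pool (or calibration) sample, a standard-addition series is run on
    top: at level index i the per-compound spike amount (fmol on column) is
    taken from that compound's calibration design, with duplicate injections
    per level. The returned ledger records, per injection and compound, the
    true on-column amount and the added calibration amount. All randomness
    flows from ``design.seed``.
    """
    panel = tuple(panel) if panel is not None else make_default_panel()
    level_counts = {len(design.levels_for(c.name)) for c in panel if c.role == ROLE_ANALYTE}
    if len(level_counts) > 1:
        raise InvalidInputError("all compounds must share the same number of levels")
    rng = np.random.default_rng(design.seed)
    traces: list[TraceSet] = []
    rows = []
    for injection_id, sample, level_index in _injection_plan(design, panel):
        common = 1.0
        if design.injection_cv > 0:
            common = max(1.0 + rng.normal(0.0, design.injection_cv), 0.05)
        for comp in panel:
            base_fmol = sample.on_column_fmol(comp.name, design.injection_volume_ul)
            added = 0.0
            if level_index is not None and comp.role == ROLE_ANALYTE:
                added = design.levels_for(comp.name)[level_index]
            fmol = base_fmol + added
            scale = common
            if design.area_noise_cv > 0:
                scale *= max(1.0 + rng.normal(0.0, design.area_noise_cv), 0.05)
            child_seed = int(rng.integers(0, 2**31))
            traces.append(
                simulate_traces(
                    comp, fmol, design, child_seed, injection_id=injection_id, scale=scale
                )
            )
            rows.append(
                {
                    "injection_id": injection_id,
                    "sample_id": sample.sample_id,
                    "sample_type": "calibration" if level_index is not None else sample.sample_type,
                    "level_index": -1 if level_index is None else level_index,
                    "compound": comp.name,
                    "role": comp.role,
                    "true_fmol": fmol,
                    "added_fmol": added,
                }
            )
    ledger = pd.DataFrame(rows)
    return Batch(traces=traces, ledger=ledger, design=design, panel=panel)
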