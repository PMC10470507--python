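"""Study-style result tables and dissolved-phase mass balances.

Replicate concentrations are summarized as mean +/- sample SD (the SD is
withheld when fewer than three independent replicates back it), displayed at
two significant figures. The dissolved-phase mass balance differences a
spent-medium summary against its medium blank; the uncertainty of the
difference can be propagated in quadrature (default, standard practice for
independent errors) or as a straight sum of the two SDs (conservative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .detection import DetectionStatus
from .errors import InvalidInputError
from .quantify import QuantResult

__all__ = [
    "SummaryValue",
    "MassBalance",
    "format_sigfigs",
    "summarize_replicates",
    "dissolved_phase_change",
    "render_report",
]


def format_sigfigs(x: float, sig: int = 2) -> str:
    """Format to ``sig`` significant figures the way the result tables print.

    Values rounding to >= 10**(sig-1) lose the decimal point ("11", "-20");
    smaller values keep exactly ``sig`` significant digits ("1.6", "0.027").
    """
    if not math.isfinite(x):
        return str(x)
    if x == 0:
        return "0.0"
    d = sig - 1 - math.floor(math.log10(abs(x)))
    y = round(x, d)
    if y == 0:
        return "0.0"
    # rounding may push into the next decade (0.0995 -> 0.10); recompute
    d2 = sig - 1 - math.floor(math.log10(abs(y)))
    d = min(d, d2)
    if d <= 0:
        return str(int(round(y)))
    return f"{y:.{d}f}"


@dataclass(frozen=True)
class SummaryValue:
    """Replicate summary: mean, optional SD, replicate count, display text."""

    mean: float
    sd: float | None
    n: int
    display: str

    @property
    def units_scale(self) -> float:  # placeholder for unit tagging
        return 1.0


def summarize_replicates(
    values: Sequence[float], n_independent: int, sig: int = 2
) -> SummaryValue:
    """Mean +/- sample SD of replicate measurements.

    The SD (n-1 denominator) is reported only when at least three independent
    replicates exist; technical duplicates of a single sample yield a mean
    without an SD.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InvalidInputError("need at least one value")
    mean = float(np.mean(vals))
    sd: float | None = None
    if n_independent >= 3 and vals.size >= 2:
        sd = float(np.std(vals, ddof=1))
    if sd is None:
        display = format_sigfigs(mean, sig)
    else:
        display = f"{format_sigfigs(mean, sig)} ± {format_sigfigs(sd, sig)}"
    return SummaryValue(mean=mean, sd=sd, n=int(vals.size), display=display)


@dataclass(frozen=True)
class MassBalance:
    """Spent-minus-blank concentration change with propagated uncertainty."""

    compound: str
    spent: SummaryValue
    blank: SummaryValue
    delta_mean: float
    delta_uncertainty: float
    propagation_mode: str
    display: str


def dissolved_phase_change(
    spent: SummaryValue,
    blank: SummaryValue,
    mode: str = "quadrature",
    compound: str = "",
    sig: int = 2,
) -> MassBalance:
    """Change in the dissolved phase: spent-medium mean minus blank mean.

    Uncertainty of the difference: quadrature mode sqrt(s1^2 + s2^2)
    (independent errors), sum mode s1 + s2 (conservative upper bound).
    Summaries lacking an SD contribute zero to the propagated uncertainty.
    """
    if mode not in ("quadrature", "sum"):
        raise InvalidInputError(f"unknown propagation mode {mode!r}")
    delta = spent.mean - blank.mean
    s1 = spent.sd or 0.0
    s2 = blank.sd or 0.0
    u = math.hypot(s1, s2) if mode == "quadrature" else s1 + s2
    display = f"{format_sigfigs(delta, sig)} ± {format_sigfigs(u, sig)}"
    return MassBalance(
        compound=compound,
        spent=spent,
        blank=blank,
        delta_mean=delta,
        delta_uncertainty=u,
        propagation_mode=mode,
        display=display,
    )


def _cell(result: QuantResult, sig: int) -> str:
    if result.status == DetectionStatus.nd:
        return "nd"
    if result.status == DetectionStatus.nq:
        return "nq"
    return format_sigfigs(result.conc_corrected, sig)


def render_report(
    results: Iterable[QuantResult | MassBalance], sig: int = 2
) -> str:
    """Render a deterministic tab-separated report.

    Quantification results pivot to one row per sample with one column per
    compound; combinations never measured render as "X", non-detects as "nd",
    unquantifiable detections as "nq". Mass balances append as a second block.
    Identical inputs yield identical bytes.
    """
    quants = [r for r in results if isinstance(r, QuantResult)]
    balances = [r for r in results if isinstance(r, MassBalance)]

    lines: list[str] = []
    if quants:
        compounds = sorted({r.compound for r in quants})
        samples = sorted({r.sample_id for r in quants})
        cells = {(r.sample_id, r.compound): _cell(r, sig) for r in quants}
        lines.append("\t".join(["Sample"] + compounds))
        for s in samples:
            lines.append(
                "\t".join([s] + [cells.get((s, c), "X") for c in compounds])
            )
    if balances:
        if lines:
            lines.append("")
        lines.append("\t".join(["Compound", "Change in dissolved phase"]))
        for b in sorted(balances, key=lambda b: b.compound):
            lines.append("\t".join([b.compound, b.display]))
    return "\n".join(lines) + "\n"
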