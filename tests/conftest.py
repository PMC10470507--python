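import numpy as np
import pytest

from srmquant.chromatography import TraceSet
from srmquant.synthetic import BatchDesign, make_default_panel


@pytest.fixture(scope="session")
def panel():
    return make_default_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {c.name: c for c in panel}


def gaussian_trace(
    amplitude: float,
    rt: float,
    sigma: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 12.0,
    dt: float = 0.5 / 60.0,
    injection_id: str = "inj0",
    compound: str = "X",
) -> TraceSet:
    """Single-fragment Gaussian peak on a uniform grid, for oracle tests."""
    t = np.arange(0.0, round(t_max / dt) + 1) * dt
    y = amplitude * np.exp(-((t - rt) ** 2) / (2 * sigma**2)) + baseline
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return TraceSet(injection_id, compound, t, (y,))


def famp_study_samples(concentrations_pm, efficiency: float = 0.5):
    """Study-style sample set: a FAMP concentration ladder, blanks, a
    spiked/unspiked recovery pair, and the QC pool drawn from the ladder."""
    from srmquant.validation import build_study_samples

    return build_study_samples(concentrations_pm, efficiency=efficiency)
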