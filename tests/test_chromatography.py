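"""Integration, S/N and quantifier-selection checks against closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from srmquant.chromatography import (
    IntegrationWindow,
    PeakArea,
    TraceSet,
    integrate_peak,
    select_quantifier_transitions,
    signal_to_noise,
    summed_area,
)
from srmquant.errors import InvalidInputError, InvalidWindowError
from srmquant.synthetic import BatchDesign, simulate_traces

from conftest import gaussian_trace


class TestIntegratePeak:
    @pytest.mark.parametrize("sigma", [0.02, 0.05, 0.1])
    def test_gaussian_area_oracle(self, sigma):
        amp = 1e4
        ts = gaussian_trace(amp, rt=5.0, sigma=sigma)
        window = IntegrationWindow(5.0, 4 * sigma)
        area = integrate_peak(ts, window).area
        assert area == pytest.approx(amp * sigma * math.sqrt(2 * math.pi), rel=5e-3)

    def test_constant_baseline_integrates_to_zero(self):
        ts = gaussian_trace(0.0, rt=5.0, sigma=0.05, baseline=500.0)
        assert integrate_peak(ts, IntegrationWindow(5.0, 0.2)).area == 0.0

    def test_flat_tail_window_is_negligible(self):
        ts = gaussian_trace(1e4, rt=5.0, sigma=0.05)
        full = integrate_peak(ts, IntegrationWindow(5.0, 0.2)).area
        tail = integrate_peak(ts, IntegrationWindow(8.0, 0.2)).area
        assert tail < 1e-3 * full

    def test_window_outside_trace_rejected(self):
        ts = gaussian_trace(1.0, rt=5.0, sigma=0.05)
        with pytest.raises(InvalidWindowError):
            integrate_peak(ts, IntegrationWindow(12.5, 0.2))

    def test_apex_inside_window_and_baseline_corrected(self):
        ts = gaussian_trace(1e4, rt=5.0, sigma=0.05, baseline=300.0)
        pa = integrate_peak(ts, IntegrationWindow(5.0, 0.2))
        assert abs(pa.apex_time - 5.0) <= 0.2
        assert pa.apex_intensity == pytest.approx(1e4, rel=1e-3)

    @pytest.mark.parametrize("shift_steps", [-60, 30, 120])
    def test_shift_invariance(self, shift_steps):
        dt = 0.5 / 60.0
        shift = shift_steps * dt
        a = integrate_peak(
            gaussian_trace(5e3, rt=5.0, sigma=0.05), IntegrationWindow(5.0, 0.2)
        ).area
        b = integrate_peak(
            gaussian_trace(5e3, rt=5.0 + shift, sigma=0.05),
            IntegrationWindow(5.0 + shift, 0.2),
        ).area
        assert b == pytest.approx(a, rel=1e-9)

    def test_negative_residual_clamps_to_zero(self):
        # inverted peak: baseline correction leaves a negative integral
        t = np.arange(0, 1441) * (0.5 / 60.0)
        y = 1000.0 - 900.0 * np.exp(-((t - 5.0) ** 2) / (2 * 0.05**2))
        ts = TraceSet("i", "X", t, (y,))
        assert integrate_peak(ts, IntegrationWindow(5.0, 0.2)).area == 0.0


class TestSignalToNoise:
    def test_noise_free_peak_gives_sentinel(self):
        ts = gaussian_trace(1e4, rt=5.0, sigma=0.05)
        assert signal_to_noise(ts, IntegrationWindow(5.0, 0.2)) == math.inf

    def test_pure_noise_snr_is_order_unity(self):
        snrs = [
            signal_to_noise(
                gaussian_trace(0.0, 5.0, 0.05, noise_sd=50.0, seed=s),
                IntegrationWindow(5.0, 0.2),
            )
            for s in range(100)
        ]
        assert np.median(snrs) < 5.0
        assert np.median(snrs) > 0.5

    def test_snr_linear_in_amplitude(self):
        window = IntegrationWindow(5.0, 0.2)
        lo = signal_to_noise(
            gaussian_trace(1e4, 5.0, 0.05, noise_sd=20.0, seed=3), window
        )
        hi = signal_to_noise(
            gaussian_trace(2e4, 5.0, 0.05, noise_sd=20.0, seed=3), window
        )
        assert hi / lo == pytest.approx(2.0, rel=0.05)

    def test_too_few_outside_points_rejected(self):
        t = np.linspace(4.9, 5.1, 30)
        ts = TraceSet("i", "X", t, (np.ones(30),))
        with pytest.raises(InvalidInputError):
            signal_to_noise(ts, IntegrationWindow(5.0, 0.09))


class TestQuantifierSelection:
    def _cal_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["compound", "fragment_index", "level_fmol", "area", "snr"]
        )

    def test_equal_snr_prefers_clean_fragment(self):
        cal = self._cal_frame(
            [("X", 0, 25.0, 100.0, 50.0), ("X", 1, 25.0, 100.0, 50.0)]
        )
        blanks = pd.DataFrame(
            [("X", 0, 50.0), ("X", 1, 0.0)],
            columns=["compound", "fragment_index", "area"],
        )
        assert select_quantifier_transitions(cal, blanks) == {"X": 1}

    def test_single_fragment_identity(self):
        cal = self._cal_frame([("X", 0, 25.0, 100.0, 10.0)])
        blanks = pd.DataFrame(columns=["compound", "fragment_index", "area"])
        with pytest.warns(UserWarning):
            assert select_quantifier_transitions(cal, blanks) == {"X": 0}

    def test_missing_blanks_warns_and_falls_back(self):
        cal = self._cal_frame(
            [("X", 0, 25.0, 100.0, 10.0), ("X", 1, 25.0, 100.0, 30.0)]
        )
        with pytest.warns(UserWarning):
            assert select_quantifier_transitions(cal, None) == {"X": 1}

    def test_dominant_fragment_wins_under_noise(self, panel_by_name):
        """The 3x more intense fragment is selected in >=95 of 100 seeded runs."""
        from srmquant.synthetic import CompoundSpec

        spec = CompoundSpec("X", 100.0, (50.0, 60.0), (0.25, 0.75), 5.0, 0.05)
        design = BatchDesign(samples=(), noise_sd=30.0, baseline_level=20.0, seed=0)
        window = IntegrationWindow(5.0, 0.2)
        wins = 0
        for seed in range(100):
            ts = simulate_traces(spec, 5.0, design, seed=seed, injection_id="c")
            rows = []
            for k in range(2):
                pa = integrate_peak(ts, window, k)
                pa.snr = signal_to_noise(ts, window, k)
                rows.append(("X", k, 5.0, pa.area, pa.snr))
            blank_ts = simulate_traces(spec, 0.0, design, seed=10_000 + seed)
            blank_rows = pd.DataFrame(
                [
                    ("X", k, integrate_peak(blank_ts, window, k).area)
                    for k in range(2)
                ],
                columns=["compound", "fragment_index", "area"],
            )
            if select_quantifier_transitions(self._cal_frame(rows), blank_rows) == {
                "X": 1
            }:
                wins += 1
        assert wins >= 95


class TestSummedArea:
    def _pa(self, area, frag=0, inj="i", comp="X"):
        return PeakArea(inj, comp, frag, area, 5.0, 10.0)

    def test_sums_and_identity(self):
        assert summed_area([self._pa(10.0), self._pa(5.0, frag=1)]) == 15.0
        assert summed_area([self._pa(7.5)]) == 7.5
        assert summed_area([self._pa(3.0, frag=k) for k in range(4)]) == 12.0

    def test_mixed_injections_rejected(self):
        with pytest.raises(InvalidInputError):
            summed_area([self._pa(1.0, inj="a"), self._pa(1.0, inj="b")])
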