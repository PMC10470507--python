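"""Generator-level checks: extraction arithmetic, trace shapes, pooling, batches."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srmquant.chromatography import IntegrationWindow, integrate_peak
from srmquant.errors import InvalidInputError
from srmquant.synthetic import (
    RESPONSE_GAIN,
    ROLE_ANALYTE,
    ROLE_INTERNAL_STANDARD,
    BatchDesign,
    SampleDesign,
    make_default_panel,
    make_qc_pool,
    simulate_batch,
    simulate_extraction,
    simulate_traces,
)


class TestDefaultPanel:
    def test_roster_and_roles(self, panel):
        assert len(panel) == 7
        roles = [c.role for c in panel]
        assert roles.count(ROLE_INTERNAL_STANDARD) == 1
        assert all(c.n_fragments >= 2 for c in panel if c.role == ROLE_ANALYTE)

    def test_deterministic_and_distinct_rts(self, panel):
        assert make_default_panel() == panel
        analytes = [c for c in panel if c.role == ROLE_ANALYTE]
        assert len({c.retention_time for c in analytes}) == len(analytes)

    def test_heavy_standard_coelutes_with_b1(self, panel_by_name):
        assert (
            panel_by_name["B1_13C"].retention_time
            == panel_by_name["B1"].retention_time
        )

    def test_rel_intensities_validated(self, panel_by_name):
        spec = panel_by_name["FAMP"]
        assert math.isclose(sum(spec.fragment_rel_intensities), 1.0, abs_tol=1e-9)
        with pytest.raises(InvalidInputError):
            spec.__class__(
                "bad", 100.0, (50.0, 60.0), (0.5, 0.6), 5.0, 0.05
            )


class TestSimulateExtraction:
    @pytest.mark.parametrize(
        "conc,vol,eff,resusp,inj,expected",
        [
            (100.0, 20.0, 0.5, 100.0, 5.0, 50.0),
            (0.0, 20.0, 0.5, 100.0, 5.0, 0.0),
            (100.0, 20.0, 1.0, 100.0, 5.0, 100.0),
        ],
    )
    def test_unit_chain(self, conc, vol, eff, resusp, inj, expected):
        assert simulate_extraction(conc, vol, eff, resusp, inj) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sample_volume_ml=0.0),
            dict(resuspension_volume_ul=-1.0),
            dict(efficiency=0.0),
            dict(efficiency=1.5),
        ],
    )
    def test_invalid_inputs(self, kwargs):
        args = dict(
            concentration_pm=10.0,
            sample_volume_ml=20.0,
            efficiency=0.5,
            resuspension_volume_ul=100.0,
            injection_volume_ul=5.0,
        )
        args.update(kwargs)
        with pytest.raises(InvalidInputError):
            simulate_extraction(**args)

    @settings(derandomize=True, max_examples=30)
    @given(
        conc=st.floats(0.0, 1e4),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_in_concentration(self, conc, scale):
        base = simulate_extraction(conc, 20.0, 0.5, 100.0, 5.0)
        scaled = simulate_extraction(conc * scale, 20.0, 0.5, 100.0, 5.0)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)


class TestSimulateTraces:
    def _design(self, **kw):
        defaults = dict(samples=(), noise_sd=0.0, baseline_level=0.0, seed=0)
        defaults.update(kw)
        return BatchDesign(**defaults)

    def test_zero_amount_noise_free_is_flat(self, panel_by_name):
        ts = simulate_traces(panel_by_name["FAMP"], 0.0, self._design(), seed=1)
        assert all(np.all(y == 0) for y in ts.intensities)

    def test_apex_at_retention_time(self, panel_by_name):
        spec = panel_by_name["B1"]
        ts = simulate_traces(spec, 10.0, self._design(), seed=1)
        apex = ts.time[int(np.argmax(ts.intensities[0]))]
        assert abs(apex - spec.retention_time) <= ts.time[1] - ts.time[0]

    def test_area_matches_gaussian_integral(self, panel_by_name):
        spec = panel_by_name["FAMP"]
        fmol = 25.0
        ts = simulate_traces(spec, fmol, self._design(), seed=1)
        window = IntegrationWindow(spec.retention_time, 4 * spec.peak_sigma)
        for k, rel in enumerate(spec.fragment_rel_intensities):
            expected = RESPONSE_GAIN * fmol * rel * spec.peak_sigma * math.sqrt(2 * math.pi)
            area = integrate_peak(ts, window, k).area
            assert area == pytest.approx(expected, rel=5e-3)

    def test_negative_amount_rejected(self, panel_by_name):
        with pytest.raises(InvalidInputError):
            simulate_traces(panel_by_name["B1"], -1.0, self._design(), seed=1)

    def test_same_seed_reproduces(self, panel_by_name):
        d = self._design(noise_sd=10.0, baseline_level=20.0)
        a = simulate_traces(panel_by_name["HMP"], 5.0, d, seed=42)
        b = simulate_traces(panel_by_name["HMP"], 5.0, d, seed=42)
        for ya, yb in zip(a.intensities, b.intensities):
            assert np.array_equal(ya, yb)


class TestQcPool:
    def _sample(self, sid, conc, vol=20.0, eff=0.5, resusp=100.0):
        return SampleDesign(sid, "spent_medium", {"FAMP": conc}, vol, eff, resusp)

    def test_pool_is_mean_of_vial_levels(self):
        # 10 and 30 pM at eff 0.5, 20 mL, 100 uL -> vial 1.0 and 3.0 fmol/uL
        pool = make_qc_pool([self._sample("a", 10.0), self._sample("b", 30.0)])
        assert pool.vial_concentration("FAMP") == pytest.approx(2.0)

    def test_single_sample_pool_identity(self):
        s = self._sample("a", 123.0)
        pool = make_qc_pool([s])
        assert pool.vial_concentration("FAMP") == pytest.approx(
            s.vial_concentration("FAMP"), rel=1e-12
        )

    def test_pool_of_pools_equals_pool_of_union(self):
        groups = [
            [self._sample(f"g{g}s{i}", 10.0 * (g + 1) + i) for i in range(3)]
            for g in range(2)
        ]
        pool_of_pools = make_qc_pool(
            [make_qc_pool(g, f"p{i}") for i, g in enumerate(groups)]
        )
        # brute-force average over the union (equal group sizes)
        union = groups[0] + groups[1]
        expected = sum(s.vial_concentration("FAMP") for s in union) / len(union)
        assert pool_of_pools.vial_concentration("FAMP") == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_and_mixed_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            make_qc_pool([])
        other = SampleDesign("x", "environmental_dissolved", {"FAMP": 1.0})
        with pytest.raises(InvalidInputError):
            make_qc_pool([self._sample("a", 1.0), other])


class TestSimulateBatch:
    def _design(self, seed=0):
        s = SampleDesign("s1", "spent_medium", {"FAMP": 100.0}, 20.0, 0.5, 100.0)
        pool = make_qc_pool([s], "pool")
        return BatchDesign(samples=(s, pool), seed=seed, noise_sd=2.0)

    def test_calibration_levels_and_duplicates(self):
        batch = simulate_batch(self._design())
        cal = batch.ledger[batch.ledger["sample_type"] == "calibration"]
        famp = cal[cal["compound"] == "FAMP"]
        assert sorted(famp["added_fmol"].unique()) == [0.0, 25.0, 50.0, 250.0]
        per_level = famp.groupby("added_fmol")["injection_id"].nunique()
        assert (per_level == 2).all()
        het = cal[cal["compound"] == "HET"]
        assert sorted(het["added_fmol"].unique()) == [0.0, 5.0, 10.0, 50.0]

    def test_ledger_matches_extraction_arithmetic(self):
        batch = simulate_batch(self._design())
        rows = batch.ledger
        s1 = rows[(rows["sample_id"] == "s1") & (rows["compound"] == "FAMP")]
        expected = simulate_extraction(100.0, 20.0, 0.5, 100.0, 5.0)
        assert (s1["true_fmol"] == expected).all()

    def test_same_seed_identical_ledger(self):
        a = simulate_batch(self._design(seed=7)).ledger
        b = simulate_batch(self._design(seed=7)).ledger
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_noise_free_area_linear_in_fmol(self, panel_by_name):
        # linearity invariant: noise-free area proportional to on-column amount
        spec = panel_by_name["FAMP"]
        design = BatchDesign(samples=(), noise_sd=0.0, baseline_level=0.0, seed=0)
        window = IntegrationWindow(spec.retention_time, 4 * spec.peak_sigma)
        fmols = [5.0, 50.0, 500.0]
        areas = [
            integrate_peak(simulate_traces(spec, f, design, seed=0), window, 0).area
            for f in fmols
        ]
        ratios = [a / f for a, f in zip(areas, fmols)]
        assert max(ratios) - min(ratios) < 1e-6 * max(ratios)
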