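"""Channels -> stress series -> summaries -> sweep verdicts."""

import json

import numpy as np
import pytest

from mcbridge import (
    CardiacParams,
    CompressionSchedule,
    HoopStressSeries,
    PressureChannels,
    compression_sweep,
    external_pressure_sweep,
    stress_series,
    summarize,
    synthesize_channels,
)
from mcbridge.stress_pipeline import write_sweep
from mcbridge.tube_mechanics import CollapsedWallError, PressureDiameterFit

from conftest import constant_channels


def naive_inner_stress(q1, q2, fit, geometry):
    """Independent per-sample chain: quartic fit -> incompressibility -> Lamé at r = ri.

    Written out longhand (no calls into the package's stress path) as the
    oracle for the vectorized pipeline.
    """
    out = np.empty(len(q1))
    k = (geometry.R0_mm**2 - geometry.Ri_mm**2) / geometry.lambda_z
    for i, (a, b) in enumerate(zip(q1, q2)):
        p = a - b
        d0 = fit.a + fit.b * p + fit.c * p**2 - fit.d * p**3 + fit.e * p**4
        r0 = d0 / 2.0
        ri = np.sqrt(r0**2 - k)
        r = ri
        term1 = (r0**2 / r**2 + 1.0) / (r0**2 / ri**2 - 1.0)
        term2 = (1.0 + ri**2 / r**2) / (1.0 - ri**2 / r0**2)
        out[i] = term1 * a - term2 * b
    return out


class TestStressSeries:
    def test_hydrostatic_channels(self, fit, geometry):
        ch = constant_channels(100.0, 100.0)
        for site in ("proximal", "distal"):
            series = stress_series(ch, site, fit, geometry)
            assert np.allclose(series.sigma, -100.0, rtol=1e-12)

    def test_internal_pressure_only(self, fit, geometry):
        # Chains the fit at p = 100 (d0 = 5.103 mm) into the inner-wall stress.
        ch = constant_channels(100.0, 0.0)
        series = stress_series(ch, "proximal", fit, geometry)
        r0sq = (5.103 / 2.0) ** 2
        expected = (2 * r0sq - 1.1575) / 1.1575 * 100.0 - 0.0
        assert np.allclose(series.sigma, expected, rtol=1e-9)

    def test_zero_channels(self, fit, geometry):
        ch = constant_channels(0.0, 0.0)
        series = stress_series(ch, "distal", fit, geometry)
        assert np.allclose(series.sigma, 0.0, atol=1e-15)

    def test_matches_naive_reimplementation(self, fit, geometry, cardiac):
        rng = np.random.default_rng(123)
        for _ in range(20):
            level = rng.uniform(0.0, 1.0)
            q2 = rng.uniform(0.0, 40.0)
            ch = synthesize_channels(
                cardiac, CompressionSchedule(level=level), q2_setpoint=q2,
                duration=2.0, sample_rate=200.0,
                seed=int(rng.integers(1_000_000)), noise_sd=1.0,
            )
            for site in ("proximal", "distal"):
                series = stress_series(ch, site, fit, geometry)
                q1 = ch.q1_prox if site == "proximal" else ch.q1_dist
                expected = naive_inner_stress(q1, ch.q2, fit, geometry)
                assert np.allclose(series.sigma, expected, rtol=1e-9)

    def test_linearity_with_frozen_geometry(self, fit, geometry, cardiac):
        """With the loaded geometry pinned at p = 0, stress is linear in pressure.

        Scaling both channels by alpha scales sigma by alpha; oracle is the
        general Lamé formula evaluated directly at the rest radii.
        """
        from mcbridge import PressurePair, hoop_stress_general, internal_radius

        r0 = fit.a / 2.0
        ri = internal_radius(r0, geometry)
        t = np.arange(500) / 100.0
        q1 = 90.0 + 30.0 * np.sin(2 * np.pi * t)
        q2 = np.full_like(q1, 10.0)
        base = hoop_stress_general(ri, r0, ri, PressurePair(q1, q2))
        for alpha in (0.5, 2.0, -1.0):
            scaled = hoop_stress_general(ri, r0, ri, PressurePair(alpha * q1, alpha * q2))
            assert np.allclose(scaled, alpha * base, rtol=1e-12)

    def test_collapse_reports_sample_index(self, geometry):
        # A fit that collapses below transmural pressure -50.
        shrink = PressureDiameterFit(a=4.91, b=0.05, c=0.0, d=0.0, e=0.0,
                                     validity_range=(-100.0, 160.0))
        n = 100
        t = np.arange(n) / 1000.0
        q1 = np.zeros(n)
        q2 = np.zeros(n)
        q2[37] = 60.0  # transmural -60 -> d0 = 1.91 -> collapsed
        ch = PressureChannels(t=t, q1_prox=q1, q1_dist=q1, q2=q2, meta={})
        with pytest.raises(CollapsedWallError, match="index 37"):
            stress_series(ch, "proximal", shrink, geometry)

    def test_unknown_site_rejected(self, fit, geometry):
        with pytest.raises(ValueError, match="site"):
            stress_series(constant_channels(1.0, 0.0), "medial", fit, geometry)


class TestSummarize:
    def test_constant_series(self):
        s = HoopStressSeries(
            t=np.arange(1000) / 1000.0, sigma=np.full(1000, 5.0),
            site="proximal", period_s=0.5,
        )
        summary = summarize(s, window=2)
        assert summary.mean == 5.0
        assert summary.oscillatory == 0.0

    def test_sinusoid_closed_form(self):
        rate, period, cycles = 1000, 1.0, 4
        t = np.arange(rate * cycles) / rate
        sigma = 7.0 + 3.0 * np.sin(2 * np.pi * t / period)
        s = HoopStressSeries(t=t, sigma=sigma, site="distal", period_s=period)
        summary = summarize(s, window=2)
        assert summary.oscillatory == pytest.approx(6.0, rel=1e-4)
        assert summary.mean == pytest.approx(7.0, abs=1e-9)

    def test_mean_invariant_under_whole_cycle_shift(self):
        rate, period = 1000, 1.0
        t = np.arange(rate * 5) / rate
        sigma = 2.0 + np.cos(2 * np.pi * t / period + 0.7)
        means = []
        for cycles in (5, 4, 3):
            s = HoopStressSeries(t=t[: rate * cycles], sigma=sigma[: rate * cycles],
                                 site="distal", period_s=period)
            means.append(summarize(s, window=2).mean)
        assert np.ptp(means) < 1e-9

    def test_window_stability_for_periodic_input(self, fit, geometry, cardiac):
        ch = synthesize_channels(cardiac, CompressionSchedule(level=0.8), noise_sd=0.0)
        series = stress_series(ch, "proximal", fit, geometry)
        s2 = summarize(series, window=2)
        s3 = summarize(series, window=3)
        assert s2.mean == pytest.approx(s3.mean, rel=1e-9)
        assert s2.oscillatory == pytest.approx(s3.oscillatory, rel=1e-9)

    def test_too_short_series_rejected(self):
        s = HoopStressSeries(t=np.arange(100) / 100.0, sigma=np.zeros(100),
                             site="proximal", period_s=1.0)
        with pytest.raises(ValueError, match="fewer"):
            summarize(s, window=2)

    def test_unknown_period_rejected(self):
        s = HoopStressSeries(t=np.arange(100) / 100.0, sigma=np.zeros(100),
                             site="proximal", period_s=None)
        with pytest.raises(ValueError, match="period"):
            summarize(s, window=1)


class TestCompressionSweep:
    def test_default_trends_all_pass(self, fit, geometry, cardiac):
        result = compression_sweep(params=cardiac, fit=fit, geometry=geometry, seed=1)
        assert result.verdicts == {
            "proximal_mean_increasing": True,
            "distal_mean_stable": True,
            "proximal_oscillatory_increasing": True,
            "proximal_exceeds_distal_oscillatory": True,
        }
        assert len(result.summaries) == 8  # 4 levels x 2 sites

    def test_repeated_level_fails_strict_increase(self, fit, geometry, cardiac):
        result = compression_sweep([0.5, 0.5], params=cardiac, fit=fit,
                                   geometry=geometry, seed=1)
        assert result.verdicts["proximal_mean_increasing"] is False
        assert result.verdicts["proximal_oscillatory_increasing"] is False

    def test_no_compression_makes_sites_identical(self, fit, geometry, cardiac):
        result = compression_sweep([0.0], params=cardiac, fit=fit,
                                   geometry=geometry, seed=1)
        prox = result.summary("proximal", 0.0)
        dist = result.summary("distal", 0.0)
        assert prox.mean == pytest.approx(dist.mean, rel=1e-12)
        assert prox.oscillatory == pytest.approx(dist.oscillatory, rel=1e-12)

    def test_noisy_runs_average_over_seeds_and_keep_trends(self, fit, geometry, cardiac):
        result = compression_sweep(params=cardiac, fit=fit, geometry=geometry,
                                   seed=2, noise_sd=0.5, duration=3.0,
                                   sample_rate=250.0)
        assert result.verdicts["proximal_mean_increasing"] is True
        assert result.verdicts["proximal_oscillatory_increasing"] is True


class TestExternalPressureSweep:
    def test_default_trend_decreasing_at_both_sites(self, fit, geometry, cardiac):
        result = external_pressure_sweep(params=cardiac, fit=fit,
                                         geometry=geometry, seed=1)
        assert result.verdicts == {
            "proximal_mean_decreasing": True,
            "distal_mean_decreasing": True,
        }
        assert len(result.summaries) == 14  # 7 setpoints x 2 sites

    def test_single_setpoint_not_evaluable(self, fit, geometry, cardiac):
        result = external_pressure_sweep([20.0], params=cardiac, fit=fit,
                                         geometry=geometry, seed=1)
        assert result.verdicts["proximal_mean_decreasing"] is None
        assert result.verdicts["distal_mean_decreasing"] is None

    def test_unordered_grid_rejected(self, fit, geometry, cardiac):
        with pytest.raises(ValueError, match="strictly increasing"):
            external_pressure_sweep([10.0, 10.0], params=cardiac, fit=fit,
                                    geometry=geometry)


def test_write_sweep_outputs(tmp_path, fit, geometry, cardiac):
    result = external_pressure_sweep([0.0, 30.0], params=cardiac, fit=fit,
                                     geometry=geometry, seed=1,
                                     duration=2.0, sample_rate=200.0)
    csv_path, json_path = write_sweep(result, tmp_path)
    lines = csv_path.read_text().strip().splitlines()
    assert len(lines) == 1 + 4  # header + 2 conditions x 2 sites
    payload = json.loads(json_path.read_text())
    assert payload["verdicts"]["proximal_mean_decreasing"] is True
    assert payload["meta"]["seed"] == 1


def test_plotting_smoke(fit, geometry, cardiac):
    from mcbridge.plotting import plot_channels, plot_sweep

    ch = synthesize_channels(cardiac, CompressionSchedule(level=1.0),
                             duration=2.0, sample_rate=200.0)
    assert plot_channels(ch) is not None
    result = compression_sweep([0.0, 1.0], params=cardiac, fit=fit,
                               geometry=geometry, duration=2.0, sample_rate=200.0)
    axes = plot_sweep(result)
    assert len(axes) == 2
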