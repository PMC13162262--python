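"""Flux-processing chain tests: resampling, rotation, decomposition,
lag alignment, covariance fluxes, QC and spectral diagnostics."""

import math

import numpy as np
import pytest

from eddycalc import eddy
from eddycalc.carbonate import seawater_density
from eddycalc.simulate import inject_artifacts, simulate_turbulence

RHO = seawater_density(25.0, 38.0)
DAY = 86400.0


def _series(values, rate=16.0, **kw):
    return eddy.ChannelSeries(np.asarray(values, dtype=float), rate, **kw)


class TestDownsample:
    def test_constant_preserved(self):
        out = eddy.downsample(_series(np.full(1600, 3.2)), 5.0)
        assert np.allclose(out.values, 3.2)
        assert out.rate == 5.0

    def test_slow_sine_amplitude_preserved(self):
        t = np.arange(16 * 3000) / 16.0
        x = np.sin(2 * np.pi * 0.01 * t)
        out = eddy.downsample(_series(x), 5.0)
        to = np.arange(len(out)) / 5.0
        basis = np.column_stack(
            [np.sin(2 * np.pi * 0.01 * to), np.cos(2 * np.pi * 0.01 * to)]
        )
        coef, *_ = np.linalg.lstsq(basis, out.values, rcond=None)
        assert math.hypot(*coef) == pytest.approx(1.0, abs=1e-3)

    def test_nyquist_alternation_suppressed(self):
        x = np.tile([1.0, -1.0], 800)  # +/-1 at 8 Hz when sampled at 16 Hz
        out = eddy.downsample(_series(x), 5.0)
        # brute-force block means: 4-sample blocks cancel exactly, 3-sample
        # blocks leave +/-1/3, so the aliased energy drops by ~70% in RMS
        idx = np.floor(np.arange(len(x)) / 16.0 * 5.0).astype(int)
        brute = np.array([x[idx == b].mean() for b in range(idx[-1] + 1)])
        assert np.allclose(out.values, brute, atol=1e-12)
        assert np.abs(out.values).max() <= 1.0 / 3.0 + 1e-12
        assert np.sqrt(np.mean(out.values**2)) < 0.31

    def test_gap_propagation(self):
        x = np.ones(32)
        gaps = np.zeros(32, dtype=bool)
        gaps[:3] = True  # first 5 Hz block: 3/4 samples missing
        out = eddy.downsample(_series(x, gaps=gaps), 5.0)
        assert out.gaps[0] and not out.gaps[1:].any()

    def test_empty_series(self):
        out = eddy.downsample(_series([]), 5.0)
        assert len(out) == 0


def _level_flow_means(n=24, speed=0.05, seed=3):
    rng = np.random.default_rng(seed)
    az = rng.uniform(0, 2 * np.pi, n)
    u = speed * np.cos(az) * rng.uniform(0.5, 1.5, n)
    v = speed * np.sin(az) * rng.uniform(0.5, 1.5, n)
    w = np.zeros(n)
    return np.column_stack([u, v, w])


class TestPlanarFit:
    def test_untilted_is_identity(self):
        fit = eddy.planar_fit(_level_flow_means())
        assert fit.tilt_deg < 0.05
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-3)

    def test_recovers_constructed_pitch(self):
        theta = math.radians(5.0)
        rot = np.array(
            [
                [math.cos(theta), 0.0, -math.sin(theta)],
                [0.0, 1.0, 0.0],
                [math.sin(theta), 0.0, math.cos(theta)],
            ]
        )
        tilted = _level_flow_means() @ rot.T
        fit = eddy.planar_fit(tilted)
        assert fit.tilt_deg == pytest.approx(5.0, abs=0.1)
        # rotated means are level again
        _, _, w = fit.apply(tilted[:, 0], tilted[:, 1], tilted[:, 2])
        assert np.abs(w.mean()) < 1e-10 * 0.05

    def test_rotation_preserves_speed(self):
        fit = eddy.planar_fit(_level_flow_means())
        rng = np.random.default_rng(0)
        u, v, w = rng.standard_normal((3, 100))
        ur, vr, wr = fit.apply(u, v, w)
        norm_in = np.sqrt(u**2 + v**2 + (w - fit.w_offset) ** 2)
        norm_out = np.sqrt(ur**2 + vr**2 + wr**2)
        assert np.allclose(norm_in, norm_out, rtol=1e-12)

    def test_collinear_flow_degenerate(self):
        m = np.column_stack([np.linspace(0.01, 0.1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(eddy.DegenerateGeometryError):
            eddy.planar_fit(m)

    def test_too_few_vectors(self):
        with pytest.raises(eddy.InsufficientDataError):
            eddy.planar_fit(np.zeros((4, 3)))


class TestReynoldsDecompose:
    def test_constant_gives_zero_fluctuation(self):
        _, fluct = eddy.reynolds_decompose(np.full(5000, 7.0), 5.0)
        assert np.allclose(fluct, 0.0, atol=1e-12)

    def test_linear_trend_removed_away_from_edges(self):
        x = np.linspace(0.0, 10.0, 20000)
        _, fluct = eddy.reynolds_decompose(x, 5.0)
        inner = fluct[2500:-2500]
        assert np.abs(inner).max() < 1e-9

    def test_running_mean_transfer(self):
        rate = 5.0
        t = np.arange(int(3600 * rate)) / rate
        fast = np.sin(2 * np.pi * t / 50.0)
        slow = np.sin(2 * np.pi * t / 5000.0)
        _, f_fast = eddy.reynolds_decompose(fast, rate)
        _, f_slow = eddy.reynolds_decompose(slow, rate)
        assert f_fast[2500:-2500].std() >= 0.99 * fast.std()
        assert f_slow[2500:-2500].std() <= 0.05 * slow.std()

    def test_short_series_raises(self):
        with pytest.raises(eddy.InsufficientDataError):
            eddy.reynolds_decompose(np.ones(100), 5.0)


class TestLagAlign:
    def test_recovers_constructed_delay(self, rng):
        w, _ = simulate_turbulence(50.0, 3600.0, 5.0, seed=11)
        wp = w.values
        shift = 7  # 1.4 s at 5 Hz
        c = np.roll(wp, shift) + 0.2 * wp.std() * rng.standard_normal(len(wp))
        shifted, lag_s, flags = eddy.lag_align(wp, c, 5.0)
        assert lag_s == pytest.approx(1.4, abs=0.2)
        assert not flags

    def test_identity_zero_lag(self):
        w, _ = simulate_turbulence(50.0, 1800.0, 5.0, seed=4)
        _, lag_s, flags = eddy.lag_align(w.values, w.values, 5.0)
        assert lag_s == 0.0 and not flags

    def test_independent_noise_flagged_low_correlation(self, rng):
        a = rng.standard_normal(9000)
        b = rng.standard_normal(9000)
        _, lag_s, flags = eddy.lag_align(a, b, 5.0)
        assert "low_correlation" in flags
        assert abs(lag_s) <= 2.0

    def test_all_zero_undefined(self):
        z = np.zeros(5000)
        _, lag_s, flags = eddy.lag_align(z, z, 5.0)
        assert lag_s == 0.0 and "undefined_correlation" in flags


class TestComputeFlux:
    def test_identical_series_gives_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8700)
        x -= x.mean()
        win = eddy.compute_flux(x, x, None, RHO)
        expected = x.var() * RHO * DAY / 1000.0
        assert win.flux == pytest.approx(expected, rel=1e-12)

    def test_independent_series_flux_is_null(self):
        fluxes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(8700) * 0.01
            c = rng.standard_normal(8700)
            fluxes.append(eddy.compute_flux(w, c, None, RHO).flux)
        fluxes = np.array(fluxes)
        se = fluxes.std(ddof=1) / math.sqrt(len(fluxes))
        assert abs(fluxes.mean()) < 3 * se

    def test_prescribed_covariance_recovered(self):
        # acceptance-scale check lives in test_acceptance; quick version here
        w, c = simulate_turbulence(50.0, 20 * 1800.0, 5.0, seed=1)
        fluxes = [
            eddy.compute_flux(
                w.values[i * 8700 : (i + 1) * 8700],
                c.values[i * 8700 : (i + 1) * 8700],
                None,
                RHO,
            ).flux
            for i in range(20)
        ]
        assert np.mean(fluxes) == pytest.approx(50.0, rel=0.05)

    def test_under_half_valid_invalidated(self):
        x = np.ones(1000)
        mask = np.zeros(1000, dtype=bool)
        mask[: 600] = True
        win = eddy.compute_flux(x, x, mask, RHO)
        assert "invalid" in win.qc_flags and not win.valid


class TestCumulativeFluxQC:
    def test_stationary_flux_is_linear(self):
        w, c = simulate_turbulence(50.0, 1800.0, 5.0, seed=2)
        qc = eddy.cumulative_flux_qc(w.values, c.values)
        assert qc["linear"] and qc["r2"] > 0.9

    def test_single_burst_flagged(self, rng):
        w = rng.standard_normal(8700) * 0.01
        c = rng.standard_normal(8700) * 0.1
        w[4000:4005] = 0.5
        c[4000:4005] = 50.0  # one burst carries the whole covariance
        qc = eddy.cumulative_flux_qc(w, c)
        assert not qc["linear"] and qc["burst"]

    def test_zero_flux_noise_not_nonlinear(self):
        local = np.random.default_rng(42)
        w = local.standard_normal(8700)
        c = local.standard_normal(8700)
        qc = eddy.cumulative_flux_qc(w, c)
        assert qc["low_flux"] and qc["linear"]


class TestCospectrum:
    def test_self_cospectrum_parseval(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(8700)
        cs = eddy.cospectrum(w, w, 5.0)
        assert cs.total == pytest.approx(np.var(w), rel=0.01)
        assert cs.ogive[-1] == pytest.approx(1.0, rel=1e-9)

    def test_band_limited_pair_ogive(self):
        # correlation confined below 0.1 Hz by a brickwall filter
        rng = np.random.default_rng(6)
        w = rng.standard_normal(36000)
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(len(w), d=0.2)
        w_low = np.fft.irfft(spec * (f <= 0.1), len(w))
        c = w_low + 0.5 * np.fft.irfft(
            np.fft.rfft(rng.standard_normal(len(w))) * (f > 0.1), len(w)
        )
        cs = eddy.cospectrum(w, c, 5.0)
        below = cs.ogive[cs.frequencies <= 0.1]
        assert below[-1] >= 0.95

    def test_parseval_against_direct_covariance(self):
        w, c = simulate_turbulence(50.0, 1800.0, 5.0, seed=7)
        cs = eddy.cospectrum(w.values, c.values, 5.0)
        direct = np.mean(
            (w.values - w.values.mean()) * (c.values - c.values.mean())
        )
        assert cs.total == pytest.approx(direct, rel=0.01)

    def test_short_window_raises(self):
        with pytest.raises(eddy.InsufficientDataError):
            eddy.cospectrum(np.ones(500), np.ones(500), 5.0)


class TestHighFreqLoss:
    def test_identical_cospectra_zero_loss(self):
        w, c = simulate_turbulence(50.0, 3600.0, 5.0, seed=8)
        cs = eddy.cospectrum(w.values, c.values, 5.0)
        assert eddy.estimate_highfreq_loss(cs, cs) == pytest.approx(0.0, abs=1e-12)

    def test_lowpassed_sensor_loss_matches_attenuation_oracle(self):
        w, c = simulate_turbulence(200.0, 6 * 3600.0, 5.0, seed=9, noise_ratio=0.0)
        slow = inject_artifacts(c.values, 5.0, t90_s=2.4)
        cs_ref = eddy.cospectrum(w.values, c.values, 5.0)
        cs_test = eddy.cospectrum(w.values, slow, 5.0)
        loss = eddy.estimate_highfreq_loss(cs_test, cs_ref)
        # brute-force attenuated-covariance oracle
        cov_ref = np.mean((w.values - w.values.mean()) * (c.values - c.values.mean()))
        cov_att = np.mean((w.values - w.values.mean()) * (slow - slow.mean()))
        oracle = 1.0 - cov_att / cov_ref
        assert loss > 0
        assert loss == pytest.approx(oracle, abs=0.02)

    def test_extra_highfreq_content_negative_loss(self):
        rng = np.random.default_rng(10)
        w, c = simulate_turbulence(100.0, 3600.0, 5.0, seed=12, noise_ratio=0.0)
        smooth = inject_artifacts(c.values, 5.0, t90_s=3.0)
        cs_smooth = eddy.cospectrum(w.values, smooth, 5.0)
        cs_sharp = eddy.cospectrum(w.values, c.values, 5.0)
        assert eddy.estimate_highfreq_loss(cs_sharp, cs_smooth) < 0


class TestStorageAndCalibration:
    def test_storage_flux_arithmetic(self):
        assert eddy.storage_flux(200.0, 200.0, 3600.0, 1.0, 1025.0) == 0.0
        val = eddy.storage_flux(200.0, 210.0, 3600.0, 1.0, 1025.0)
        assert val == pytest.approx(10.0 / 3600.0 * 1.0 * 1025.0 * 86.4, rel=1e-12)
        assert val > 0  # rising concentration = positive storage

    def test_ph_to_proton(self):
        out = eddy.ph_to_proton(np.array([8.0, 7.0, 7.5]))
        assert out[0] == pytest.approx(10.0, rel=1e-12)
        assert out[1] == pytest.approx(100.0, rel=1e-12)
        assert out[1] > out[2] > out[0]
        with pytest.raises(ValueError):
            eddy.ph_to_proton(np.array([1.0]))

    def test_isfet_calibration(self):
        t = np.arange(100.0)
        mv = np.full(100, 250.0)
        ph = eddy.calibrate_isfet(mv, t, 50.0, 8.02)
        assert np.allclose(ph, 8.02)
        step = np.where(t < 60.0, 250.0, 309.0)  # +59 mV after the reference
        ph2 = eddy.calibrate_isfet(step, t, 30.0, 8.02)
        assert np.allclose(ph2[t >= 60.0], 8.12)
        assert np.allclose(ph2[t < 60.0], 8.02)

    def test_isfet_two_references_consistent(self):
        t = np.arange(200.0)
        mv = 100.0 + 0.59 * t  # noiseless linear drift
        a = eddy.calibrate_isfet(mv, t, 20.0, 8.0 + 0.59 * 20.0 / 590.0)
        b = eddy.calibrate_isfet(mv, t, 150.0, 8.0 + 0.59 * 150.0 / 590.0)
        assert np.allclose(a, b, atol=1e-12)

    def test_isfet_reference_outside_span(self):
        with pytest.raises(eddy.CalibrationError):
            eddy.calibrate_isfet(np.ones(10), np.arange(10.0), 99.0, 8.0)

    def test_despike_removes_spikes_only(self, rng):
        x = np.sin(np.arange(5000) / 50.0) + 0.01 * rng.standard_normal(5000)
        x_spiked = x.copy()
        x_spiked[[100, 2500, 4000]] += 5.0
        clean = eddy.despike(x_spiked, 5.0)
        assert np.isnan(clean[[100, 2500, 4000]]).all()
        assert np.isfinite(clean).mean() > 0.995
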