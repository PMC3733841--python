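"""Relaxometry: signal model, voxel/volume fitting, PD calibration."""

import math

import numpy as np
import pytest

from qmap import (
    AcquisitionProtocol,
    AcquisitionSeries,
    calibrate_pd,
    fit_volume,
    fit_voxel,
    model_signal,
)
from qmap.relaxometry import FIT_INVALID_INPUT, FIT_OK, _fit_signals


@pytest.fixture
def protocol():
    return AcquisitionProtocol()


def series_from(r1, r2, m0, protocol, shape=(4, 4, 3), affine=None):
    """Noise-free forward-model series with constant parameters."""
    data = np.empty((protocol.n_delays, protocol.n_echoes) + shape)
    for i, td in enumerate(protocol.saturation_delays_ms):
        for j, te in enumerate(protocol.echo_times_ms):
            data[i, j] = model_signal(r1, r2, m0, td, te)
    return AcquisitionSeries(data=data, protocol=protocol, affine=affine if affine is not None else np.eye(4))


class TestProtocol:
    def test_defaults_give_20_images_per_slice(self, protocol):
        assert protocol.n_delays == 4
        assert protocol.n_echoes == 5
        assert protocol.n_delays * protocol.n_echoes == 20

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"saturation_delays_ms": (400.0, 100.0)},          # not increasing
            {"saturation_delays_ms": (-100.0, 400.0)},         # negative
            {"echo_times_ms": (14.0, 14.0)},                   # not strict
            {"saturation_delays_ms": (100.0, 3000.0)},         # delay >= TR
            {"repetition_time_ms": -1.0},
        ],
    )
    def test_invalid_timing_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionProtocol(**kwargs)

    def test_json_round_trip(self, protocol, tmp_path):
        path = tmp_path / "protocol.json"
        protocol.to_json(path)
        assert AcquisitionProtocol.from_json(path) == protocol


class TestModelSignal:
    def test_zero_magnetization_gives_zero(self):
        assert model_signal(1.0, 10.0, 0.0, 500.0, 20.0) == 0.0

    def test_full_recovery_no_decay_gives_m0(self):
        # R1 -> infinity limit with TE = 0
        assert model_signal(1e6, 10.0, 42.0, 100.0, 0.0) == pytest.approx(42.0, rel=1e-12)

    def test_white_matter_closed_form(self):
        # direct evaluation of M0*(1-exp(-TD*R1))*exp(-TE*R2) at typical
        # white-matter values, frozen from an independent computation
        s = model_signal(1.38, 11.79, 70.0, 2860.0, 14.0)
        assert s == pytest.approx(58.20258832931168, rel=1e-12)
        assert s == pytest.approx(
            70.0 * (1 - math.exp(-2.860 * 1.38)) * math.exp(-0.014 * 11.79), rel=1e-14
        )

    def test_monotonic_in_delay_and_echo(self):
        delays = np.linspace(50, 2800, 30)
        echoes = np.linspace(5, 90, 30)
        s_d = model_signal(1.0, 10.0, 100.0, delays, 20.0)
        s_e = model_signal(1.0, 10.0, 100.0, 500.0, echoes)
        assert np.all(np.diff(s_d) > 0)
        assert np.all(np.diff(s_e) < 0)
        assert np.all(s_d >= 0) and np.all(s_e >= 0)

    def test_negative_rate_is_domain_error(self):
        with pytest.raises(ValueError):
            model_signal(-0.1, 10.0, 100.0, 500.0, 20.0)
        with pytest.raises(ValueError):
            model_signal(1.0, -0.1, 100.0, 500.0, 20.0)


class TestFitVoxel:
    def test_noise_free_round_trip(self, protocol):
        truth = (1.0, 10.0, 1000.0)
        signals = np.array(
            [
                [model_signal(*truth, td, te) for te in protocol.echo_times_ms]
                for td in protocol.saturation_delays_ms
            ]
        )
        r1, r2, m0, resid = fit_voxel(signals, protocol)
        assert r1 == pytest.approx(1.0, rel=1e-6)
        assert r2 == pytest.approx(10.0, rel=1e-6)
        assert m0 == pytest.approx(1000.0, rel=1e-6)
        assert resid < 1e-10

    def test_log_linear_echo_slope_equals_minus_r2(self, protocol):
        # algebraic identity: at fixed delay, log(S) is linear in TE with
        # slope -R2
        r2 = 12.345
        echoes = protocol.echoes_s
        signals = model_signal(1.2, r2, 500.0, protocol.saturation_delays_ms[-1],
                               np.asarray(protocol.echo_times_ms))
        slope = np.polyfit(echoes, np.log(signals), 1)[0]
        assert -slope == pytest.approx(r2, rel=1e-9)

    def test_all_zero_input_is_flagged_not_raised(self, protocol):
        r1, r2, m0, resid = fit_voxel(np.zeros((4, 5)), protocol)
        assert all(math.isnan(v) for v in (r1, r2, m0, resid))

    def test_shape_mismatch_is_config_error(self, protocol):
        with pytest.raises(ValueError):
            fit_voxel(np.ones((3, 5)), protocol)

    def test_noisy_recovery_median_within_2pct(self, protocol):
        # 1000 replicate voxels at sigma = 1% of M0, white-matter truth;
        # independently cross-checked against a dense grid-search oracle in
        # test_fit_beats_grid_search_oracle
        rng = np.random.default_rng(42)
        m0 = 70.0
        d, e = protocol.delays_s, protocol.echoes_s
        clean = m0 * (1 - np.exp(-d[:, None] * 1.38)) * np.exp(-e[None, :] * 11.79)
        noisy = clean[None] + rng.normal(0.0, 0.01 * m0, size=(1000,) + clean.shape)
        r1, r2, _, _, flags = _fit_signals(noisy, d, e)
        assert np.all(flags == FIT_OK)
        assert abs(np.median(r1) - 1.38) / 1.38 < 0.02
        assert abs(np.median(r2) - 11.79) / 11.79 < 0.02

    def test_fit_beats_grid_search_oracle(self, protocol):
        # least-squares objective must be <= the best dense grid-search
        # objective (independent oracle: exhaustive (R1, R2) grid with the
        # analytic M0 solution) on random noisy voxels
        rng = np.random.default_rng(5)
        d, e = protocol.delays_s, protocol.echoes_s
        n = 100
        r1t = rng.uniform(0.3, 2.0, n)
        r2t = rng.uniform(3.0, 20.0, n)
        m0t = rng.uniform(60.0, 95.0, n)
        sig = (
            m0t[:, None, None]
            * (1 - np.exp(-d[None, :, None] * r1t[:, None, None]))
            * np.exp(-e[None, None, :] * r2t[:, None, None])
        )
        sig = sig + rng.normal(0.0, 0.7, size=sig.shape)
        r1f, r2f, _, _, _ = _fit_signals(sig, d, e)

        g1 = np.arange(0.2, 2.2, 0.01)
        g2 = np.arange(2.0, 21.0, 0.05)
        f_all = (1 - np.exp(-d[:, None] * g1[None, :]))[:, None, :, None] * np.exp(
            -e[:, None] * g2[None, :]
        )[None, :, None, :]
        ff = (f_all ** 2).sum((0, 1))

        def sse(r1v, r2v, s):
            f = ((1 - np.exp(-d[:, None] * r1v)) * np.exp(-e[None, :] * r2v).reshape(1, -1)).ravel()
            sf = s.ravel() @ f
            return (s ** 2).sum() - sf ** 2 / (f @ f)

        for i in range(n):
            sf = np.einsum("de,degh->gh", sig[i], f_all)
            grid_best = ((sig[i] ** 2).sum() - (sf ** 2 / ff)).min()
            assert sse(r1f[i], r2f[i], sig[i]) <= grid_best + 1e-9 * abs(grid_best) + 1e-12

    def test_rmse_nondecreasing_in_noise(self, protocol):
        rng = np.random.default_rng(7)
        d, e = protocol.delays_s, protocol.echoes_s
        m0 = 70.0
        clean = m0 * (1 - np.exp(-d[:, None] * 1.38)) * np.exp(-e[None, :] * 11.79)
        rmses = []
        for frac in (0.005, 0.01, 0.02, 0.05):
            noisy = clean[None] + rng.normal(0.0, frac * m0, size=(400,) + clean.shape)
            r1, r2, _, _, _ = _fit_signals(noisy, d, e)
            rmses.append(np.sqrt(np.mean((r1 - 1.38) ** 2 + (r2 - 11.79) ** 2)))
        assert np.all(np.diff(rmses) > 0)


class TestFitVolume:
    def test_forward_inverse_round_trip_on_grid(self, protocol):
        # forward-inverse consistency over a physiological parameter grid
        r1g, r2g = np.meshgrid(np.linspace(0.2, 2.0, 8), np.linspace(2.0, 20.0, 8))
        r1t = np.tile(r1g.ravel(), 2)[:128].reshape(8, 4, 4)
        r2t = np.tile(r2g.ravel(), 2)[:128].reshape(8, 4, 4)
        d, e = protocol.delays_s, protocol.echoes_s
        data = (
            500.0
            * (1 - np.exp(-d[:, None, None, None, None] * r1t[None]))
            * np.exp(-e[None, :, None, None, None] * r2t[None, None])
        ).reshape(4, 5, 8, 4, 4)
        series = AcquisitionSeries(data=data, protocol=protocol, affine=np.eye(4))
        maps = fit_volume(series)
        assert np.all(maps.valid)
        assert np.allclose(maps.r1, r1t, rtol=1e-5)
        assert np.allclose(maps.r2, r2t, rtol=1e-5)
        assert np.allclose(maps.pd, 500.0, rtol=1e-5)

    def test_masked_voxels_carry_sentinel(self, protocol):
        series = series_from(1.0, 10.0, 100.0, protocol)
        mask = np.ones(series.shape, dtype=bool)
        mask[0, 0, 0] = False
        maps = fit_volume(series, mask=mask)
        assert not maps.valid[0, 0, 0]
        assert math.isnan(maps.r1[0, 0, 0]) and math.isnan(maps.r2[0, 0, 0])
        assert maps.fit_flags[0, 0, 0] == FIT_INVALID_INPUT
        assert maps.valid[1, 1, 1]

    def test_deterministic(self, protocol):
        rng = np.random.default_rng(3)
        series = series_from(1.0, 10.0, 100.0, protocol)
        series.data = series.data + rng.normal(0, 1.0, series.data.shape)
        a = fit_volume(series)
        b = fit_volume(series)
        assert np.array_equal(a.r1, b.r1, equal_nan=True)
        assert np.array_equal(a.r2, b.r2, equal_nan=True)
        assert np.array_equal(a.pd, b.pd, equal_nan=True)

    def test_mask_shape_mismatch_rejected(self, protocol):
        series = series_from(1.0, 10.0, 100.0, protocol)
        with pytest.raises(ValueError):
            fit_volume(series, mask=np.ones((2, 2, 2), dtype=bool))

    def test_series_io_round_trip(self, protocol, tmp_path):
        series = series_from(1.2, 9.0, 80.0, protocol, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        series.save(tmp_path / "series.nii")
        loaded = AcquisitionSeries.load(tmp_path / "series.nii")
        assert loaded.protocol == protocol
        assert np.allclose(loaded.data, series.data, rtol=1e-6)
        assert np.allclose(loaded.affine, series.affine)


class TestCalibratePD:
    def _maps(self, protocol, m0_values):
        vol = np.asarray(m0_values, dtype=float).reshape(-1, 1, 1)
        series = series_from(0.3, 1.0, 1.0, protocol, shape=vol.shape)
        series.data = series.data * vol[None, None]
        return fit_volume(series)

    def test_reference_median_maps_to_100(self, protocol):
        maps = self._maps(protocol, [500.0, 500.0, 350.0])
        mask = np.zeros(maps.shape, dtype=bool)
        mask[:2] = True
        cal = calibrate_pd(maps, mask)
        assert np.allclose(cal.pd[mask], 100.0, rtol=1e-6)
        assert cal.pd[2, 0, 0] == pytest.approx(70.0, rel=1e-6)
        assert np.array_equal(cal.r1, maps.r1, equal_nan=True)

    def test_idempotent(self, protocol):
        maps = self._maps(protocol, [500.0, 400.0, 300.0])
        mask = np.ones(maps.shape, dtype=bool)
        once = calibrate_pd(maps, mask)
        twice = calibrate_pd(once, mask)
        assert np.allclose(once.pd, twice.pd, rtol=1e-12)

    def test_preserves_ratios(self, protocol):
        maps = self._maps(protocol, [500.0, 350.0, 125.0])
        mask = np.zeros(maps.shape, dtype=bool)
        mask[0] = True
        cal = calibrate_pd(maps, mask)
        assert cal.pd[1, 0, 0] / cal.pd[2, 0, 0] == pytest.approx(
            maps.pd[1, 0, 0] / maps.pd[2, 0, 0], rel=1e-12
        )

    def test_empty_mask_is_error(self, protocol):
        maps = self._maps(protocol, [500.0])
        with pytest.raises(ValueError):
            calibrate_pd(maps, np.zeros(maps.shape, dtype=bool))
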