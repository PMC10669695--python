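"""Forward–inverse consistency, bound handling and map fitting."""

import dataclasses

import numpy as np
import pytest

from dwigrade.fitting import (
    FitConfig,
    fit_adc,
    fit_dki,
    fit_ivim,
    fit_parameter_maps,
)
from dwigrade.signal_models import (
    BScheme,
    DkiParams,
    IvimParams,
    dki_signal,
    ivim_signal,
    mono_signal,
    MonoParams,
)
from dwigrade.volume import DwiVolume


def ivim_series(scheme, f, d, dp, s0=1000.0):
    b = scheme.b(scheme.ivim_subset)
    return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * dp))


def dki_series(scheme, dapp, kapp, s0=1000.0):
    b = scheme.b(scheme.dki_subset)
    return np.exp(np.log(s0) - b * dapp + (b * dapp) ** 2 * kapp / 6.0)


class TestAdc:
    def test_exact_inverse_of_forward_model(self):
        assert fit_adc(1000.0, 1000.0 * np.exp(-0.8)) == pytest.approx(
            1.0e-3, rel=1e-12)

    def test_no_decay_gives_zero(self):
        assert fit_adc(500.0, 500.0) == 0.0

    def test_round_trip_at_reported_low_grade_mean(self):
        s800 = mono_signal(MonoParams(s0=1000.0, adc=1.471e-3), 800.0)
        assert fit_adc(1000.0, s800) == pytest.approx(1.471e-3, rel=1e-12)

    def test_non_positive_signal_marks_invalid(self):
        assert np.isnan(fit_adc(0.0, 100.0))
        assert np.isnan(fit_adc(100.0, -1.0))


class TestIvimFit:
    @pytest.mark.parametrize("f,d,dp", [
        (0.197, 1.129e-3, 48.165e-3),   # high-grade group means
        (0.239, 1.339e-3, 45.952e-3),   # low-grade group means
        (0.4, 2.5e-3, 20.0e-3),
        (0.05, 0.5e-3, 70.0e-3),
    ])
    def test_noise_free_recovery_within_1e6(self, scheme, f, d, dp):
        res = fit_ivim(ivim_series(scheme, f, d, dp), scheme)
        assert res.params.f == pytest.approx(f, rel=1e-6)
        assert res.params.d == pytest.approx(d, rel=1e-6)
        assert res.params.dp == pytest.approx(dp, rel=1e-6)
        assert res.converged

    def test_f_zero_collapse(self, scheme):
        res = fit_ivim(ivim_series(scheme, 0.0, 1.2e-3, 30e-3), scheme)
        assert res.params.f == 0.0
        assert res.params.d == pytest.approx(1.2e-3, rel=1e-6)
        assert "dp_unidentifiable" in res.flags

    def test_out_of_bounds_dp_clipped_exactly_at_bound(self, scheme):
        b = scheme.b(scheme.ivim_subset)
        sig = 1000.0 * (0.8 * np.exp(-b * 1.1e-3) + 0.2 * np.exp(-b * 100e-3))
        res = fit_ivim(sig, scheme)
        assert res.params.dp == 80.0e-3
        assert "dp" in res.at_bound
        assert not res.converged
        # constrained-optimum oracle: grid search over the bounded box
        y = sig / sig[0]

        def ssr(f, d, dp):
            return np.sum(((1 - f) * np.exp(-b * d) + f * np.exp(-b * dp) - y) ** 2)

        fs = np.linspace(0, 0.8, 17)
        ds = np.linspace(0, 5e-3, 26)
        dps = np.linspace(0, 80e-3, 21)
        grid = [(ssr(f, d, dp), f, d, dp) for f in fs for d in ds for dp in dps]
        best = min(grid)
        assert best[3] == 80.0e-3  # grid optimum sits on the dp upper bound
        assert res.residual_norm <= best[0] + 1e-12

    def test_degenerate_flat_signal(self, scheme):
        res = fit_ivim(np.full(12, 500.0), scheme)
        assert res.params.f == 0.0 and res.params.d == 0.0
        assert "degenerate" in res.flags

    def test_determinism(self, scheme):
        sig = ivim_series(scheme, 0.3, 1.0e-3, 40e-3)
        a = fit_ivim(sig, scheme)
        bres = fit_ivim(sig.copy(), scheme)
        assert dataclasses.astuple(a.params) == dataclasses.astuple(bres.params)
        assert a.residual_norm == bres.residual_norm

    def test_random_interior_tuples_recovered(self, scheme, rng):
        for _ in range(10):
            f = rng.uniform(0.05, 0.75)
            d = rng.uniform(0.2e-3, 4.5e-3)
            dp = rng.uniform(8e-3, 75e-3)
            res = fit_ivim(ivim_series(scheme, f, d, dp), scheme)
            assert res.params.f == pytest.approx(f, rel=1e-6)
            assert res.params.d == pytest.approx(d, rel=1e-6)
            assert res.params.dp == pytest.approx(dp, rel=1e-6)

    def test_nonpositive_signal_rejected(self, scheme):
        sig = ivim_series(scheme, 0.2, 1e-3, 40e-3)
        sig[3] = 0.0
        with pytest.raises(ValueError):
            fit_ivim(sig, scheme)


class TestDkiFit:
    @pytest.mark.parametrize("dapp,kapp", [
        (1.499e-3, 0.678),   # low-grade group means
        (1.297e-3, 0.819),   # high-grade group means
        (0.6e-3, 2.2),
        (3.0e-3, 0.1),
    ])
    def test_noise_free_recovery_within_1e6(self, scheme, dapp, kapp):
        res = fit_dki(dki_series(scheme, dapp, kapp), scheme)
        assert res.params.dapp == pytest.approx(dapp, rel=1e-6)
        assert res.params.kapp == pytest.approx(kapp, rel=1e-6)

    def test_kapp_zero_recovered(self, scheme):
        res = fit_dki(dki_series(scheme, 1.3e-3, 0.0), scheme)
        assert res.params.kapp == pytest.approx(0.0, abs=1e-8)

    def test_out_of_bounds_kapp_clipped_exactly(self, scheme):
        sig = dki_series(scheme, 1.0e-3, 3.0)
        res = fit_dki(sig, scheme)
        assert res.params.kapp == 2.5
        assert "kapp" in res.at_bound and not res.converged
        # bounded grid-search oracle in log-residual space
        b = scheme.b(scheme.dki_subset)
        y = np.log(sig)

        def ssr(dapp, kapp):
            return np.sum((y[0] - b * dapp + (b * dapp) ** 2 * kapp / 6 - y) ** 2)

        grid = [(ssr(da, ka), da, ka)
                for da in np.linspace(0, 5e-3, 51)
                for ka in np.linspace(0, 2.5, 26)]
        best = min(grid)
        assert best[2] == 2.5
        assert res.residual_norm <= best[0] + 1e-12


class TestMapFitting:
    def test_two_region_phantom_recovered_piecewise(self, scheme):
        nb = len(scheme.values)
        data = np.empty((4, 4, 1, nb))
        pa = dict(f=0.2, d=1.0e-3, dp=40e-3)
        pb = dict(f=0.1, d=2.0e-3, dp=20e-3)
        b = scheme.b()
        for params, sl in ((pa, np.s_[:2]), (pb, np.s_[2:])):
            low = b <= 800
            series = np.empty(nb)
            series[low] = ivim_signal(
                IvimParams(s0=1000.0, **params), b[low])
            series[~low] = dki_signal(
                DkiParams(s0=1000.0, dapp=params["d"], kapp=0.5), b[~low])
            data[sl] = series
        maps = fit_parameter_maps(DwiVolume(data=data, scheme=scheme))
        assert maps.valid.all()
        np.testing.assert_allclose(maps.maps["d"][:2], pa["d"], rtol=1e-6)
        np.testing.assert_allclose(maps.maps["d"][2:], pb["d"], rtol=1e-6)
        np.testing.assert_allclose(maps.maps["f"][:2], pa["f"], rtol=1e-6)
        np.testing.assert_allclose(maps.maps["dp"][2:], pb["dp"], rtol=1e-5)

    def test_empty_mask_gives_all_invalid(self, scheme):
        data = np.ones((3, 3, 1, len(scheme.values)))
        maps = fit_parameter_maps(DwiVolume(data=data, scheme=scheme),
                                  mask=np.zeros((3, 3, 1), bool))
        assert not maps.valid.any()
        assert np.isnan(maps.maps["d"]).all()

    def test_zero_signal_voxel_flagged_invalid_only(self, scheme):
        nb = len(scheme.values)
        b = scheme.b()
        series = 1000.0 * np.exp(-b * 1e-3)
        data = np.tile(series, (2, 2, 1, 1))
        data[0, 0, 0, :] = 0.0
        maps = fit_parameter_maps(DwiVolume(data=data, scheme=scheme))
        assert not maps.valid[0, 0, 0]
        assert maps.valid.sum() == 3

    def test_bound_respect_under_noise(self, scheme, rng):
        sig = ivim_series(scheme, 0.3, 1.2e-3, 50e-3, s0=100.0)
        for _ in range(20):
            noisy = np.abs(sig + rng.normal(0, 5.0, sig.shape))
            noisy[noisy <= 0] = 1e-6
            res = fit_ivim(noisy, scheme)
            assert 0.0 <= res.params.f <= 0.8
            assert 0.0 <= res.params.d <= 5e-3
            assert 0.0 <= res.params.dp <= 80e-3
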