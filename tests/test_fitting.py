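"""Direction averaging and voxelwise model fitting."""

import numpy as np
import pytest

from qdwi.fitting import (FitConfig, average_directions, fit_ctrw,
                          fit_ivim_segmented, fit_mono, fit_parameter_maps,
                          fit_sem)
from qdwi.models import (CTRWParams, IVIMParams, MonoParams, SEMParams,
                         ctrw_signal, ivim_signal, mono_signal, sem_signal)
from qdwi.scheme import DWISignal


def _sig(scheme, curve, s0=1.0):
    return DWISignal(scheme, s0, np.asarray(curve) * s0)


class TestAverageDirections:
    def test_equal_values_pass_through(self, scheme):
        vol = np.full((2, scheme.n_b, scheme.n_directions), 3.5)
        out = average_directions(vol, scheme)
        np.testing.assert_allclose(out.data, 3.5)
        assert out.valid.all() and out.n_excluded == 0

    def test_geometric_mean_of_two_groups(self, scheme):
        sch = scheme.__class__(scheme.b_values, 2)
        vol = np.stack([np.full((sch.n_b,), np.e),
                        np.full((sch.n_b,), np.e ** 3)], axis=-1)[None]
        out = average_directions(vol, sch)
        # b=0 passes through arithmetically, b>0 shells geometrically
        assert out.data[0, 0] == pytest.approx((np.e + np.e ** 3) / 2)
        np.testing.assert_allclose(out.data[0, 1:], np.e ** 2, rtol=1e-12)

    def test_matches_log_domain_oracle(self, scheme, rng):
        vol = rng.lognormal(0.0, 0.3, size=(4, scheme.n_b,
                                            scheme.n_directions))
        out = average_directions(vol, scheme)
        expected = np.exp(np.log(vol).mean(axis=-1))
        np.testing.assert_allclose(out.data[:, 1:], expected[:, 1:],
                                   rtol=1e-12)

    def test_nonpositive_excluded_and_flagged(self, scheme):
        vol = np.full((1, scheme.n_b, scheme.n_directions), 2.0)
        vol[0, 3, 0] = -1.0                       # one bad direction
        vol[0, 5, :] = 0.0                        # a fully dead shell
        out = average_directions(vol, scheme)
        assert out.data[0, 3] == pytest.approx(2.0)
        assert not out.valid[0, 5]
        assert out.n_excluded == 1 + scheme.n_directions


class TestRoundTrips:
    """Noiseless signals on the 13-b scheme are recovered to contract."""

    def test_mono(self, scheme):
        res = fit_mono(_sig(scheme, mono_signal(scheme.b, MonoParams(1.2))))
        assert res.params.adc == pytest.approx(1.2, abs=1e-4)

    def test_ivim(self, scheme):
        for d, dstar, f in [(1.0, 10.0, 0.1), (0.983, 7.298, 0.089)]:
            res = fit_ivim_segmented(
                _sig(scheme, ivim_signal(scheme.b, IVIMParams(d, dstar, f))))
            assert res.params.d == pytest.approx(d, rel=1e-2)
            assert res.params.d_star == pytest.approx(dstar, rel=1e-2)
            assert res.params.f == pytest.approx(f, abs=1e-3)

    def test_sem(self, scheme):
        res = fit_sem(_sig(scheme, sem_signal(scheme.b,
                                              SEMParams(1.117, 0.867))))
        assert res.params.ddc == pytest.approx(1.117, rel=1e-3)
        assert res.params.alpha == pytest.approx(0.867, rel=1e-3)

    def test_ctrw(self, scheme):
        res = fit_ctrw(_sig(scheme, ctrw_signal(
            scheme.b, CTRWParams(1.218, 0.825, 0.938))))
        assert res.params.dm == pytest.approx(1.218, rel=1e-2)
        assert res.params.alpha == pytest.approx(0.825, rel=1e-2)
        assert res.params.beta == pytest.approx(0.938, rel=1e-2)

    def test_ctrw_optimality(self, scheme):
        truth = CTRWParams(1.218, 0.825, 0.938)
        y = ctrw_signal(scheme.b, truth)
        res = fit_ctrw(_sig(scheme, y))
        rss_truth = float(np.sum((ctrw_signal(scheme.b, truth) - y) ** 2))
        assert res.rss <= rss_truth + 1e-10


class TestReductions:
    def test_degenerate_constant_signal(self, scheme):
        res = fit_mono(_sig(scheme, np.ones(scheme.n_b)))
        assert res.params.adc == FitConfig().adc_bounds[0]
        assert "degenerate" in res.flags and not res.success

    def test_ivim_f_zero_reduces_to_mono(self, scheme):
        res = fit_ivim_segmented(
            _sig(scheme, mono_signal(scheme.b, MonoParams(1.1))))
        assert res.params.f == pytest.approx(0.0, abs=2e-3)
        assert res.params.d == pytest.approx(1.1, rel=1e-2)

    def test_sem_alpha_one_boundary(self, scheme):
        res = fit_sem(_sig(scheme, mono_signal(scheme.b, MonoParams(1.0))))
        assert res.params.alpha >= 0.999

    def test_ctrw_alpha_beta_one_boundary(self, scheme):
        res = fit_ctrw(_sig(scheme, mono_signal(scheme.b, MonoParams(1.0))))
        assert res.params.alpha >= 0.99 and res.params.beta >= 0.99


def _rician_curve(y, snr, rng):
    return np.sqrt((y + rng.standard_normal(y.size) / snr) ** 2
                   + (rng.standard_normal(y.size) / snr) ** 2)


def _noisy_sig(scheme, y, snr, rng):
    c = _rician_curve(y, snr, rng)
    # normalized by the measured (noisy) b=0 value, as in the map pipeline
    return DWISignal(scheme, c[0], c)


class TestNoisyRecovery:
    def test_mono_snr50_mean_within_2pct(self, scheme, rng):
        y = mono_signal(scheme.b, MonoParams(1.088))
        fits = [fit_mono(_noisy_sig(scheme, y, 50.0, rng)).params.adc
                for _ in range(200)]
        assert np.mean(fits) == pytest.approx(1.088, rel=0.02)

    def test_rmse_degrades_monotonically_with_noise(self, scheme, rng):
        y = mono_signal(scheme.b, MonoParams(1.088))
        rmse = []
        for snr in (200.0, 100.0, 50.0, 25.0):
            errs = [fit_mono(_noisy_sig(scheme, y, snr, rng)).params.adc
                    - 1.088 for _ in range(120)]
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert np.all(np.diff(rmse) > 0)

    def test_sem_alpha_median_bias(self, scheme, rng):
        y = sem_signal(scheme.b, SEMParams(1.117, 0.867))
        fits = [fit_sem(_noisy_sig(scheme, y, 50.0, rng)).params.alpha
                for _ in range(150)]
        assert abs(np.median(fits) - 0.867) <= 0.02


class TestParameterMaps:
    def _phantom(self, scheme):
        """5x5x1 phantom, two diffusivity regions, CTRW truth."""
        vol = np.zeros((5, 5, 1, scheme.n_b))
        truth = {}
        for i in range(5):
            for j in range(5):
                dm = 0.9 if i < 2 else 1.4
                truth[(i, j)] = dm
                vol[i, j, 0] = 1000.0 * mono_signal(scheme.b, MonoParams(dm))
        return vol, truth

    def test_two_region_phantom(self, scheme):
        vol, truth = self._phantom(scheme)
        mask = np.ones((5, 5, 1), dtype=bool)
        maps = fit_parameter_maps(vol, scheme, mask, "mono")
        assert len(maps) == 1 and maps[0].valid.all()
        for (i, j), dm in truth.items():
            assert maps[0].data[i, j, 0] == pytest.approx(dm, rel=1e-3)
        lo, hi = FitConfig().adc_bounds
        assert np.all((maps[0].data[mask] >= lo) & (maps[0].data[mask] <= hi))

    def test_empty_mask(self, scheme):
        vol, _ = self._phantom(scheme)
        maps = fit_parameter_maps(vol, scheme,
                                  np.zeros((5, 5, 1), bool), "mono")
        assert not maps[0].valid.any()
        assert np.all(np.isnan(maps[0].data))

    def test_corrupted_voxel_isolated(self, scheme):
        vol, truth = self._phantom(scheme)
        vol[2, 2, 0] = 0.0                   # dead voxel
        mask = np.ones((5, 5, 1), dtype=bool)
        maps = fit_parameter_maps(vol, scheme, mask, "mono")
        assert not maps[0].valid[2, 2, 0]
        assert maps[0].valid.sum() == mask.sum() - 1
        assert maps[0].data[0, 0, 0] == pytest.approx(truth[(0, 0)], rel=1e-3)

    def test_validity_accounts_for_every_masked_voxel(self, scheme):
        vol, _ = self._phantom(scheme)
        mask = np.zeros((5, 5, 1), dtype=bool)
        mask[1:4, 1:4, 0] = True
        for model in ("mono", "sem"):
            maps = fit_parameter_maps(vol, scheme, mask, model)
            assert (maps[0].valid | ~mask).all()
            assert np.isnan(maps[0].data[~mask]).all()


def test_fitconfig_validation(scheme):
    with pytest.raises(ValueError):
        FitConfig(adc_bounds=(2.0, 1.0))
    with pytest.raises(ValueError):
        FitConfig(ivim_split_b=123.0).check_scheme(scheme)
    FitConfig(ivim_split_b=200.0).check_scheme(scheme)
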