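"""Mono-exponential T2* fitting."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from placentaging import (
    MultiEchoVolume,
    PhantomSpec,
    T2StarMap,
    fit_volume,
    fit_voxel,
    masked_mean_t2s,
    simulate_multiecho_volume,
)
from placentaging.relaxometry import EmptyMaskError

from conftest import TE


def loglinear_t2s(te, signals):
    """Independent closed-form oracle: unweighted log-linear regression."""
    slope, _ = np.polyfit(te, np.log(signals), 1)
    return -1.0 / slope


class TestFitVoxel:
    @pytest.mark.parametrize("t2s_true", [10, 25, 60, 100, 150, 200, 250, 290])
    def test_noiseless_recovery_matches_closed_form(self, t2s_true):
        signals = 100.0 * np.exp(-TE / t2s_true)
        s0, t2s, valid = fit_voxel(TE, signals)
        assert valid
        assert abs(t2s - t2s_true) / t2s_true < 1e-4
        assert abs(s0 - 100.0) < 1e-3
        assert abs(t2s - loglinear_t2s(TE, signals)) / t2s_true < 1e-4

    def test_two_echo_closed_form(self):
        te2 = TE[:2]
        signals = 80.0 * np.exp(-te2 / 77.7)
        _, t2s, valid = fit_voxel(te2, signals)
        oracle = (te2[1] - te2[0]) / np.log(signals[0] / signals[1])
        assert valid and abs(t2s - oracle) < 1e-6

    def test_no_decay_clips_to_ceiling(self):
        s0, t2s, valid = fit_voxel(TE, np.full(4, 50.0))
        assert valid and t2s == 300.0

    def test_unclipped_no_decay_exceeds_ceiling(self):
        _, t2s, valid = fit_voxel(TE, np.full(4, 50.0), clip_ceiling=None)
        assert valid and t2s > 300.0

    @pytest.mark.parametrize(
        "signals",
        [np.zeros(4), np.full(4, np.nan), np.array([0.0, -1.0, 0.0, -2.0]),
         np.array([100.0, np.inf, 50.0, 20.0])],
    )
    def test_degenerate_signals_flagged_invalid(self, signals):
        *_, valid = fit_voxel(TE, signals)
        assert not valid

    def test_nonpositive_echo_excluded_not_fatal(self):
        # 3 usable echoes remain -> fit proceeds on them
        clean = 100.0 * np.exp(-TE / 60.0)
        dirty = clean.copy()
        dirty[2] = -4.0
        _, t2s, valid = fit_voxel(TE, dirty)
        assert valid
        keep = [0, 1, 3]
        assert abs(t2s - loglinear_t2s(TE[keep], clean[keep])) < 1e-3

    def test_nonincreasing_echo_times_rejected(self):
        with pytest.raises(ValueError):
            fit_voxel(np.array([13.8, 13.8, 127.0, 183.6]), np.ones(4))

    def test_matches_scipy_lm_on_noisy_series(self):
        # independent route: scipy's Levenberg-Marquardt on the same model
        rng = np.random.default_rng(0)
        for _ in range(10):
            t2s_true = rng.uniform(20, 250)
            y = rng.uniform(50, 150) * np.exp(-TE / t2s_true) + rng.normal(0, 1.0, 4)
            if (y <= 0).any():
                continue
            _, t2s, valid = fit_voxel(TE, y, clip_ceiling=None)
            popt, _ = curve_fit(
                lambda t, s0, r: s0 * np.exp(-t * r), TE, y,
                p0=[y[0], 1.0 / 50.0], method="lm", maxfev=2000,
            )
            assert valid
            assert abs(t2s - 1.0 / popt[1]) / (1.0 / popt[1]) < 1e-4


class TestFitVolume:
    def test_noiseless_phantom_voxelwise(self):
        spec = PhantomSpec(grid_shape=(24, 24, 3), snr=np.inf, texture_scale=0.04)
        vol, mask = simulate_multiecho_volume(
            {"subject_id": "a", "mean_t2s": 90.0}, spec, seed=1
        )
        out = fit_volume(vol)
        truth = (vol.echo_times[-1] - vol.echo_times[0]) / np.log(
            vol.data[..., 0] / np.maximum(vol.data[..., -1], 1e-30)
        )
        assert np.abs(out.t2s[mask] - truth[mask]).max() < 1e-4
        assert abs(masked_mean_t2s(out, mask) - 90.0) < 0.1

    def test_fluid_clipped_to_300(self):
        from placentaging.phantom import _ellipsoid_mask

        spec = PhantomSpec(grid_shape=(48, 48, 4), snr=np.inf, fluid_t2s=1000.0)
        vol, mask = simulate_multiecho_volume(
            {"subject_id": "a", "mean_t2s": 80.0}, spec, seed=1
        )
        out = fit_volume(vol)
        fluid = _ellipsoid_mask(spec.grid_shape, spec.fluid_center, spec.fluid_semiaxes) & ~mask
        assert fluid.any()
        assert np.all(out.t2s[fluid & out.valid] == 300.0)

    def test_clip_count_matches_unclipped_run(self):
        rng = np.random.default_rng(4)
        t2s_true = rng.uniform(100, 500, size=(6, 6, 2))
        data = 100.0 * np.exp(-TE[None, None, None, :] / t2s_true[..., None])
        vol = MultiEchoVolume(data, TE)
        clipped = fit_volume(vol)
        raw = fit_volume(vol, clip_ceiling=None)
        assert (clipped.t2s == 300.0).sum() == (raw.t2s > 300.0).sum()
        # clipping is idempotent and caps the map
        assert clipped.t2s[clipped.valid].max() <= 300.0
        assert np.array_equal(np.minimum(clipped.t2s, 300.0), clipped.t2s)

    def test_all_background_invalid(self):
        vol = MultiEchoVolume(np.zeros((4, 4, 2, 4)), TE)
        out = fit_volume(vol)
        assert not out.valid.any()

    def test_noise_consistency_at_snr50(self):
        spec = PhantomSpec(grid_shape=(48, 48, 4), snr=50.0, texture_scale=0.0)
        vol, mask = simulate_multiecho_volume(
            {"subject_id": "a", "mean_t2s": 80.0}, spec, seed=2
        )
        out = fit_volume(vol)
        err = np.abs(out.t2s[mask & out.valid] - 80.0) / 80.0
        assert np.median(err) < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MultiEchoVolume(np.ones((4, 4, 2, 3)), TE)
        with pytest.raises(ValueError):
            MultiEchoVolume(np.ones((4, 4, 8)), TE)


class TestMaskedMean:
    def _map(self, values):
        arr = np.asarray(values, dtype=float)
        return T2StarMap(t2s=arr, s0=np.ones_like(arr), valid=np.ones(arr.shape, bool))

    def test_uniform_and_mixed_regions(self):
        m = self._map(np.full((4, 4, 2), 80.0))
        assert masked_mean_t2s(m, np.ones((4, 4, 2), bool)) == 80.0
        half = np.full((4, 4, 2), 60.0)
        half[2:] = 100.0
        assert masked_mean_t2s(self._map(half), np.ones((4, 4, 2), bool)) == 80.0

    def test_empty_intersection_raises(self):
        m = self._map(np.full((4, 4, 2), 80.0))
        m.valid[:] = False
        with pytest.raises(EmptyMaskError):
            masked_mean_t2s(m, np.ones((4, 4, 2), bool))

    def test_shape_mismatch(self):
        m = self._map(np.full((4, 4, 2), 80.0))
        with pytest.raises(ValueError):
            masked_mean_t2s(m, np.ones((3, 4, 2), bool))
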