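"""Conditioning chain: MARA correction, band-stop filtering, detrending."""

import numpy as np
import pytest

from trfnirs.hrf import build_regressor
from trfnirs.paradigm import BlockDesign, build_timeline
from trfnirs.preprocess import (
    FilterSpec,
    MaraSpec,
    PreprocessError,
    bandstop_filter,
    bandstop_response_db,
    detrend,
    mara_correct,
    preprocess_series,
)
from trfnirs.simulate import (
    ArtifactSpec,
    SignalSimConfig,
    inject_motion_artifacts,
    simulate_activation_series,
    simulate_rest_series,
)

FS = 1.0 / 0.3


def _times(n=1100):
    return np.arange(n) * 0.3


class TestBandstop:
    def test_physio_lines_attenuated_20_db(self):
        db = bandstop_response_db([0.1, 0.2, 1.0])
        assert (db <= -20.0).all()

    def test_task_fundamental_within_1_db(self):
        db = bandstop_response_db([1.0 / 60.0])
        assert abs(db[0]) <= 1.0

    def test_mayer_sinusoid_residual_below_10_percent(self):
        t = _times()
        x = np.sin(2 * np.pi * 0.1 * t)
        y = bandstop_filter(x)
        c = slice(150, 950)  # away from edges
        assert np.std(y[c]) <= 0.10 * np.std(x[c])

    def test_task_sinusoid_preserved_within_1_percent(self):
        t = _times()
        x = np.sin(2 * np.pi * t / 60.0)
        y = bandstop_filter(x)
        c = slice(150, 950)
        assert np.std(y[c]) == pytest.approx(np.std(x[c]), rel=0.01)

    def test_dc_series_unchanged(self):
        y = bandstop_filter(np.full(600, 3.7))
        np.testing.assert_allclose(y, 3.7, rtol=1e-6)

    def test_stop_band_above_nyquist_rejected(self):
        with pytest.raises(PreprocessError):
            bandstop_filter(np.zeros(100), FilterSpec(stop_band_hz=(0.08, 2.0)))


class TestDetrend:
    def test_pure_ramp_zeroed(self):
        out = detrend(np.linspace(0, 10, 300))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_ramp_plus_sinusoid_recovers_sinusoid(self):
        t = _times(600)
        sin = np.sin(2 * np.pi * 0.05 * t)
        out = detrend(sin + 0.03 * t + 2.0)
        assert np.std(out) == pytest.approx(np.std(sin), rel=0.01)

    def test_zero_series_stays_zero(self):
        np.testing.assert_allclose(detrend(np.zeros(50)), 0.0, atol=1e-12)

    def test_output_mean_near_zero(self, rng):
        out = detrend(rng.normal(2.0, 1.0, 400) + np.linspace(0, 5, 400))
        assert abs(out.mean()) < 1e-8


class TestMara:
    def _clean(self, seed=0):
        return simulate_rest_series(SignalSimConfig(
            noise_sd=2.0, activation_amplitude=0.0, seed=seed))

    def test_artifact_free_series_untouched(self):
        x = self._clean(3)
        out, segs = mara_correct(x)
        np.testing.assert_array_equal(out, x)
        assert segs == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 5, 8])
    def test_spike_detected_and_sd_preserved(self, seed):
        x = self._clean(seed)
        corrupt, mask = inject_motion_artifacts(
            x, ArtifactSpec(n_spikes=1, spike_amplitude_sd=10.0), seed=seed + 100)
        fixed, segs = mara_correct(corrupt)
        k = np.flatnonzero(mask)[0]
        assert any(lo <= k < hi for lo, hi in segs)
        assert fixed.std() == pytest.approx(x.std(), rel=0.20)

    @pytest.mark.parametrize("seed", [0, 1, 2, 5, 8])
    def test_baseline_shift_reduced_80_percent(self, seed):
        x = self._clean(seed)
        corrupt, mask = inject_motion_artifacts(
            x, ArtifactSpec(n_shifts=1), seed=seed + 200)
        fixed, _ = mara_correct(corrupt)
        k = np.flatnonzero(mask)[0]
        step = lambda y: np.mean(y[k:]) - np.mean(y[:k])  # noqa: E731
        injected = step(corrupt) - step(x)
        residual = step(fixed) - step(x)
        assert abs(residual) <= 0.20 * abs(injected)

    def test_invalid_window_rejected(self):
        with pytest.raises(PreprocessError):
            mara_correct(np.zeros(10), MaraSpec(moving_window_s=10.0))


class TestChain:
    def test_filter_and_detrend_linear(self, rng):
        a = rng.normal(size=700)
        b = rng.normal(size=700)
        fa = detrend(bandstop_filter(a))
        fb = detrend(bandstop_filter(b))
        fab = detrend(bandstop_filter(a + 2 * b))
        np.testing.assert_allclose(fab, fa + 2 * fb, atol=1e-8)

    def test_activation_structure_survives_chain(self, design):
        # conditioning must not cost the correlation feature > 0.05
        # relative to the unfiltered series (low-noise activation run)
        reg = build_regressor(design)
        x, _ = simulate_activation_series(
            SignalSimConfig(design=design, noise_sd=1.0, seed=31))
        raw_r = np.corrcoef(x, reg)[0, 1]
        out = preprocess_series(x, design.frame_interval_s)
        chain_r = np.corrcoef(out, reg)[0, 1]
        assert chain_r > raw_r - 0.05

    def test_chain_order_is_mara_filter_detrend(self, design):
        # a large spike would leak through the zero-phase filter as ringing
        # if MARA ran after it; verify the chain output is spike-free
        x = 5.0 * build_regressor(design)
        corrupt, mask = inject_motion_artifacts(
            x + simulate_rest_series(SignalSimConfig(
                noise_sd=1.0, activation_amplitude=0.0, seed=9)),
            ArtifactSpec(n_spikes=1, spike_amplitude_sd=15.0), seed=21)
        out = preprocess_series(corrupt, design.frame_interval_s)
        k = np.flatnonzero(mask)[0]
        assert abs(out[k]) < 8.0  # spike (>= 15 SD) removed before filtering
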