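"""Filtering, baseline correction, epoching and feature construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from nirsemo.io import RunConfig
from nirsemo.optics import HemoSeries
from nirsemo.pipeline import preprocess_recording
from nirsemo.preprocessing import (
    bandpass,
    baseline_correct,
    build_features,
    extract_samples,
    validate_events,
)
from nirsemo.synthetic import NoiseModel, SimDesign, gen_recording

FS = 50.0


def _filtfilt_gain(freq_hz: float, fs: float = FS) -> float:
    """Independent oracle: squared-magnitude response of the zero-phase filter."""
    sos = signal.butter(4, [0.01, 0.2], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)  # forward-backward application squares |H|


class TestBandpass:
    def test_constant_input_removed(self):
        out = bandpass(np.full(30000, 5.0), fs=FS)
        n = len(out)
        core = out[n // 4 : -n // 4]
        assert np.max(np.abs(core)) < 1e-6 * 5.0

    @pytest.mark.parametrize(
        "freq,lo,hi",
        [(0.1, 0.9, 1.1), (1.2, 0.0, 0.05)],  # passband vs cardiac rejection
    )
    def test_gain_against_frequency_response_oracle(self, freq, lo, hi):
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, fs=FS)
        core = slice(len(t) // 3, 2 * len(t) // 3)
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert lo <= gain <= hi
        assert gain == pytest.approx(_filtfilt_gain(freq), abs=0.02)

    def test_invalid_band_errors(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(x, low_hz=0.2, high_hz=0.01, fs=FS)
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(x, low_hz=0.01, high_hz=30.0, fs=FS)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.zeros(10), fs=FS)


def _hemo(data, fs=FS):
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    return HemoSeries(
        hbo=arr, hbr=np.zeros_like(arr), fs=fs,
        channel_id=np.arange(1, arr.shape[0] + 1),
    )


def _events(onset, offset, clip_id="c1", condition="positive"):
    return pd.DataFrame(
        {"clip_id": [clip_id], "onset_s": [onset], "offset_s": [offset],
         "condition": [condition]}
    )


class TestBaselineCorrect:
    def test_segment_equal_to_baseline_mean_becomes_zero(self):
        x = np.full(int(60 * FS), 3.7)
        out = baseline_correct(_hemo(x), _events(20.0, 50.0))
        on, off = int(20 * FS), int(50 * FS)
        assert np.allclose(out.hbo[0, on:off], 0.0)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(60 * FS))
        ev = _events(20.0, 50.0)
        a = baseline_correct(_hemo(x), ev)
        b = baseline_correct(_hemo(x + 11.5), ev)
        on, off = int(20 * FS), int(50 * FS)
        assert np.allclose(a.hbo[0, on:off], b.hbo[0, on:off])

    def test_ramp_baseline_matches_arithmetic_mean(self):
        # 10-s linear ramp right before onset: baseline = its plain mean
        n = int(60 * FS)
        x = np.zeros(n)
        on = int(20 * FS)
        ramp = np.linspace(0.0, 1.0, int(10 * FS))
        x[on - len(ramp):on] = ramp
        x[on:] = 5.0
        out = baseline_correct(_hemo(x), _events(20.0, 50.0))
        assert out.hbo[0, on] == pytest.approx(5.0 - ramp.mean())

    def test_insufficient_prestim_names_clip(self):
        with pytest.raises(ValueError, match="clip early"):
            baseline_correct(
                _hemo(np.zeros(int(40 * FS))), _events(5.0, 35.0, clip_id="early")
            )


class TestExtractSamples:
    def test_70s_clip_gives_three_500_point_windows(self):
        x = np.zeros((1, int(100 * FS)))
        windows = extract_samples(_hemo(x), _events(20.0, 90.0))
        assert len(windows) == 3
        assert all(w.hbo.shape == (1, 500) for w in windows)
        assert [w.sample_index for w in windows] == [1, 2, 3]

    def test_six_clips_give_eighteen_windows(self):
        evs = pd.DataFrame(
            {
                "clip_id": [f"c{i}" for i in range(6)],
                "onset_s": [20 + 80.0 * i for i in range(6)],
                "offset_s": [60 + 80.0 * i for i in range(6)],
                "condition": ["negative"] * 6,
            }
        )
        x = np.zeros((1, int(520 * FS)))
        windows = extract_samples(_hemo(x), evs)
        assert len(windows) == 18  # 3 windows x 6 clips = 18 samples/category

    def test_windows_tile_last_30s_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, int(100 * FS)))
        h = _hemo_2ch(x)
        windows = extract_samples(h, _events(20.0, 90.0))
        tiled = np.concatenate([w.hbo for w in windows], axis=1)
        off = int(90 * FS)
        assert np.array_equal(tiled, x[:, off - 1500 : off])

    def test_short_clip_is_an_error(self):
        x = np.zeros((1, int(60 * FS)))
        with pytest.raises(ValueError, match="29.9"):
            extract_samples(_hemo(x), _events(20.0, 49.9))


def _hemo_2ch(arr):
    return HemoSeries(
        hbo=arr, hbr=np.zeros_like(arr), fs=FS, channel_id=np.array([1, 2])
    )


class TestBuildFeatures:
    def test_constant_channel_maps_to_its_value(self):
        x = np.zeros((24, int(100 * FS)))
        x[5] = 2.25
        h = HemoSeries(x, np.zeros_like(x), FS, np.arange(1, 25))
        windows = extract_samples(h, _events(20.0, 90.0))
        feats = build_features(windows, participant_id="p")
        hbo = [f for f in feats if f.chromophore == "HbO"]
        assert all(len(f.vector) == 24 for f in feats)
        assert all(f.vector[5] == pytest.approx(2.25) for f in hbo)

    def test_mean_matches_arithmetic_oracle(self):
        from nirsemo.preprocessing import SampleWindow

        w = SampleWindow(
            clip_id="c", condition="positive", sample_index=1,
            hbo=np.array([[1.0, 2.0, 6.0]]), hbr=np.array([[0.0, 0.0, 3.0]]),
        )
        feats = build_features([w], "p", n_channels=1)
        by = {f.chromophore: f for f in feats}
        assert by["HbO"].vector[0] == pytest.approx(3.0)
        assert by["HbR"].vector[0] == pytest.approx(1.0)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, int(100 * FS)))
        h = _hemo_2ch(x)
        hr = _hemo_2ch(x[:, ::-1].copy())
        ev = _events(20.0, 90.0)
        f1 = build_features(extract_samples(h, ev), "p", n_channels=2)
        # reversing each window's samples leaves the time-mean unchanged
        windows = extract_samples(h, ev)
        for w in windows:
            object.__setattr__(w, "hbo", w.hbo[:, ::-1])
        f2 = build_features(windows, "p", n_channels=2)
        for a, b in zip(f1, f2):
            assert np.allclose(a.vector, b.vector)

    def test_missing_channels_error(self):
        x = np.zeros((2, int(100 * FS)))
        windows = extract_samples(_hemo_2ch(x), _events(20.0, 90.0))
        with pytest.raises(ValueError, match="channels"):
            build_features(windows, "p", n_channels=24)


class TestEventValidation:
    def test_overlap_and_lead_in_checks(self):
        ev = pd.DataFrame(
            {
                "clip_id": ["a", "b"],
                "onset_s": [20.0, 45.0],
                "offset_s": [50.0, 80.0],
                "condition": ["positive", "positive"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            validate_events(ev)
        ev2 = ev.copy()
        ev2.loc[0, "onset_s"] = 2.0
        ev2.loc[0, "offset_s"] = 32.0
        ev2.loc[1, "onset_s"] = 100.0
        ev2.loc[1, "offset_s"] = 130.0
        with pytest.raises(ValueError, match="onset"):
            validate_events(ev2)


class TestEndToEndRecovery:
    def test_injected_activation_recovered_after_filter_attenuation(self):
        """Pipeline features track the band-passed ground truth within 15%."""
        quiet = NoiseModel(
            cardiac_amp=0, resp_amp=0, mayer_amp=0, drift_sd=0, white_sd=0,
            measurement_sd=0,
        )
        design = SimDesign(
            n_participants=1, fs=10.0, noise=quiet,
            clip_amp_range=(1.0, 1.0), participant_scale_range=(1.0, 1.0),
            duration_range_s=(40.0, 60.0), rest_jitter_s=0.0,
        )
        raw, truth = gen_recording(design, 0, seed=3)
        config = RunConfig(fs=10.0)
        feats = preprocess_recording(raw, config, participant_id="p")

        # oracle: identical filter/baseline/window pipeline on the clean truth
        clean = truth.clean_concentration()
        filt = bandpass(clean.hbo, fs=design.fs, axis=-1)
        hemo = HemoSeries(filt, np.zeros_like(filt), design.fs, clean.channel_id)
        hemo = baseline_correct(hemo, raw.events)
        expected = build_features(
            extract_samples(hemo, raw.events), "p", n_channels=design.n_channels
        )
        got = {(f.clip_id, f.sample_index): f for f in feats if f.chromophore == "HbO"}
        errs = []
        for e in expected:
            if e.chromophore != "HbO":
                continue
            ref = np.abs(e.vector).max()
            if ref < 0.05:  # skip near-zero channels (neutral clip)
                continue
            diff = np.abs(got[(e.clip_id, e.sample_index)].vector - e.vector).max()
            errs.append(diff / ref)
        assert np.mean(errs) < 0.15
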