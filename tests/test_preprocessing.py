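"""Preprocessing pipeline: filter frequency response, segmentation geometry,
bad-trial detection, normalisation/clamping, and stage ordering."""

import numpy as np
import pytest

from vepdecode.preprocessing import (BadTrialCriteria, EpochSet, FilterSpec,
                                     detect_bad_trials, filter_raw,
                                     normalize_clamp, preprocess_session,
                                     segment_trials)
from vepdecode.sim import (ChannelLayout, EventList, RawRecording, SessionSpec,
                           VEPModel, inject_artifacts, make_session_events,
                           synthesize_recording)


def _recording_from_signal(sig, spec):
    events = make_session_events(spec, seed=0)
    return RawRecording(signal=sig, fs_hz=spec.fs_hz, layout=ChannelLayout(),
                        events=events)


def _tone_recording(freq, fs=250.0, dur_s=70.0):
    spec = SessionSpec(n_classes=2, images_per_class=2, fs_hz=fs, lead_in_s=1.0)
    n = int(dur_s * fs)
    t = np.arange(n) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t), (8, 1))
    return _recording_from_signal(sig, spec), spec


def _fft_amplitude(x, freq, fs):
    n = len(x)
    window = np.hanning(n)
    spectrum = np.abs(np.fft.rfft(x * window))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return spectrum[np.argmin(np.abs(freqs - freq))]


class TestFilterResponse:
    def test_60hz_attenuated_at_least_30db(self):
        rec, _ = _tone_recording(60.0)
        out = filter_raw(rec)
        # compare steady-state interior (skip filter edges)
        sl = slice(2500, -2500)
        a_in = _fft_amplitude(rec.signal[0, sl], 60.0, 250.0)
        a_out = _fft_amplitude(out.signal[0, sl], 60.0, 250.0)
        assert 20 * np.log10(a_in / a_out) >= 30.0

    def test_10hz_passband_change_below_1db(self):
        rec, _ = _tone_recording(10.0)
        out = filter_raw(rec)
        sl = slice(2500, -2500)
        a_in = _fft_amplitude(rec.signal[0, sl], 10.0, 250.0)
        a_out = _fft_amplitude(out.signal[0, sl], 10.0, 250.0)
        assert abs(20 * np.log10(a_in / a_out)) <= 1.0

    def test_constant_offset_removed_by_highpass(self):
        spec = SessionSpec(n_classes=2, images_per_class=2)
        sig = np.full((8, 5000), 42.0)
        rec = _recording_from_signal(sig, spec)
        out = filter_raw(rec)
        assert np.abs(out.signal.mean()) < 1e-6

    def test_zero_phase_preserves_symmetric_pulse_latency(self):
        spec = SessionSpec(n_classes=2, images_per_class=2)
        sig = np.zeros((8, 5000))
        centre = 2500
        width = np.arange(-100, 101)
        sig[:, centre + width] = np.exp(-0.5 * (width / 12.0) ** 2)
        rec = _recording_from_signal(sig, spec)
        out = filter_raw(rec)
        assert abs(int(np.argmax(out.signal[0])) - centre) <= 1

    def test_invalid_band_ordering_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(hp_hz=70, notch_hz=60, lp_hz=95).validate(250.0)

    def test_nan_confined_to_affected_channel(self, tiny_recording):
        rec = tiny_recording.copy()
        rec.signal[3, 1000] = np.nan
        out = filter_raw(rec)
        assert np.isnan(out.signal[3]).all()
        assert np.isfinite(out.signal[[0, 1, 2, 4, 5, 6, 7]]).all()


class TestSegmentation:
    def test_250hz_2s_exposure_gives_500_sample_epochs(self, tiny_recording):
        epochs = segment_trials(tiny_recording)
        assert epochs.data.shape[1:] == (8, 500)

    def test_one_epoch_per_event_with_aligned_labels(self, tiny_recording):
        epochs = segment_trials(tiny_recording)
        assert epochs.n_trials == len(tiny_recording.events)
        np.testing.assert_array_equal(epochs.labels,
                                      tiny_recording.events.class_ids)

    def test_unit_impulse_at_onset_appears_at_sample_zero(self, tiny_spec):
        events = make_session_events(tiny_spec, seed=0)
        sig = np.zeros((8, int(events.onsets[-1]) + 800))
        sig[:, events.onsets[4]] = 1.0
        rec = RawRecording(signal=sig, fs_hz=tiny_spec.fs_hz,
                           layout=ChannelLayout(), events=events)
        epochs = segment_trials(rec)
        assert epochs.data[4, 0, 0] == 1.0
        assert epochs.data[4, 0, 1:].sum() == 0.0

    def test_window_past_end_of_recording_names_event(self, tiny_spec):
        events = make_session_events(tiny_spec, seed=0)
        sig = np.zeros((8, int(events.onsets[-1]) + 100))  # too short
        rec = RawRecording.__new__(RawRecording)  # bypass length validation
        rec.signal, rec.fs_hz = sig, tiny_spec.fs_hz
        rec.layout, rec.events, rec.session_id = ChannelLayout(), events, "x"
        with pytest.raises(ValueError, match="event 19"):
            segment_trials(rec)


class TestBadTrials:
    def test_crafted_artifacts_flagged_with_reasons(self, tiny_recording):
        rec = inject_artifacts(tiny_recording,
                               [(1, "nan"), (4, "flat"), (9, "clone_channel")],
                               seed=1)
        mask = detect_bad_trials(segment_trials(rec))
        assert mask.flags[[1, 4, 9]].all()
        assert mask.reasons[1] == {"nan"}
        assert "flat" in mask.reasons[4]
        assert "corr_high" in mask.reasons[9]

    def test_clean_synthetic_trials_not_flagged(self, tiny_recording):
        mask = detect_bad_trials(segment_trials(tiny_recording))
        assert mask.n_flagged == 0
        assert mask.drop_rate == 0.0

    def test_independent_white_noise_trials_pass_default_criteria(self):
        """Null simulation (1000 trials of independent white noise): the
        default correlation thresholds must not fire."""
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1000, 8, 500))
        epochs = EpochSet(data=data, labels=np.zeros(1000, dtype=int),
                          retained=np.ones(1000, dtype=bool))
        mask = detect_bad_trials(epochs)
        assert mask.n_flagged == 0

    def test_criteria_bounds_validated(self):
        with pytest.raises(ValueError):
            BadTrialCriteria(corr_low=0.5, corr_high=0.4)


class TestNormalizeClamp:
    def test_mean_zero_sd_one_per_channel(self, tiny_recording):
        epochs = segment_trials(tiny_recording)
        out = normalize_clamp(epochs)
        ret = out.retained_data()
        np.testing.assert_allclose(ret.mean(axis=(0, 2)), 0, atol=1e-9)
        np.testing.assert_allclose(ret.std(axis=(0, 2)), 1, atol=1e-6)

    def test_25_sd_spike_clamped_to_20(self, tiny_recording):
        epochs = segment_trials(tiny_recording)
        sd = epochs.data[:, 0, :].std()
        mean = epochs.data[:, 0, :].mean()
        epochs.data[0, 0, 0] = mean + 25 * sd
        out = normalize_clamp(epochs)
        assert out.data.max() <= 20.0
        assert out.data[0, 0, 0] == pytest.approx(20.0, abs=0.2)

    def test_constant_channel_raises(self, tiny_recording):
        epochs = segment_trials(tiny_recording)
        epochs.data[:, 5, :] = 3.14
        with pytest.raises(ValueError, match="channel"):
            normalize_clamp(epochs)

    def test_normalized_epochs_rejected_by_detector(self, tiny_recording):
        out = normalize_clamp(segment_trials(tiny_recording))
        with pytest.raises(ValueError):
            detect_bad_trials(out)


class TestFullPipeline:
    def test_clean_high_snr_session_drops_nothing(self, tiny_recording):
        epochs, report = preprocess_session(tiny_recording)
        assert report.n_dropped == 0
        assert epochs.n_retained == epochs.n_trials

    def test_injected_nan_trials_reduce_retained_count(self, tiny_spec, tiny_model):
        events = make_session_events(tiny_spec, seed=11)
        rec = synthesize_recording(events, tiny_model, seed=12)
        rec = inject_artifacts(rec, [(0, "nan"), (5, "nan"), (12, "nan")],
                               seed=0)
        epochs, report = preprocess_session(rec)
        assert report.n_dropped == 3
        assert epochs.n_retained == len(events) - 3
        assert report.pct_dropped == pytest.approx(100 * 3 / len(events))

    def test_output_is_finite_and_bounded(self, tiny_recording):
        epochs, _ = preprocess_session(tiny_recording)
        ret = epochs.retained_data()
        assert np.isfinite(ret).all()
        assert np.abs(ret).max() <= 20.0

    def test_pipeline_is_deterministic(self, tiny_recording):
        a, _ = preprocess_session(tiny_recording)
        b, _ = preprocess_session(tiny_recording)
        np.testing.assert_array_equal(a.data, b.data)

    def test_majority_drop_warns_but_returns(self, tiny_spec, tiny_model, caplog):
        events = make_session_events(tiny_spec, seed=21)
        rec = synthesize_recording(events, tiny_model, seed=22)
        bad = [(i, "nan") for i in range(12)]        # 12 of 20 trials
        rec = inject_artifacts(rec, bad, seed=0)
        with caplog.at_level("WARNING"):
            epochs, report = preprocess_session(rec)
        assert report.n_dropped == 12
        assert any("dropped" in r.message for r in caplog.records)

    def test_mask_computed_before_filtering(self, tiny_spec, tiny_model):
        """A flat trial stays flagged even though filtering would disguise
        its flatness (ringing), because the mask comes from unfiltered data."""
        events = make_session_events(tiny_spec, seed=31)
        rec = synthesize_recording(events, tiny_model, seed=32)
        rec = inject_artifacts(rec, [(8, "flat")], seed=0)
        filtered = filter_raw(rec)
        post_mask = detect_bad_trials(segment_trials(filtered))
        epochs, report = preprocess_session(rec)
        assert not epochs.retained[8]
        # the filtered signal no longer looks flat on that channel
        assert "flat" not in post_mask.reasons[8]
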