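"""Synthetic session generator: event geometry, template fidelity, noise
statistics, artifact injection."""

import numpy as np
import pytest
from scipy import signal as sps

from vepdecode.sim import (ARTIFACT_KINDS, ChannelLayout, SessionSpec,
                           VEPModel, inject_artifacts, make_session_events,
                           synthesize_recording)


class TestEvents:
    def test_default_session_has_600_events_spanning_30_minutes(self):
        events = make_session_events(SessionSpec(), seed=0)
        assert len(events) == 600
        assert events.duration_s == pytest.approx(1800.0)   # 30 minutes

    def test_spacing_is_exactly_stim_plus_isi(self, tiny_spec):
        events = make_session_events(tiny_spec, seed=5)
        np.testing.assert_array_equal(np.diff(events.onsets),
                                      tiny_spec.trial_spacing_samples)

    def test_label_multiset_is_balanced_and_orders_differ_by_seed(self, tiny_spec):
        e1 = make_session_events(tiny_spec, seed=1)
        e2 = make_session_events(tiny_spec, seed=2)
        for e in (e1, e2):
            counts = np.bincount(e.class_ids, minlength=tiny_spec.n_classes)
            np.testing.assert_array_equal(counts, tiny_spec.images_per_class)
        assert not np.array_equal(
            np.stack([e1.class_ids, e1.image_ids]),
            np.stack([e2.class_ids, e2.image_ids]))

    def test_same_seed_reproduces_events(self, tiny_spec):
        e1 = make_session_events(tiny_spec, seed=9)
        e2 = make_session_events(tiny_spec, seed=9)
        np.testing.assert_array_equal(e1.class_ids, e2.class_ids)
        np.testing.assert_array_equal(e1.onsets, e2.onsets)

    def test_non_integer_sample_spacing_rejected(self):
        with pytest.raises(ValueError):
            SessionSpec(stim_dur_s=2.0007, fs_hz=250)


class TestRecording:
    def test_zero_noise_trials_equal_class_template(self, clean_recording):
        spec = clean_recording.events.spec
        model = VEPModel.default(n_classes=4, snr=2.0, seed=7).noiseless()
        for onset, cls in zip(clean_recording.events.onsets,
                              clean_recording.events.class_ids):
            window = clean_recording.signal[:, onset:onset + spec.stim_samples]
            template = model.class_template(int(cls), spec.fs_hz,
                                            spec.stim_samples)
            expected = model.spatial_signature[int(cls), :, None] * template
            np.testing.assert_array_equal(window, expected)

    def test_class_mean_epoch_equals_template_at_infinite_snr(self, clean_recording):
        spec = clean_recording.events.spec
        model = VEPModel.default(n_classes=4, snr=2.0, seed=7).noiseless()
        cls = 2
        onsets = clean_recording.events.onsets[
            clean_recording.events.class_ids == cls]
        epochs = np.stack([clean_recording.signal[:, o:o + spec.stim_samples]
                           for o in onsets])
        template = (model.spatial_signature[cls][:, None]
                    * model.class_template(cls, spec.fs_hz, spec.stim_samples))
        assert np.abs(epochs.mean(axis=0) - template).max() < 1e-12

    def test_n1_trough_precedes_p2_peak_in_every_class(self, clean_recording):
        spec = clean_recording.events.spec
        model = VEPModel.default(n_classes=4, snr=2.0, seed=7).noiseless()
        for cls in range(4):
            tpl = model.class_template(cls, spec.fs_hz, spec.stim_samples)
            assert tpl.argmin() < tpl.argmax()

    def test_same_seed_is_bit_identical(self, tiny_spec, tiny_model):
        events = make_session_events(tiny_spec, seed=1)
        a = synthesize_recording(events, tiny_model, seed=3)
        b = synthesize_recording(events, tiny_model, seed=3)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_noise_power_matches_welch_oracle(self):
        """Zero templates: per-channel power ~ white + pink + line components,
        checked against a Welch spectrum of a long noise-only recording."""
        spec = SessionSpec(n_classes=2, images_per_class=2, lead_in_s=120.0)
        model = VEPModel.default(2, snr=0.0, seed=7)
        model.shape_jitter_sd = 0.0
        events = make_session_events(spec, seed=0)
        rec = synthesize_recording(events, model, seed=1)
        x = rec.signal[0]
        f, pxx = sps.welch(x, fs=spec.fs_hz, nperseg=4096)
        total_var = np.trapezoid(pxx, f)
        expected = model.noise_sd_uv ** 2
        assert total_var == pytest.approx(expected, rel=0.15)
        # line component: a sharp peak at 60 Hz
        line_bin = np.argmin(np.abs(f - model.line_freq_hz))
        background = np.median(pxx[(f > 50) & (f < 58)])
        assert pxx[line_bin] > 10 * background

    def test_inter_trial_windows_contain_no_evoked_component(self, tiny_spec):
        model = VEPModel.default(4, snr=5.0, seed=7).noiseless()
        events = make_session_events(tiny_spec, seed=1)
        rec = synthesize_recording(events, model, seed=2)
        spec = tiny_spec
        for onset in events.onsets:
            gray = rec.signal[:, onset + spec.stim_samples:
                              onset + spec.trial_spacing_samples]
            assert np.abs(gray).max() == 0.0


class TestArtifacts:
    def test_each_kind_produces_its_signature(self, tiny_recording):
        spec = tiny_recording.events.spec
        rec = inject_artifacts(tiny_recording,
                               [(7, "nan"), (3, "flat"), (5, "clone_channel")],
                               seed=0)
        w = spec.stim_samples
        o = tiny_recording.events.onsets
        assert np.isnan(rec.signal[:, o[7]:o[7] + w]).sum() >= 1
        ptp = np.ptp(rec.signal[:, o[3]:o[3] + w], axis=1)
        assert ptp.min() == 0.0
        trial5 = rec.signal[:, o[5]:o[5] + w]
        corr = np.corrcoef(trial5)
        np.fill_diagonal(corr, 0)
        assert np.nanmax(np.abs(corr)) == pytest.approx(1.0)

    def test_empty_spec_is_identity_and_others_untouched(self, tiny_recording):
        rec = inject_artifacts(tiny_recording, [], seed=0)
        np.testing.assert_array_equal(rec.signal, tiny_recording.signal)
        rec2 = inject_artifacts(tiny_recording, [(7, "nan")], seed=0)
        o = tiny_recording.events.onsets
        w = tiny_recording.events.spec.stim_samples
        untouched = np.ones(tiny_recording.n_samples, dtype=bool)
        untouched[o[7]:o[7] + w] = False
        np.testing.assert_array_equal(rec2.signal[:, untouched],
                                      tiny_recording.signal[:, untouched])

    def test_out_of_range_trial_and_unknown_kind_rejected(self, tiny_recording):
        with pytest.raises(IndexError):
            inject_artifacts(tiny_recording, [(999, "nan")], seed=0)
        with pytest.raises(ValueError):
            inject_artifacts(tiny_recording, [(0, "zap")], seed=0)

    def test_kind_inventory(self):
        assert set(ARTIFACT_KINDS) == {"nan", "flat", "clone_channel", "burst"}


def test_layout_requires_8_unique_labels():
    with pytest.raises(ValueError):
        ChannelLayout(("O1", "O2"))
    assert ChannelLayout().names[0] == "PO8"
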