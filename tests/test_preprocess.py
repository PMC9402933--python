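"""Filtering, epoching, rejection, referencing and label derivation."""

import numpy as np
import pandas as pd
import pytest

from flickersart.containers import EpochSet, ProbeResponse
from flickersart.preprocess import (
    assign_labels,
    bandpass,
    baseline_correct,
    epoch,
    preprocess_session,
    reject_artifacts,
    rereference_average,
    segment,
)

FS = 512.0


def sinusoid_recording(freq, n_sec=10.0, amp=1.0):
    t = np.arange(int(n_sec * FS)) / FS
    return (amp * np.sin(2 * np.pi * freq * t))[None, :]


def make_epochs(data, tmin=-500.0, fs=FS, channels=None):
    data = np.asarray(data, dtype=float)
    times = tmin + np.arange(data.shape[2]) * 1000.0 / fs
    channels = channels or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data=data, times=times, fs=fs, channel_names=channels)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = sinusoid_recording(10.0)
        y = bandpass(x, FS)
        core = slice(int(2 * FS), int(8 * FS))  # avoid convolution edges
        ratio = np.abs(y[0, core]).max() / np.abs(x[0, core]).max()
        assert abs(ratio - 1.0) < 0.05

    def test_out_of_band_attenuated(self):
        x = sinusoid_recording(100.0)
        y = bandpass(x, FS)
        core = slice(int(2 * FS), int(8 * FS))
        assert np.sqrt(np.mean(y[0, core] ** 2)) < 0.1 * np.sqrt(
            np.mean(x[0, core] ** 2)
        )

    def test_dc_removed(self):
        x = np.full((1, int(10 * FS)), 50.0)
        y = bandpass(x, FS)
        core = slice(int(2 * FS), int(8 * FS))
        assert abs(y[0, core].mean()) < 1.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(sinusoid_recording(10), FS, low=0.5, high=300.0)


class TestEpoch:
    def events(self, samples):
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(samples)),
                "sample": samples,
                "trial_type": "go",
                "block": 0,
            }
        )

    def test_stated_convention_sample_count(self):
        rec = np.zeros((2, int(20 * FS)))
        ep = epoch(rec, self.events([4000]), FS, ["a", "b"])
        assert ep.n_samples == 2458  # floor(4800 * 0.512) + 1

    def test_impulse_lands_at_time_zero(self):
        rec = np.zeros((1, int(20 * FS)))
        rec[0, 4000] = 1.0
        ep = epoch(rec, self.events([4000]), FS, ["a"])
        nz = np.flatnonzero(ep.data[0, 0])
        assert nz.tolist() == [int(np.argmin(np.abs(ep.times)))]
        assert ep.times[nz[0]] == 0.0

    def test_edge_event_dropped_with_warning(self, caplog):
        rec = np.zeros((1, int(20 * FS)))
        with caplog.at_level("WARNING"):
            ep = epoch(rec, self.events([10, 4000]), FS, ["a"])
        assert ep.n_trials == 1
        assert "dropped" in caplog.text

    def test_zero_recording_gives_zero_epochs(self):
        rec = np.zeros((1, int(20 * FS)))
        ep = epoch(rec, self.events([4000, 5000]), FS, ["a"])
        assert not np.any(ep.data)


class TestBaselineAndSegment:
    def test_constant_epoch_zeroed(self):
        ep = make_epochs(np.full((2, 1, 564), 3.25))
        out = baseline_correct(ep, (-500, 0))
        assert np.allclose(out.data, 0.0)

    def test_window_mean_is_zero_for_ramp(self):
        n = 564
        ramp = np.linspace(0, 1, n)[None, None, :]
        ep = make_epochs(ramp)
        out = baseline_correct(ep, (-500, 0))
        mask = out.time_mask(-500, 0)
        assert abs(out.data[0, 0, mask].mean()) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((3, 2, 564)))
        once = baseline_correct(ep, (-500, 0))
        twice = baseline_correct(once, (-500, 0))
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_segment_sample_count(self):
        n_full = int(round(1800 * FS / 1000)) + 1  # -500..1300 ms
        ep = make_epochs(np.random.default_rng(1).standard_normal((2, 1, n_full)))
        out = segment(ep, -200, 900)
        assert out.n_samples == 564  # floor(1100 * 0.512) + 1

    def test_crop_of_crop_equals_single_crop(self):
        n_full = int(round(1800 * FS / 1000)) + 1
        ep = make_epochs(np.random.default_rng(2).standard_normal((2, 1, n_full)))
        one = segment(ep, -200, 900, rebaseline_window=None)
        two = segment(
            segment(ep, -300, 1000, rebaseline_window=None),
            -200, 900, rebaseline_window=None,
        )
        np.testing.assert_allclose(one.data, two.data)

    def test_out_of_span_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 564)))
        with pytest.raises(ValueError):
            segment(ep, -600, 900)


class TestRejectAndRereference:
    def test_clean_trials_kept(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(10 * rng.standard_normal((20, 3, 100)))
        out, keep = reject_artifacts(ep, 150.0)
        assert keep.all() and out.n_trials == 20

    def test_spike_trial_rejected(self):
        rng = np.random.default_rng(4)
        data = 10 * rng.standard_normal((10, 3, 100))
        data[4, 1, 50] = 500.0
        out, keep = reject_artifacts(make_epochs(data), 150.0)
        assert not keep[4] and keep.sum() == 9
        assert 4 not in out.trial_meta["trial_index"].to_numpy()

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(1000 * rng.standard_normal((5, 2, 50)))
        out, keep = reject_artifacts(ep, np.inf)
        assert keep.all()
        np.testing.assert_array_equal(out.data, ep.data)

    def test_all_rejected_raises(self):
        ep = make_epochs(np.full((3, 1, 50), 0.0))
        ep.data[:, 0, 0] = 1000.0
        with pytest.raises(ValueError):
            reject_artifacts(ep, 150.0)

    def test_average_reference_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(6)
        ep = make_epochs(rng.standard_normal((4, 5, 100)))
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12
        twice = rereference_average(out)
        np.testing.assert_allclose(out.data, twice.data, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        a = np.random.default_rng(7).standard_normal((2, 1, 100))
        ep = make_epochs(np.concatenate([a, -a], axis=1))
        out = rereference_average(ep)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(make_epochs(np.zeros((1, 1, 10))))


class TestAssignLabels:
    def probe(self, after, option, stickiness=None):
        return ProbeResponse(0, after, option, stickiness)

    def test_on_task_more_sticky_window(self):
        labels = assign_labels(20, [self.probe(10, 1, 7)])
        assert list(labels.attention_state[6:11]) == ["on_task"] * 5
        assert list(labels.stickiness_class[6:11]) == ["more_sticky"] * 5
        assert labels.attention_state[5] == "excluded"
        assert labels.attention_state[11] == "excluded"

    def test_midpoint_rating_excluded(self):
        labels = assign_labels(10, [self.probe(6, 3, 5)])
        assert labels.attention_state[6] == "mind_wandering"
        assert labels.stickiness_class[6] == "excluded"

    @pytest.mark.parametrize("option,expected", [
        (1, "on_task"), (2, "on_task"),
        (3, "mind_wandering"), (5, "mind_wandering"),
        (4, "excluded"), (6, "excluded"),
    ])
    def test_option_text_mapping(self, option, expected):
        labels = assign_labels(10, [self.probe(6, option, 2)])
        assert labels.attention_state[6] == expected

    def test_missing_rating_excluded(self):
        labels = assign_labels(10, [self.probe(6, 1, None)])
        assert labels.stickiness_class[6] == "excluded"

    def test_invalid_option_rejected(self):
        with pytest.raises(ValueError):
            ProbeResponse(0, 5, 7)

    def test_label_count_bound(self, small_session):
        labels = assign_labels(len(small_session.events), small_session.probes)
        n_labeled = (labels.attention_state != "excluded").sum()
        assert n_labeled <= len(small_session.probes) * 5


class TestFullChain:
    def test_shapes_and_alignment(self, small_pre):
        pre = small_pre
        assert pre.epochs_tf.n_samples == int(1800 * FS // 1000) + 1  # floor convention
        assert pre.epochs_erp.n_samples == 564
        assert pre.epochs_tf.n_trials == pre.epochs_erp.n_trials
        assert len(pre.labels) == pre.epochs_tf.n_trials
        # average reference holds on the tf epochs
        assert np.abs(pre.epochs_tf.data.mean(axis=1)).max() < 1e-9
        # erp epochs re-baselined on [-200, 0]
        mask = pre.epochs_erp.time_mask(-200, 0)
        base = pre.epochs_erp.data[:, :, mask].mean(axis=2)
        assert np.abs(base).max() < 1e-9

    def test_deterministic(self, small_session):
        a = preprocess_session(small_session)
        b = preprocess_session(small_session)
        np.testing.assert_array_equal(a.epochs_erp.data, b.epochs_erp.data)
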