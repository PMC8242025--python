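"""Behavioral filters, re-referencing, epoching, rejection, baseline."""

import math

import numpy as np
import pandas as pd
import pytest

from gfba.errors import ConfigError, DataError
from gfba.preprocess import (
    EpochSet,
    baseline_correct,
    extract_epochs,
    filter_behavior,
    reject_artifacts,
    rereference,
    summarize_behavior,
)
from gfba.synth import ContinuousRecording


def _toy_trials(rts, corrects, task="color", trial_type="PC"):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": 0,
            "task": task,
            "block": 0,
            "trial": range(n),
            "trial_id": range(n),
            "trial_type": trial_type,
            "repetition": "switch",
            "rt_ms": rts,
            "correct": pd.array(corrects, dtype="boolean"),
        }
    )


def _epochs(data, fs=100.0, t0=-20):
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[2]
    time_ms = (np.arange(n_samples) + t0) * 1000.0 / fs
    channels = tuple(f"PO{i}" for i in range(data.shape[1]))
    return EpochSet(
        data=data,
        time_ms=time_ms,
        channels=channels,
        sampling_rate=fs,
        trial_ids=np.arange(data.shape[0]),
    )


class TestFilterBehavior:
    def test_enumerated_flags(self):
        trials = _toy_trials([150, 250, 1400, 300], [True, True, True, False])
        out = filter_behavior(trials)
        assert out.anticipatory.tolist() == [True, False, False, False]
        assert out.delayed.tolist() == [False, False, True, False]
        assert out.incorrect.tolist() == [False, False, False, True]
        assert out.loc[out.erp_eligible, "rt_ms"].tolist() == [250]

    def test_thresholds_are_strict(self):
        out = filter_behavior(_toy_trials([200.0, 1300.0], [True, True]))
        assert not out.anticipatory.any()
        assert not out.delayed.any()
        assert out.erp_eligible.all()

    def test_missing_rt_flagged_invalid(self):
        out = filter_behavior(_toy_trials([np.nan, 400], [True, True]))
        assert out.invalid_rt.tolist() == [True, False]
        assert out.erp_eligible.tolist() == [False, True]


class TestSummarizeBehavior:
    def test_all_correct_gives_100_percent(self):
        out = summarize_behavior(filter_behavior(_toy_trials([300, 400], [True, True])))
        assert (out.accuracy_pct == 100.0).all()

    def test_hand_built_cells(self):
        trials = pd.concat(
            [
                _toy_trials([300, 500], [True, True], "color", "PC"),
                _toy_trials([400, 600], [True, False], "color", "DC"),
            ],
            ignore_index=True,
        )
        trials["trial_id"] = range(len(trials))
        out = summarize_behavior(filter_behavior(trials)).set_index(
            ["task", "trial_type"]
        )
        assert out.loc[("color", "PC"), "mean_rt_ms"] == 400.0
        assert out.loc[("color", "DC"), "mean_rt_ms"] == 400.0  # correct only
        assert out.loc[("color", "DC"), "accuracy_pct"] == 50.0

    def test_empty_cell_is_nan_and_magenta_excluded(self, quiet_subject):
        _, _, trials, _ = quiet_subject
        out = summarize_behavior(trials)
        assert set(out.trial_type) == {"PC", "DC", "nontarget"}
        assert len(out) == 6  # the 2 x 3 analysis frame


class TestRereference:
    def _recording(self, data, channels=("PO3", "M1", "M2")):
        return ContinuousRecording(
            channels=channels,
            sampling_rate=100.0,
            data=np.asarray(data, dtype=float),
            events=np.zeros((0, 2), dtype=int),
        )

    def test_zero_left_mastoid_is_identity(self):
        rec = self._recording([[1.0, 2.0], [0.0, 0.0], [0.5, 0.5]])
        out = rereference(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_constant_left_mastoid_shifts_all_channels(self):
        rec = self._recording([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
        out = rereference(rec)
        np.testing.assert_allclose(out.data[0], [0.0, 0.0])
        np.testing.assert_allclose(out.data[1], [1.0, 1.0])

    def test_implied_reference_is_mastoid_average(self):
        # true scalp potential s, mastoids m1 and r; online right-mastoid
        # reference records c - r per channel and 0 for the reference itself
        rng = np.random.default_rng(0)
        s, m1, r = rng.normal(size=(3, 50))
        rec = self._recording(np.stack([s - r, m1 - r, np.zeros(50)]))
        out = rereference(rec)
        np.testing.assert_allclose(out.data[0], s - (m1 + r) / 2.0, atol=1e-12)

    def test_missing_mastoid_is_named_error(self):
        rec = self._recording(np.zeros((2, 5)), channels=("PO3", "M2"))
        with pytest.raises(DataError, match="M1"):
            rereference(rec)


class TestExtractEpochs:
    def test_sample_count_at_acquisition_rate(self):
        # enumeration of the grid: samples with -200 <= m/fs*1000 < 700
        fs = 254.31
        expected = sum(1 for m in range(-1000, 1000) if -200 <= m * 1000 / fs < 700)
        assert expected == 229
        n = 3000
        rec = ContinuousRecording(
            channels=("PO3", "M1", "M2"),
            sampling_rate=fs,
            data=np.zeros((3, n)),
            events=np.array([[600, 0]]),
        )
        trials = pd.DataFrame({"trial_id": [0]})
        epochs = extract_epochs(rec, trials)
        assert epochs.data.shape == (1, 3, 229)
        onset = np.argmin(np.abs(epochs.time_ms))
        assert epochs.time_ms[onset] == 0.0

    def test_edge_event_dropped_with_warning(self, caplog):
        rec = ContinuousRecording(
            channels=("PO3", "M1", "M2"),
            sampling_rate=100.0,
            data=np.zeros((3, 200)),
            events=np.array([[0, 0], [100, 1]]),
        )
        trials = pd.DataFrame({"trial_id": [0, 1]})
        with caplog.at_level("WARNING"):
            epochs = extract_epochs(rec, trials, window_ms=(-200, 700))
        assert epochs.trial_ids.tolist() == [1]  # only the interior event
        assert "edge" in caplog.text


class TestRejectArtifacts:
    def test_flat_epochs_kept(self):
        epochs = _epochs(np.zeros((4, 2, 10)))
        kept, report = reject_artifacts(epochs, threshold_uv=100.0)
        assert kept.n_epochs == 4
        assert report.rejection_fraction == 0.0

    def test_threshold_bracket_on_transient(self):
        data = np.zeros((2, 1, 10))
        data[1, 0, 3] = 60.0
        data[1, 0, 4] = -60.0  # 120 µV peak-to-peak
        kept, report = reject_artifacts(_epochs(data), threshold_uv=100.0)
        assert report.rejected.tolist() == [False, True]
        kept2, _ = reject_artifacts(_epochs(data), threshold_uv=130.0)
        assert kept2.n_epochs == 2

    def test_mastoids_not_screened(self):
        data = np.zeros((1, 3, 10))
        data[0, 2, 0] = 500.0
        epochs = EpochSet(
            data=data,
            time_ms=np.arange(10.0),
            channels=("PO3", "PO7", "M1"),
            sampling_rate=100.0,
            trial_ids=[0],
        )
        _, report = reject_artifacts(epochs, threshold_uv=100.0)
        assert not report.rejected.any()

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            reject_artifacts(_epochs(np.zeros((1, 1, 4))), threshold_uv=0.0)

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(1)
        epochs = _epochs(60.0 * rng.normal(size=(30, 2, 20)))
        kept, _ = reject_artifacts(epochs, threshold_uv=150.0)
        again, report = reject_artifacts(kept, threshold_uv=150.0)
        assert again.n_epochs == kept.n_epochs
        assert not report.rejected.any()
        for t1, t2 in [(100.0, 150.0), (150.0, 250.0)]:
            k1, _ = reject_artifacts(epochs, threshold_uv=t1)
            k2, _ = reject_artifacts(epochs, threshold_uv=t2)
            assert set(k1.trial_ids) <= set(k2.trial_ids)


class TestBaselineCorrect:
    def test_constant_offset_removed(self):
        epochs = _epochs(np.full((2, 1, 40), 5.0))
        out = baseline_correct(epochs, baseline_ms=(-150, 0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.baseline_applied

    def test_zero_mean_baseline_unchanged(self):
        data = np.zeros((1, 1, 40))
        data[0, 0, 25:] = 7.0  # post-stimulus only (t0 = -20 samples)
        epochs = _epochs(data)
        out = baseline_correct(epochs, baseline_ms=(-150, 0))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_baseline_mean_is_zero_after(self):
        rng = np.random.default_rng(2)
        epochs = _epochs(rng.normal(size=(5, 3, 40)))
        out = baseline_correct(epochs, baseline_ms=(-150, 0))
        mask = (out.time_ms >= -150) & (out.time_ms < 0)
        np.testing.assert_allclose(
            out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-9
        )

    def test_window_outside_epoch_errors(self):
        with pytest.raises(ConfigError):
            baseline_correct(_epochs(np.zeros((1, 1, 10))), baseline_ms=(-900, -800))

    def test_commutes_with_averaging(self):
        rng = np.random.default_rng(3)
        epochs = _epochs(rng.normal(size=(8, 2, 40)))
        corrected = baseline_correct(epochs)
        avg_then_correct = baseline_correct(
            EpochSet(
                data=epochs.data.mean(axis=0, keepdims=True),
                time_ms=epochs.time_ms,
                channels=epochs.channels,
                sampling_rate=epochs.sampling_rate,
                trial_ids=[0],
            )
        )
        np.testing.assert_allclose(
            corrected.data.mean(axis=0), avg_then_correct.data[0], atol=1e-12
        )
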