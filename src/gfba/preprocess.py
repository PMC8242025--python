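"""Behavioral filtering, re-referencing, epoching, artifact rejection,
and baseline correction.

Conventions: every time window is left-closed right-open on the sample
grid; the epoch window defaults to [-200, 700) ms around stimulus onset;
an epoch is rejected when its peak-to-peak amplitude on *any* scalp
(non-mastoid) channel exceeds the threshold; the prestimulus baseline
defaults to [-150, 0) ms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MASTOID_LEFT, MASTOID_RIGHT, ANALYZED_TRIAL_TYPES
from .errors import ConfigError, DataError
from .synth import ContinuousRecording

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Trials x channels x samples voltage tensor around stimulus onset."""

    data: np.ndarray
    time_ms: np.ndarray
    channels: tuple[str, ...]
    sampling_rate: float
    trial_ids: np.ndarray
    baseline_applied: bool = False

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise DataError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise DataError("channel axis does not match channel names")
        if self.data.shape[2] != len(self.time_ms):
            raise DataError("sample axis does not match time axis")
        if self.data.shape[0] != len(self.trial_ids):
            raise DataError("trial axis does not match trial ids")
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise DataError("trial ids must be unique")
        if len(self.time_ms) > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise DataError("time axis must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel '{name}' not in epochs") from None

    def select(self, trial_ids) -> "EpochSet":
        """Sub-EpochSet for the given trial ids (order preserved)."""
        wanted = set(np.asarray(trial_ids).tolist())
        mask = np.array([tid in wanted for tid in self.trial_ids])
        return EpochSet(
            data=self.data[mask],
            time_ms=self.time_ms,
            channels=self.channels,
            sampling_rate=self.sampling_rate,
            trial_ids=self.trial_ids[mask],
            baseline_applied=self.baseline_applied,
        )


@dataclass
class RejectionReport:
    """Per-epoch peak-to-peak maxima and the rejection outcome."""

    p2p: pd.DataFrame  # trial_id index, one column per scalp channel
    rejected: np.ndarray
    threshold_uv: float

    @property
    def rejection_fraction(self) -> float:
        return float(np.mean(self.rejected)) if len(self.rejected) else 0.0

    def to_frame(self) -> pd.DataFrame:
        out = self.p2p.copy()
        out["rejected"] = self.rejected
        return out

    def summary(self) -> dict:
        return {
            "threshold_uv": self.threshold_uv,
            "n_epochs": int(len(self.rejected)),
            "n_rejected": int(np.sum(self.rejected)),
            "rejection_fraction": self.rejection_fraction,
        }


def filter_behavior(
    trials: pd.DataFrame, rt_min_ms: float = 200.0, rt_max_ms: float = 1300.0
) -> pd.DataFrame:
    """Flag anticipatory (<200 ms), delayed (>1300 ms), incorrect, and
    RT-less trials; ``erp_eligible`` is true when none of the flags is set.

    Thresholds are strict inequalities: an RT of exactly 200 or 1300 ms
    survives.
    """
    if "rt_ms" not in trials.columns:
        raise DataError("trials have no rt_ms column; simulate or load behavior first")
    out = trials.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    correct = out["correct"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    out["invalid_rt"] = np.isnan(rt)
    out["anticipatory"] = ~out["invalid_rt"] & (rt < rt_min_ms)
    out["delayed"] = ~out["invalid_rt"] & (rt > rt_max_ms)
    out["incorrect"] = ~correct
    out["erp_eligible"] = ~(
        out["anticipatory"] | out["delayed"] | out["incorrect"] | out["invalid_rt"]
    )
    n_bad = int(out["invalid_rt"].sum())
    if n_bad:
        logger.warning("%d trial(s) with missing RT flagged invalid", n_bad)
    return out


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy (%) and mean RT per task x trial type (PC/DC/nontarget).

    Accuracy is computed over valid (in-range, responded) trials; mean RT
    over correct in-range trials.  The extra probe color is excluded.
    Empty cells yield NaN, never zero.
    """
    if "erp_eligible" not in trials.columns:
        raise DataError("run filter_behavior before summarize_behavior")
    t = trials[trials["trial_type"].isin(ANALYZED_TRIAL_TYPES)]
    rows = []
    for (task, ttype), grp in t.groupby(["task", "trial_type"], sort=True):
        valid = grp[~(grp["anticipatory"] | grp["delayed"] | grp["invalid_rt"])]
        rt_trials = valid[~valid["incorrect"]]
        rows.append(
            {
                "task": task,
                "trial_type": ttype,
                "n_trials": len(grp),
                "n_valid": len(valid),
                "accuracy_pct": (
                    100.0 * (~valid["incorrect"]).mean() if len(valid) else np.nan
                ),
                "mean_rt_ms": (
                    float(rt_trials["rt_ms"].mean()) if len(rt_trials) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def rereference(
    recording: ContinuousRecording, weight: float = 0.5
) -> ContinuousRecording:
    """Re-reference to the linked mastoids.

    Acquisition is assumed referenced to the right mastoid; subtracting
    ``weight`` (default one half) of the recorded left-mastoid channel from
    every channel makes the implied reference the (weighted) mean of both
    mastoids.  Mastoid channels are retained.
    """
    if MASTOID_LEFT not in recording.channels:
        raise DataError(f"missing mastoid channel '{MASTOID_LEFT}'")
    if MASTOID_RIGHT not in recording.channels:
        raise DataError(f"missing mastoid channel '{MASTOID_RIGHT}'")
    m_left = recording.data[recording.channel_index(MASTOID_LEFT)].copy()
    return ContinuousRecording(
        channels=recording.channels,
        sampling_rate=recording.sampling_rate,
        data=recording.data - weight * m_left[None, :],
        events=recording.events,
        subject=recording.subject,
    )


def epoch_sample_offsets(window_ms, sampling_rate: float) -> np.ndarray:
    """Sample offsets m relative to the onset sample with lo <= t_m < hi."""
    lo, hi = window_ms
    dt = 1000.0 / sampling_rate
    m_lo = int(math.ceil(lo / dt - 1e-9))
    m_hi = int(math.ceil(hi / dt - 1e-9))
    return np.arange(m_lo, m_hi)


def extract_epochs(
    recording: ContinuousRecording,
    trials: pd.DataFrame,
    window_ms=(-200.0, 700.0),
) -> EpochSet:
    """Cut fixed-length epochs around each event present in ``trials``.

    Events too close to a recording edge for the full window are dropped
    with a logged warning rather than padded.
    """
    fs = recording.sampling_rate
    offsets = epoch_sample_offsets(window_ms, fs)
    if offsets.size == 0:
        raise ConfigError("epoch window contains no samples")
    time_ms = offsets * 1000.0 / fs

    wanted = set(trials["trial_id"].tolist())
    ev_samples, ev_ids = [], []
    n_total = recording.data.shape[1]
    n_dropped = 0
    for sample, tid in recording.events:
        if tid not in wanted:
            continue
        if sample + offsets[0] < 0 or sample + offsets[-1] >= n_total:
            n_dropped += 1
            continue
        ev_samples.append(sample)
        ev_ids.append(tid)
    if n_dropped:
        logger.warning(
            "dropped %d trial(s) too close to the recording edge", n_dropped
        )
    if not ev_samples:
        data = np.empty((0, len(recording.channels), len(offsets)))
        return EpochSet(
            data=data,
            time_ms=time_ms,
            channels=recording.channels,
            sampling_rate=fs,
            trial_ids=np.array([], dtype=np.int64),
        )
    idx = np.asarray(ev_samples)[:, None] + offsets[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2)
    return EpochSet(
        data=data,
        time_ms=time_ms,
        channels=recording.channels,
        sampling_rate=fs,
        trial_ids=np.asarray(ev_ids, dtype=np.int64),
    )


def scalp_channels(channels) -> list[str]:
    return [c for c in channels if c not in (MASTOID_LEFT, MASTOID_RIGHT)]


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = 100.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold.

    The maximum-minus-minimum over the full epoch is screened on every
    scalp channel; exceeding the threshold on any one of them rejects the
    epoch.  The kept set preserves epoch order.
    """
    if threshold_uv <= 0:
        raise ConfigError("rejection threshold must be > 0")
    scalp = scalp_channels(epochs.channels)
    ch_idx = [epochs.channel_index(c) for c in scalp]
    if epochs.n_epochs:
        sub = epochs.data[:, ch_idx, :]
        p2p = sub.max(axis=2) - sub.min(axis=2)
    else:
        p2p = np.empty((0, len(ch_idx)))
    rejected = (p2p > threshold_uv).any(axis=1)
    report = RejectionReport(
        p2p=pd.DataFrame(p2p, columns=scalp, index=pd.Index(epochs.trial_ids, name="trial_id")),
        rejected=rejected,
        threshold_uv=threshold_uv,
    )
    kept = EpochSet(
        data=epochs.data[~rejected],
        time_ms=epochs.time_ms,
        channels=epochs.channels,
        sampling_rate=epochs.sampling_rate,
        trial_ids=epochs.trial_ids[~rejected],
        baseline_applied=epochs.baseline_applied,
    )
    return kept, report


def baseline_correct(epochs: EpochSet, baseline_ms=(-150.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    lo, hi = baseline_ms
    mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    if not mask.any():
        raise ConfigError("baseline window contains no samples of the epoch")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline,
        time_ms=epochs.time_ms,
        channels=epochs.channels,
        sampling_rate=epochs.sampling_rate,
        trial_ids=epochs.trial_ids,
        baseline_applied=True,
    )
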