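"""Condition averaging, difference waves, channel pooling, grand averages,
mean amplitudes, and the display-only Gaussian smoother.

The attention contrast of interest is the difference wave between probes in
an attended color (present target color PC, or the distracting alternative
DC) and probes in a never-relevant non-target color; its mean amplitude in
the early (73–96 ms) and late (167–254 ms) windows quantifies the global
feature-based attention modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError, DataError
from .preprocess import EpochSet


@dataclass
class Waveform:
    """Channels x samples time series with its provenance label."""

    data: np.ndarray
    time_ms: np.ndarray
    channels: tuple[str, ...]
    sampling_rate: float
    n_trials: object = 0  # int, or tuple for difference waves
    label: str = ""
    display_only: bool = False

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise DataError("waveform rows must match channel names")
        if self.data.shape[1] != len(self.time_ms):
            raise DataError("waveform columns must match time axis")

    def _check_compatible(self, other: "Waveform") -> None:
        if self.data.shape != other.data.shape:
            raise DataError("waveform shapes differ")
        if self.channels != other.channels:
            raise DataError("waveform channels differ")
        if not np.allclose(self.time_ms, other.time_ms):
            raise DataError("waveform time axes differ")


def average_condition(
    epochs: EpochSet,
    trials: pd.DataFrame,
    task: str,
    trial_type: str,
    require_eligible: bool = True,
) -> Waveform:
    """Arithmetic mean over the epochs of one task x trial-type cell.

    Only ERP-eligible trials enter (correct, in-range RT), and the extra
    probe color never enters the PC/DC/non-target averages.
    """
    sel = trials[(trials["task"] == task) & (trials["trial_type"] == trial_type)]
    if require_eligible:
        if "erp_eligible" not in sel.columns:
            raise DataError("trials lack eligibility flags; run filter_behavior")
        sel = sel[sel["erp_eligible"]]
    sub = epochs.select(sel["trial_id"].to_numpy())
    if sub.n_epochs == 0:
        raise DataError(f"no epochs for cell task={task!r}, trial_type={trial_type!r}")
    return Waveform(
        data=sub.data.mean(axis=0),
        time_ms=epochs.time_ms,
        channels=epochs.channels,
        sampling_rate=epochs.sampling_rate,
        n_trials=int(sub.n_epochs),
        label=f"{task}/{trial_type}",
    )


def difference_wave(a: Waveform, b: Waveform) -> Waveform:
    """Sample-wise a - b (e.g. DC minus non-target)."""
    a._check_compatible(b)
    return Waveform(
        data=a.data - b.data,
        time_ms=a.time_ms,
        channels=a.channels,
        sampling_rate=a.sampling_rate,
        n_trials=(a.n_trials, b.n_trials),
        label=f"({a.label})-({b.label})",
    )


def pool_channels(w: Waveform, names=("PO3", "PO7")) -> Waveform:
    """Average the named channels into a single pooled channel."""
    idx = []
    for name in names:
        if name not in w.channels:
            raise DataError(f"channel '{name}' not in waveform")
        idx.append(w.channels.index(name))
    return Waveform(
        data=w.data[idx].mean(axis=0, keepdims=True),
        time_ms=w.time_ms,
        channels=("+".join(names),),
        sampling_rate=w.sampling_rate,
        n_trials=w.n_trials,
        label=w.label,
    )


def grand_average(waveforms: list[Waveform]) -> Waveform:
    """Unweighted mean across subjects (not across trials)."""
    if not waveforms:
        raise DataError("grand_average needs at least one waveform")
    first = waveforms[0]
    for w in waveforms[1:]:
        first._check_compatible(w)
        if w.label != first.label:
            raise DataError(
                f"mixed labels in grand average: {w.label!r} vs {first.label!r}"
            )
    return Waveform(
        data=np.mean([w.data for w in waveforms], axis=0),
        time_ms=first.time_ms,
        channels=first.channels,
        sampling_rate=first.sampling_rate,
        n_trials=len(waveforms),
        label=f"grand({first.label})",
    )


def mean_amplitude(w: Waveform, window_ms) -> float:
    """Mean over samples with window_start <= t < window_end (µV).

    For multichannel waveforms the mean is over channels as well.
    """
    lo, hi = window_ms
    mask = (w.time_ms >= lo) & (w.time_ms < hi)
    if not mask.any():
        raise ConfigError(f"window {window_ms} contains no samples")
    return float(w.data[:, mask].mean())


def gaussian_sigma_ms(half_amp_cutoff_hz: float) -> float:
    """Kernel width (ms) whose amplitude response is 0.5 at the cutoff.

    A Gaussian kernel with time-domain sigma_t has amplitude response
    exp(-2 pi^2 f^2 sigma_t^2); solving for 0.5 at f_c gives
    sigma_t = sqrt(ln 2 / (2 pi^2 f_c^2))  (~8.15 ms at 23 Hz).
    """
    if half_amp_cutoff_hz <= 0:
        raise ConfigError("cutoff frequency must be > 0")
    return 1000.0 * math.sqrt(math.log(2.0) / (2.0 * math.pi**2 * half_amp_cutoff_hz**2))


def gaussian_lowpass(w: Waveform, half_amp_cutoff_hz: float = 23.0) -> Waveform:
    """Display-only Gaussian smoother (reflective edge padding).

    Applied for plotting; statistics always run on unfiltered data, so the
    output is flagged ``display_only``.
    """
    sigma_samples = gaussian_sigma_ms(half_amp_cutoff_hz) * w.sampling_rate / 1000.0
    smoothed = gaussian_filter1d(w.data, sigma=sigma_samples, axis=1, mode="reflect")
    return Waveform(
        data=smoothed,
        time_ms=w.time_ms,
        channels=w.channels,
        sampling_rate=w.sampling_rate,
        n_trials=w.n_trials,
        label=w.label,
        display_only=True,
    )
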