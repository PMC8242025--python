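"""Synthetic trial tables, behavior, and continuous EEG for the
unattended-probe paradigm.

The generator reproduces the statistical structure the downstream analysis
assumes: two tasks (color / orientation discrimination) run in blocks with
two alternating target-color pairs, a task-irrelevant probe drawn from five
colors, reaction times with a distractor-color cost and a repetition
benefit, and probe-evoked potentials at parieto-occipital channels carrying
an early distractor-color-only negativity and late negativities for both
attended colors.  A per-trial amplitude deviate of the early negativity is
shared between :func:`simulate_behavior` and :func:`synthesize_recording`
so that trials with a larger early negativity respond faster — the
structure the fast/slow RT-split analysis is designed to detect.

Trial-type semantics (probe relative to the block's target-color pair):

``PC``
    probe matches the present target color;
``DC``
    probe matches the distracting alternative target color (the other
    member of the pair);
``magenta`` (generally: the extra probe color)
    the probe color that is never a target;
``nontarget``
    any other probe color (the other pair's colors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

from .config import (
    EffectParams,
    ParadigmConfig,
    MASTOID_LEFT,
    MASTOID_RIGHT,
)
from .errors import ConfigError, DataError

#: Column order of the trial table (the TrialRecord contract).
TRIAL_COLUMNS = [
    "subject",
    "task",
    "block",
    "color_pair",
    "trial",
    "onset_s",
    "target_color",
    "probe_color",
    "target_orientation",
    "trial_type",
    "rt_ms",
    "correct",
    "repetition",
]

#: Extra columns the generator appends (kept on round trip).
EXTRA_TRIAL_COLUMNS = ["trial_id", "early_amp_dev_uv"]

_ORIENTATIONS = ("left", "right")

# fixed stream tags so each stage draws from an independent substream
_TAG_DESIGN, _TAG_BEHAVIOR, _TAG_EEG = 7, 11, 13


@dataclass
class ErpTemplate:
    """Base probe-evoked waveform added on every trial at analysis channels.

    A smooth biphasic deflection: a positivity near 100 ms and a negativity
    near 170 ms, each a Gaussian bump (latency ms, width ms, amplitude µV).
    Only the condition *deltas* on top of this template carry the effects
    of interest; the template itself is identical across conditions.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (100.0, 18.0, 3.0),
        (170.0, 25.0, -4.0),
    )

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t_ms, dtype=float)
        for lat, width, amp in self.components:
            out += amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)
        return out


@dataclass
class ContinuousRecording:
    """Multichannel voltage trace with stimulus events.

    ``data`` is channels x samples in µV; ``events`` is an (n, 2) integer
    array of (sample index of stimulus onset, trial id).
    """

    channels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    events: np.ndarray
    subject: int = 0

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise DataError("channel names must be unique")
        if self.data.shape[0] != len(self.channels):
            raise DataError("data rows must match channel count")
        if self.events.size and (
            self.events[:, 0].min() < 0
            or self.events[:, 0].max() >= self.data.shape[1]
        ):
            raise DataError("event sample indices outside the recording")

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel '{name}' not in recording") from None


def onset_sample(onset_s: float, sampling_rate: float) -> int:
    """First sample at or after the stimulus onset time (0-based)."""
    return int(math.ceil(onset_s * sampling_rate - 1e-9))


def window_samples(window_ms, sampling_rate: float) -> np.ndarray:
    """Sample offsets m (relative to onset) with lo <= m/fs*1000 < hi.

    The left-closed right-open convention used for every window in the
    package (effect injection, mean amplitudes, baselines, epochs).
    """
    lo, hi = window_ms
    dt = 1000.0 / sampling_rate
    m_lo = int(math.ceil(lo / dt - 1e-9))
    m_hi = int(math.ceil(hi / dt - 1e-9))  # first excluded sample
    return np.arange(m_lo, m_hi)


def _block_schedule(config: ParadigmConfig, subject: int):
    """(task, pair_index) per block, honoring the pseudorandomization rule.

    The target-color pair alternates on every block and the task changes
    every second block; the four possible orders (first task x first pair)
    are cycled across subjects.  Each task receives exactly
    ``blocks_per_task`` blocks (with an odd count the strict task
    alternation cannot hold for the last blocks and the remainder is
    assigned to the unfilled task).
    """
    order = subject % 4
    task_first, pair_first = order // 2, order % 2
    n_pairs = len(config.target_color_pairs)
    n_total = 2 * config.blocks_per_task
    counts = {0: 0, 1: 0}
    schedule = []
    for b in range(n_total):
        t = (task_first + b // 2) % 2
        if counts[t] >= config.blocks_per_task:
            t = 1 - t
        counts[t] += 1
        pair = (pair_first + b) % n_pairs if n_pairs else 0
        schedule.append((config.tasks[t], pair))
    return schedule


def design_trials(config: ParadigmConfig, seed: int | None = None) -> pd.DataFrame:
    """Lay out every trial for every subject (RT/correct left unset).

    Per trial the target color is uniform over the block's pair, the probe
    color uniform over the five probe colors, and the orientation uniform
    over left/right, all independent.  Onset times cumulate the stimulus
    duration plus a uniform inter-stimulus-interval draw.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    frames = []
    trial_id0 = 0
    for subject in range(config.n_subjects):
        rng = np.random.default_rng([_TAG_DESIGN, subject, seed])
        t_cursor = 1.0  # pre-roll so the first epoch has pre-stimulus data
        for block, (task, pair_idx) in enumerate(_block_schedule(config, subject)):
            n = config.trials_per_block
            if n == 0:
                continue
            pair = config.target_color_pairs[pair_idx]
            targets = np.asarray(pair)[rng.integers(0, 2, n)]
            probes = np.asarray(config.probe_colors)[
                rng.integers(0, len(config.probe_colors), n)
            ]
            orientations = np.asarray(_ORIENTATIONS)[rng.integers(0, 2, n)]
            isi_ms = rng.uniform(config.isi_range[0], config.isi_range[1], n)
            durations = (config.stimulus_duration + isi_ms) / 1000.0
            onsets = t_cursor + np.concatenate([[0.0], np.cumsum(durations[:-1])])
            t_cursor = onsets[-1] + durations[-1] + config.block_gap_s

            other = np.where(targets == pair[0], pair[1], pair[0])
            trial_type = np.where(
                probes == targets,
                "PC",
                np.where(
                    probes == other,
                    "DC",
                    np.where(probes == config.extra_probe_color, "magenta", "nontarget"),
                ),
            )
            repetition = np.where(
                np.concatenate([["?"], targets[:-1]]) == targets, "repeat", "switch"
            ).astype(object)
            repetition[0] = "undefined"

            frames.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "task": task,
                        "block": block,
                        "color_pair": "_".join(pair),
                        "trial": np.arange(n),
                        "onset_s": onsets,
                        "target_color": targets,
                        "probe_color": probes,
                        "target_orientation": orientations,
                        "trial_type": trial_type,
                        "rt_ms": np.nan,
                        "correct": pd.array([None] * n, dtype="boolean"),
                        "repetition": repetition,
                        "trial_id": np.arange(trial_id0, trial_id0 + n),
                    }
                )
            )
            trial_id0 += n
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS + ["trial_id"])
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS + ["trial_id"]]


def simulate_behavior(
    trials: pd.DataFrame, effects: EffectParams, seed: int = 0
) -> pd.DataFrame:
    """Fill in reaction times, correctness, and the shared amplitude deviate.

    RT = base + DC cost (color-task DC trials) - repetition benefit (repeat
    trials) + coupling x per-trial early-amplitude deviate + Gaussian noise,
    truncated at 50 ms.  The deviate (µV) is nonzero only on color-task DC
    trials — the trials that carry the early negativity — and is reused by
    :func:`synthesize_recording`, which makes fast trials carry a
    larger-magnitude early negativity.
    """
    effects.validate()
    out = trials.copy()
    n = len(out)
    rng = np.random.default_rng([_TAG_BEHAVIOR, seed])
    is_dc_color = ((out["trial_type"] == "DC") & (out["task"] == "color")).to_numpy()
    dev = np.where(is_dc_color, rng.normal(0.0, 1.0, n), 0.0) * effects.early_amp_jitter_sd
    rt = (
        effects.rt_base_mean
        + effects.dc_rt_cost * is_dc_color
        - effects.repetition_benefit * (out["repetition"] == "repeat").to_numpy()
        + effects.early_amp_rt_coupling * dev
        + rng.normal(0.0, 1.0, n) * effects.rt_base_sd
    )
    out["rt_ms"] = np.maximum(rt, 50.0)
    out["correct"] = pd.array(
        rng.uniform(0.0, 1.0, n) < effects.accuracy_rate, dtype="boolean"
    )
    out["early_amp_dev_uv"] = dev
    return out


def _shaped_noise(
    n_channels: int, n_samples: int, effects: EffectParams, rng: np.random.Generator
) -> np.ndarray:
    """White plus 1/f^a noise; each component scaled to its target sd."""
    noise = np.zeros((n_channels, n_samples))
    if effects.noise_white_sd > 0:
        noise += effects.noise_white_sd * rng.standard_normal(
            (n_channels, n_samples), dtype=np.float32
        )
    if effects.noise_pink_sd > 0 and n_samples > 2:
        # synthesize (single precision) on the next fast FFT length and crop
        n_fft = scipy.fft.next_fast_len(n_samples)
        freqs = np.fft.rfftfreq(n_fft).astype(np.float32)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** np.float32(-effects.noise_pink_exponent / 2.0)
        spec = amp * (
            rng.standard_normal((n_channels, freqs.size), dtype=np.float32)
            + 1j * rng.standard_normal((n_channels, freqs.size), dtype=np.float32)
        )
        pink = scipy.fft.irfft(spec, n_fft, axis=1)[:, :n_samples]
        sd = pink.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        noise += effects.noise_pink_sd * pink / sd
    return noise


def synthesize_recording(
    trials: pd.DataFrame,
    effects: EffectParams,
    config: ParadigmConfig,
    seed: int = 0,
    template: ErpTemplate | None = None,
) -> ContinuousRecording:
    """Continuous multichannel EEG for one subject's trial table.

    Every trial adds the base probe-evoked template at the analysis
    channels plus condition deltas (boxcars over the configured windows):
    the early negativity with per-trial jitter on color-task DC trials, the
    late negativity on PC trials (scaled down in the orientation task), and
    a smaller late negativity on color-task DC trials.  Blink transients hit
    all scalp channels on randomly selected trials; mastoids carry noise
    only.
    """
    effects.validate()
    config.validate()
    if trials["subject"].nunique() > 1:
        raise DataError("synthesize_recording expects a single subject's trials")
    if "early_amp_dev_uv" not in trials.columns:
        raise DataError(
            "trials lack the shared amplitude deviates; run simulate_behavior first"
        )
    for name in ("early_dc_window", "late_pc_window"):
        lo, hi = getattr(effects, name)
        if not (0.0 <= lo <= hi <= 700.0):
            raise ConfigError(f"{name} must lie within the post-stimulus epoch [0, 700] ms")

    fs = config.sampling_rate
    subject = int(trials["subject"].iloc[0]) if len(trials) else 0
    rng = np.random.default_rng([_TAG_EEG, subject, seed])

    end_s = (trials["onset_s"].max() + 2.0) if len(trials) else 2.0
    n_samples = int(math.ceil(end_s * fs))
    n_ch = len(config.channels)
    data = _shaped_noise(n_ch, n_samples, effects, rng)

    tmpl = template or ErpTemplate()
    m_post = window_samples((0.0, 700.0), fs)  # template support
    t_post = m_post * 1000.0 / fs
    base = tmpl.evaluate(t_post)
    m_early = window_samples(effects.early_dc_window, fs)
    m_late = window_samples(effects.late_pc_window, fs)

    analysis_idx = [config.channels.index(c) for c in config.analysis_channels]
    scalp_idx = [
        i
        for i, c in enumerate(config.channels)
        if c not in (MASTOID_LEFT, MASTOID_RIGHT)
    ]

    events = np.zeros((len(trials), 2), dtype=np.int64)
    blink_mask = rng.uniform(0.0, 1.0, len(trials)) < effects.blink_rate
    blink_lat = rng.uniform(0.0, 500.0, len(trials))

    onsets = trials["onset_s"].to_numpy()
    ttypes = trials["trial_type"].to_numpy()
    tasks = trials["task"].to_numpy()
    devs = trials["early_amp_dev_uv"].to_numpy()
    tids = trials["trial_id"].to_numpy()

    for i in range(len(trials)):
        ev = onset_sample(onsets[i], fs)
        events[i] = (ev, tids[i])
        wave = base.copy()
        if ttypes[i] == "DC" and tasks[i] == "color":
            wave[m_early] += effects.early_dc_amp + devs[i]
            wave[m_late] += effects.late_dc_amp
        elif ttypes[i] == "PC":
            scale = 1.0 if tasks[i] == "color" else effects.orientation_task_pc_scale
            wave[m_late] += effects.late_pc_amp * scale
        sl = slice(ev, ev + len(wave))
        for ch in analysis_idx:
            data[ch, sl] += wave[: data.shape[1] - ev]
        if blink_mask[i] and effects.blink_amp != 0.0:
            bump = effects.blink_amp * np.exp(
                -0.5 * ((t_post - blink_lat[i]) / 40.0) ** 2
            )
            for ch in scalp_idx:
                data[ch, sl] += bump[: data.shape[1] - ev]

    return ContinuousRecording(
        channels=config.channels,
        sampling_rate=fs,
        data=data,
        events=events,
        subject=subject,
    )
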