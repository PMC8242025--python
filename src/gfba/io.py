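"""File round-tripping: trial tables (TSV), recordings/epochs/waveforms
(HDF5), leadfields/source estimates (HDF5), configs (YAML), reports (JSON).

Every HDF5 artifact is stamped with ``schema_version`` and checked on
read; numeric payloads are stored float32, so round trips are lossless to
float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import (
    SCHEMA_VERSION,
    PipelineConfig,
    pipeline_config_from_dict,
    pipeline_config_to_dict,
)
from .errors import ConfigError, DataError
from .erp import Waveform
from .preprocess import EpochSet
from .source import Leadfield, SourceEstimate
from .synth import TRIAL_COLUMNS, ContinuousRecording


def _check_schema(attrs, path) -> None:
    version = attrs.get("schema_version")
    if version is None:
        raise DataError(f"{path}: missing schema_version attribute")
    if str(version) != SCHEMA_VERSION:
        raise DataError(
            f"{path}: schema_version {version!r} != supported {SCHEMA_VERSION!r}"
        )


def _open_h5(path, kind: str) -> h5py.File:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DataError(f"cannot read {kind} file {path}: {exc}") from exc
    return f


# ---------------------------------------------------------------------------
# trial tables


def write_trials(trials: pd.DataFrame, path) -> None:
    """TSV, one row per trial, TrialRecord columns first, extras after;
    missing values as empty strings."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"cannot read trial table {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trial table {path} missing column(s): {missing}")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype("boolean")
    return df


# ---------------------------------------------------------------------------
# recordings and epochs


def write_recording(recording: ContinuousRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f.create_dataset("events", data=recording.events.astype(np.int64))
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["channel_names"] = list(recording.channels)
        f.attrs["subject"] = recording.subject
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_recording(path) -> ContinuousRecording:
    with _open_h5(path, "recording") as f:
        _check_schema(f.attrs, path)
        for name in ("data", "events"):
            if name not in f:
                raise DataError(f"{path}: missing dataset /{name}")
        return ContinuousRecording(
            channels=tuple(str(c) for c in f.attrs["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            data=f["data"][()].astype(float),
            events=f["events"][()],
            subject=int(f.attrs.get("subject", 0)),
        )


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("time_ms", data=epochs.time_ms.astype(np.float64))
        f.create_dataset("trial_ids", data=epochs.trial_ids.astype(np.int64))
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["channel_names"] = list(epochs.channels)
        f.attrs["baseline_applied"] = epochs.baseline_applied
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path) -> EpochSet:
    with _open_h5(path, "epochs") as f:
        _check_schema(f.attrs, path)
        for name in ("data", "time_ms", "trial_ids"):
            if name not in f:
                raise DataError(f"{path}: missing dataset /{name}")
        return EpochSet(
            data=f["data"][()].astype(float),
            time_ms=f["time_ms"][()],
            channels=tuple(str(c) for c in f.attrs["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            trial_ids=f["trial_ids"][()],
            baseline_applied=bool(f.attrs["baseline_applied"]),
        )


# ---------------------------------------------------------------------------
# waveforms


def write_waveform(w: Waveform, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=w.data.astype(np.float32))
        f.create_dataset("time_ms", data=w.time_ms)
        f.attrs["sampling_rate"] = w.sampling_rate
        f.attrs["channel_names"] = list(w.channels)
        f.attrs["label"] = w.label
        f.attrs["n_trials"] = json.dumps(w.n_trials)
        f.attrs["display_only"] = w.display_only
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_waveform(path) -> Waveform:
    with _open_h5(path, "waveform") as f:
        _check_schema(f.attrs, path)
        n_trials = json.loads(f.attrs["n_trials"])
        if isinstance(n_trials, list):
            n_trials = tuple(n_trials)
        return Waveform(
            data=f["data"][()].astype(float),
            time_ms=f["time_ms"][()],
            channels=tuple(str(c) for c in f.attrs["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            n_trials=n_trials,
            label=str(f.attrs["label"]),
            display_only=bool(f.attrs["display_only"]),
        )


def write_waveform_tsv(w: Waveform, path) -> None:
    """Human-auditable export: time_ms plus one column per channel."""
    df = pd.DataFrame({"time_ms": w.time_ms})
    for i, ch in enumerate(w.channels):
        df[ch] = w.data[i]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# source objects


def write_leadfield(L: Leadfield, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=L.gain)
        f.create_dataset("locations", data=L.source_locations)
        f.attrs["sensor_names"] = list(L.sensor_names)
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_leadfield(path) -> Leadfield:
    with _open_h5(path, "leadfield") as f:
        _check_schema(f.attrs, path)
        return Leadfield(
            gain=f["gain"][()],
            sensor_names=tuple(str(s) for s in f.attrs["sensor_names"]),
            source_locations=f["locations"][()],
        )


def write_source_estimate(est: SourceEstimate, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=est.amplitudes.astype(np.float32))
        f.create_dataset("time_ms", data=np.asarray(est.time_ms))
        f.attrs["lambda"] = est.lam
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_source_estimate(path) -> SourceEstimate:
    with _open_h5(path, "source estimate") as f:
        _check_schema(f.attrs, path)
        return SourceEstimate(
            amplitudes=f["amplitudes"][()].astype(float),
            time_ms=f["time_ms"][()],
            lam=float(f.attrs["lambda"]),
        )


# ---------------------------------------------------------------------------
# configs and reports


def load_config(path) -> PipelineConfig:
    try:
        with open(path) as f:
            raw = yaml.safe_load(f)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    return pipeline_config_from_dict(raw)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(pipeline_config_to_dict(cfg), f, sort_keys=False)


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=_default)
        f.write("\n")


def read_report(path) -> dict:
    try:
        with open(path) as f:
            return json.load(f)
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read report {path}: {exc}") from exc
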