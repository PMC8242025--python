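"""Toy-scale minimum-norm least-squares (MNLS) source estimation.

The forward model is a leadfield L (sensors x sources); the inverse
operator is the Tikhonov-regularized minimum-norm solution
``W = L^T (L L^T + lambda I)^(-1)``.  For lambda = 0 and data in the range
of L, ``W x`` is the minimum-Euclidean-norm exact solution of ``L s = x``.
The same operator implements sensor-array repositioning: project the
individual-array data into source space, then forward-project with the
canonical array's leadfield.

This is the computational skeleton of a distributed-source analysis on a
synthetic forward model — no anatomical head model, depth weighting, or
noise-covariance whitening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


@dataclass
class Leadfield:
    """Sensors x sources gain matrix with sensor names and 3-D locations."""

    gain: np.ndarray
    sensor_names: tuple[str, ...]
    source_locations: np.ndarray  # (n_sources, 3) mm, arbitrary head frame

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        self.sensor_names = tuple(self.sensor_names)
        self.source_locations = np.asarray(self.source_locations, dtype=float)
        if self.gain.ndim != 2 or min(self.gain.shape) < 1:
            raise DataError("leadfield gain must be a 2-D sensors x sources matrix")
        if not np.all(np.isfinite(self.gain)):
            raise DataError("leadfield gain has non-finite entries")
        if len(self.sensor_names) != self.gain.shape[0]:
            raise DataError("sensor name count does not match gain rows")
        if self.source_locations.shape != (self.gain.shape[1], 3):
            raise DataError("source locations must be (n_sources, 3)")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourceEstimate:
    """Sources x samples current amplitudes."""

    amplitudes: np.ndarray
    time_ms: np.ndarray
    lam: float

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise DataError("source amplitudes must be sources x samples")
        if self.amplitudes.shape[1] != len(self.time_ms):
            raise DataError("sample axis does not match time axis")


@dataclass
class ROI:
    label: str
    source_indices: tuple[int, ...]

    def __post_init__(self):
        self.source_indices = tuple(int(i) for i in self.source_indices)
        if not self.source_indices:
            raise DataError("ROI must contain at least one source")


def make_toy_leadfield(
    n_sensors: int, n_sources: int, mode: str = "random_full_rank", seed: int = 0
) -> Leadfield:
    """Deterministic toy forward models.

    ``random_full_rank``: i.i.d. Gaussian gains, redrawn until the rank is
    min(dims).  ``ring_geometry``: sensors and sources on concentric rings
    with distance-decaying gains (well-separated sources, good for
    localization demos).  ``identity``: square identity gain.
    """
    if n_sensors < 1 or n_sources < 1:
        raise ConfigError("n_sensors and n_sources must be >= 1")
    rng = np.random.default_rng([17, seed])
    names = tuple(f"S{i:03d}" for i in range(n_sensors))
    if mode == "identity":
        if n_sensors != n_sources:
            raise ConfigError("identity mode requires n_sensors == n_sources")
        gain = np.eye(n_sensors)
        theta = 2 * np.pi * np.arange(n_sources) / n_sources
        locs = np.stack([80 * np.cos(theta), 80 * np.sin(theta), np.zeros(n_sources)], 1)
    elif mode == "random_full_rank":
        for _ in range(100):
            gain = rng.standard_normal((n_sensors, n_sources))
            if np.linalg.matrix_rank(gain) == min(n_sensors, n_sources):
                break
        else:  # pragma: no cover - essentially impossible
            raise DataError("could not draw a full-rank leadfield")
        locs = rng.uniform(-80, 80, size=(n_sources, 3))
    elif mode == "ring_geometry":
        src_theta = 2 * np.pi * np.arange(n_sources) / n_sources
        sen_theta = 2 * np.pi * np.arange(n_sensors) / n_sensors
        src = np.stack([70 * np.cos(src_theta), 70 * np.sin(src_theta)], 1)
        sen = np.stack([100 * np.cos(sen_theta), 100 * np.sin(sen_theta)], 1)
        dist = np.linalg.norm(sen[:, None, :] - src[None, :, :], axis=2)
        gain = 1.0 / (1.0 + (dist / 30.0) ** 2)
        locs = np.concatenate([src, np.zeros((n_sources, 1))], axis=1)
    else:
        raise ConfigError(f"unknown leadfield mode {mode!r}")
    return Leadfield(gain=gain, sensor_names=names, source_locations=locs)


def default_lambda(L: Leadfield, scale: float = 0.01) -> float:
    """Trace-scaled Tikhonov default: trace(L L^T) / n_sensors * scale."""
    return float(np.trace(L.gain @ L.gain.T) / L.n_sensors * scale)


def mnls_operator(L: Leadfield, lam: float = 0.0) -> np.ndarray:
    """Inverse operator W = L^T (L L^T + lambda I)^(-1), sources x sensors."""
    if lam < 0:
        raise ConfigError("lambda must be >= 0")
    gram = L.gain @ L.gain.T
    if lam == 0.0:
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise DataError(
                "L L^T is (near-)singular at lambda = 0; use a positive "
                "regularization parameter"
            )
    return L.gain.T @ np.linalg.inv(gram + lam * np.eye(L.n_sensors))


def apply_inverse(
    W: np.ndarray, sensor_data: np.ndarray, time_ms=None, lam: float = 0.0
) -> SourceEstimate:
    """Apply the inverse operator to sensors x samples data."""
    x = np.atleast_2d(np.asarray(sensor_data, dtype=float))
    if W.shape[1] != x.shape[0]:
        raise DataError(
            f"operator expects {W.shape[1]} sensors, data has {x.shape[0]}"
        )
    if time_ms is None:
        time_ms = np.arange(x.shape[1], dtype=float)
    return SourceEstimate(amplitudes=W @ x, time_ms=np.asarray(time_ms), lam=lam)


def reposition_sensors(
    x_ind: np.ndarray, L_ind: Leadfield, L_canon: Leadfield, lam: float = 0.0
) -> np.ndarray:
    """Transform individual-array data to a canonical sensor array.

    Two steps: into source space with the individual array's MNLS inverse,
    then backprojection with the canonical leadfield:
    ``x_canon = L_canon W_ind x_ind``.
    """
    if L_ind.n_sources != L_canon.n_sources:
        raise DataError("individual and canonical leadfields must share sources")
    W = mnls_operator(L_ind, lam)
    return L_canon.gain @ (W @ np.atleast_2d(np.asarray(x_ind, dtype=float)))


def roi_waveform(est: SourceEstimate, roi: ROI) -> np.ndarray:
    """Source-strength time course: mean |amplitude| across ROI members."""
    idx = np.asarray(roi.source_indices)
    if idx.min() < 0 or idx.max() >= est.amplitudes.shape[0]:
        raise DataError(f"ROI '{roi.label}' has out-of-range source indices")
    return np.abs(est.amplitudes[idx]).mean(axis=0)
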