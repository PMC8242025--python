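"""Within-subject factorial ANOVA, paired t-tests, the sampling-rate
corrected alpha, sliding-window scans, and consecutive-samples onset
detection — implemented from first principles.

The workhorse is a balanced two-way repeated-measures ANOVA: each effect
(factor A, factor B, A x B) is tested against its own subject-interaction
error term, and nonsphericity is handled with the classical
Greenhouse–Geisser epsilon estimated from the covariance of the
orthonormal-contrast-transformed within-subject scores.  The sliding scans
apply the same ANOVA (or a paired t) to short window means sample by
sample, control the per-test level with the corrected alpha
``1 - (1 - alpha0)^(2 fc / fs)`` (which accounts for the effective number
of independent tests given the acquisition low-pass at ``fc`` and sampling
rate ``fs``), and declare an effect onset at the first of five or more
consecutive sub-alpha samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import helmert
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha correction


def corrected_alpha(alpha0: float, fc: float, fs: float) -> float:
    """Per-sample significance level 1 - (1 - alpha0)^(2 fc / fs)."""
    if not 0.0 < alpha0 < 1.0:
        raise ConfigError("alpha0 must be in (0, 1)")
    if fs <= 0:
        raise ConfigError("fs must be > 0")
    if not 0.0 <= fc <= fs / 2.0:
        raise ConfigError("fc must satisfy 0 <= fc <= fs/2")
    return 1.0 - (1.0 - alpha0) ** (2.0 * fc / fs)


# ---------------------------------------------------------------------------
# paired t


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired Student's t-test, closed form.

    Zero-variance differences are handled explicitly: sd = 0 with a
    nonzero mean difference gives p = 0 (flagged degenerate); sd = mean = 0
    gives t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired_t needs two equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise DataError("paired_t needs at least two pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, degenerate=True)
        return PairedTResult(
            t=math_copysign_inf(md), df=df, p=0.0, degenerate=True
        )
    t = md / (sd / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df)
    return PairedTResult(t=float(t), df=df, p=float(p))


def math_copysign_inf(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA


@dataclass
class EffectStats:
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p_gg: float


@dataclass
class AnovaResult:
    """Per-effect statistics of a two-way within-subject ANOVA."""

    effects: dict[str, EffectStats]
    factor_names: tuple[str, str]
    factor_levels: tuple[int, int]
    n_subjects: int

    def __getitem__(self, key: str) -> EffectStats:
        return self.effects[key]


def _contrast_matrices(a: int, b: int):
    """Orthonormal contrast rows for A, B, and A x B in the ab cell space."""
    ca = helmert(a, full=False) if a > 1 else np.zeros((0, a))
    cb = helmert(b, full=False) if b > 1 else np.zeros((0, b))
    one_a = np.full((1, a), 1.0 / a)
    one_b = np.full((1, b), 1.0 / b)
    return {
        "A": np.kron(ca, one_b),
        "B": np.kron(one_a, cb),
        "A:B": np.kron(ca, cb),
    }


def _gg_epsilon(y_flat: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Greenhouse–Geisser epsilon from contrast-transformed scores.

    ``y_flat``: (..., n, ab); ``contrast``: (r, ab).  Returns (...).
    With r = 1 the estimator is exactly 1 (sphericity is trivial for a
    single contrast).
    """
    r = contrast.shape[0]
    if r <= 1:
        return np.ones(y_flat.shape[:-2])
    z = y_flat @ contrast.T  # (..., n, r)
    zc = z - z.mean(axis=-2, keepdims=True)
    s = np.swapaxes(zc, -1, -2) @ zc  # (..., r, r) scatter; scale cancels
    tr = np.trace(s, axis1=-2, axis2=-1)
    tr2 = np.sum(s * np.swapaxes(s, -1, -2), axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(tr2 > 0, tr**2 / (r * tr2), 1.0)
    return np.clip(eps, 1.0 / r, 1.0)


def _rm_anova_arrays(y: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Batched balanced two-way within-subject ANOVA.

    ``y`` has shape (..., n_subjects, a, b); leading axes are independent
    problems (e.g. sliding windows).  Returns per-effect arrays of F, dfs,
    epsilon, and p-values.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 3:
        raise DataError("rm_anova input must be subjects x a x b (at least 3-D)")
    if not np.all(np.isfinite(y)):
        raise DataError("rm_anova input contains non-finite values (missing cells?)")
    n, a, b = y.shape[-3:]
    if n < 2:
        raise DataError("rm_anova needs at least two subjects")
    if a < 2 or b < 2:
        raise DataError("rm_anova needs at least two levels per factor")

    mu = y.mean(axis=(-3, -2, -1))
    mi = y.mean(axis=(-3, -1))  # (..., a)
    mj = y.mean(axis=(-3, -2))  # (..., b)
    mij = y.mean(axis=-3)  # (..., a, b)
    ms = y.mean(axis=(-2, -1))  # (..., n)
    msi = y.mean(axis=-1)  # (..., n, a)
    msj = y.mean(axis=-2)  # (..., n, b)

    mu_ = mu[..., None]
    ss_a = n * b * ((mi - mu_) ** 2).sum(-1)
    ss_b = n * a * ((mj - mu_) ** 2).sum(-1)
    ss_ab = n * (
        (mij - mi[..., :, None] - mj[..., None, :] + mu[..., None, None]) ** 2
    ).sum((-1, -2))
    ss_as = b * (
        (msi - ms[..., :, None] - mi[..., None, :] + mu[..., None, None]) ** 2
    ).sum((-1, -2))
    ss_bs = a * (
        (msj - ms[..., :, None] - mj[..., None, :] + mu[..., None, None]) ** 2
    ).sum((-1, -2))
    resid = (
        y
        - msi[..., :, :, None]
        - msj[..., :, None, :]
        - mij[..., None, :, :]
        + ms[..., :, None, None]
        + mi[..., None, :, None]
        + mj[..., None, None, :]
        - mu[..., None, None, None]
    )
    ss_abs = (resid**2).sum((-1, -2, -3))

    y_flat = y.reshape(*y.shape[:-2], a * b)
    contrasts = _contrast_matrices(a, b)

    table = {
        "A": (ss_a, ss_as, a - 1, (n - 1) * (a - 1)),
        "B": (ss_b, ss_bs, b - 1, (n - 1) * (b - 1)),
        "A:B": (ss_ab, ss_abs, (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1)),
    }
    # degenerate guard: sums of squares at the level of float rounding
    # noise (identical data) must give F = 0, not a ratio of float residue
    amax = np.abs(y).max(axis=(-1, -2, -3))
    tiny = (amax * 1e-10) ** 2 * (n * a * b) + 1e-300

    out: dict[str, dict[str, np.ndarray]] = {}
    for name, (ss_eff, ss_err, df1, df2) in table.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(
                ss_err > tiny,
                (ss_eff / df1) / np.maximum(ss_err / df2, 1e-300),
                np.where(ss_eff > tiny, np.inf, 0.0),
            )
        eps = _gg_epsilon(y_flat, contrasts[name])
        p_unc = f_dist.sf(f, df1, df2)
        p_gg = f_dist.sf(f, eps * df1, eps * df2)
        out[name] = {
            "F": f,
            "df_num": df1,
            "df_den": df2,
            "epsilon": eps,
            "p_uncorrected": p_unc,
            "p_gg": np.maximum(p_gg, p_unc),
        }
    return out


def rm_anova(
    table: np.ndarray,
    factor_levels: tuple[int, int] | None = None,
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-way within-subject ANOVA on a balanced subject x cell table.

    ``table`` is either (n_subjects, a, b) or (n_subjects, a*b) with
    ``factor_levels`` = (a, b); cells must be complete (no imputation).
    """
    y = np.asarray(table, dtype=float)
    if y.ndim == 2:
        if factor_levels is None:
            raise DataError("factor_levels required for a flat subject x cell table")
        a, b = factor_levels
        if y.shape[1] != a * b:
            raise DataError("cell count does not match factor_levels")
        y = y.reshape(y.shape[0], a, b)
    elif y.ndim != 3:
        raise DataError("table must be 2-D or 3-D")
    arrays = _rm_anova_arrays(y)
    effects = {}
    rename = {"A": factor_names[0], "B": factor_names[1],
              "A:B": f"{factor_names[0]}:{factor_names[1]}"}
    for key, vals in arrays.items():
        effects[rename[key]] = EffectStats(
            F=float(vals["F"]),
            df_num=float(vals["df_num"]),
            df_den=float(vals["df_den"]),
            epsilon=float(vals["epsilon"]),
            p_uncorrected=float(vals["p_uncorrected"]),
            p_gg=float(vals["p_gg"]),
        )
    return AnovaResult(
        effects=effects,
        factor_names=factor_names,
        factor_levels=(y.shape[1], y.shape[2]),
        n_subjects=y.shape[0],
    )


# ---------------------------------------------------------------------------
# onset detection and sliding scans


def detect_onsets(pvals, alpha: float, min_run: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive samples with p < alpha.

    Returns (first, last) sample indices (inclusive) of each run; the
    interval onset is the first sample of its run.
    """
    p = np.asarray(pvals, dtype=float)
    below = p < alpha
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                intervals.append((start, i - 1))
            start = None
    if start is not None and len(below) - start >= min_run:
        intervals.append((start, len(below) - 1))
    return intervals


@dataclass
class Interval:
    onset_sample: int
    offset_sample: int
    onset_ms: float
    offset_ms: float


@dataclass
class SlidingResult:
    """Per-window p-values and detected significant intervals."""

    window_start_ms: np.ndarray
    window_samples: int
    window_width_ms: float
    pvals: dict[str, np.ndarray]
    intervals: dict[str, list[Interval]]
    alpha: float
    min_run: int
    stats: dict[str, np.ndarray] = field(default_factory=dict)

    def n_windows(self) -> int:
        return len(self.window_start_ms)


def _window_starts(time_ms: np.ndarray, range_ms, window_samples: int):
    """Indices (into the time axis) of window start samples inside range.

    Tested samples satisfy range_lo <= t <= range_hi; windows that would
    run past the end of the tested range are skipped.
    """
    lo, hi = range_ms
    in_range = np.flatnonzero((time_ms >= lo) & (time_ms <= hi))
    if in_range.size < window_samples:
        raise DataError("tested range shorter than one window")
    n_skip = window_samples - 1
    if n_skip:
        logger.debug("skipping %d trailing window position(s)", n_skip)
    return in_range[: in_range.size - n_skip]


def _intervals_from_pvals(
    pvals: np.ndarray,
    starts_ms: np.ndarray,
    width_ms: float,
    alpha: float,
    min_run: int,
) -> list[Interval]:
    out = []
    for i0, i1 in detect_onsets(pvals, alpha, min_run):
        out.append(
            Interval(
                onset_sample=int(i0),
                offset_sample=int(i1),
                onset_ms=float(starts_ms[i0]),
                offset_ms=float(starts_ms[i1] + width_ms),
            )
        )
    return out


def sliding_anova(
    data: np.ndarray,
    time_ms: np.ndarray,
    range_ms=(0.0, 300.0),
    window_samples: int = 3,
    alpha: float | None = None,
    alpha0: float = 0.05,
    lowpass_fc_hz: float = 50.0,
    sampling_rate: float | None = None,
    min_run: int = 5,
    use_gg: bool = True,
    factor_names: tuple[str, str] = ("TASK", "COLOR"),
) -> dict[str, SlidingResult] | SlidingResult:
    """Sample-by-sample two-way rANOVA on short window means.

    ``data``: subjects x a x b x samples array of pooled single-channel
    condition waveforms (all subjects, all cells).  For each window start
    the per-subject cell value is the mean over ``window_samples``
    consecutive samples; the ANOVA runs per window; intervals come from
    :func:`detect_onsets` at the corrected alpha.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise DataError("sliding_anova input must be subjects x a x b x samples")
    time_ms = np.asarray(time_ms, dtype=float)
    if sampling_rate is None:
        dt = float(np.median(np.diff(time_ms)))
        sampling_rate = 1000.0 / dt
    if alpha is None:
        alpha = corrected_alpha(alpha0, lowpass_fc_hz, sampling_rate)
    starts = _window_starts(time_ms, range_ms, window_samples)
    # (W, n, a, b): mean over the window starting at each tested sample
    wins = np.stack(
        [data[..., s : s + window_samples].mean(axis=-1) for s in starts], axis=0
    )
    arrays = _rm_anova_arrays(wins)
    width_ms = window_samples * 1000.0 / sampling_rate
    starts_ms = time_ms[starts]
    rename = {"A": factor_names[0], "B": factor_names[1],
              "A:B": f"{factor_names[0]}:{factor_names[1]}"}
    pvals, intervals, stats = {}, {}, {}
    key = "p_gg" if use_gg else "p_uncorrected"
    for eff, vals in arrays.items():
        name = rename[eff]
        p = vals[key]
        pvals[name] = p
        stats[name] = vals["F"]
        intervals[name] = _intervals_from_pvals(p, starts_ms, width_ms, alpha, min_run)
    return SlidingResult(
        window_start_ms=starts_ms,
        window_samples=window_samples,
        window_width_ms=width_ms,
        pvals=pvals,
        intervals=intervals,
        alpha=alpha,
        min_run=min_run,
        stats=stats,
    )


def sliding_t(
    data: np.ndarray,
    time_ms: np.ndarray,
    range_ms=(0.0, 300.0),
    window_samples: int = 3,
    alpha: float = 0.05,
    min_run: int = 5,
    sampling_rate: float | None = None,
) -> SlidingResult:
    """Explorative sliding paired t-test between two conditions.

    ``data``: subjects x 2 x samples.  Runs an uncorrected-alpha scan by
    default (the explorative mode).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1] != 2:
        raise DataError("sliding_t input must be subjects x 2 x samples")
    time_ms = np.asarray(time_ms, dtype=float)
    if sampling_rate is None:
        dt = float(np.median(np.diff(time_ms)))
        sampling_rate = 1000.0 / dt
    starts = _window_starts(time_ms, range_ms, window_samples)
    d = data[:, 0, :] - data[:, 1, :]
    wins = np.stack(
        [d[:, s : s + window_samples].mean(axis=-1) for s in starts], axis=0
    )  # (W, n)
    n = wins.shape[1]
    if n < 2:
        raise DataError("sliding_t needs at least two subjects")
    md = wins.mean(axis=1)
    sd = wins.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, md / (sd / np.sqrt(n)), np.where(md == 0, 0.0, np.inf))
    p = 2.0 * t_dist.sf(np.abs(t), n - 1)
    p = np.where((sd == 0) & (md != 0), 0.0, p)
    p = np.where((sd == 0) & (md == 0), 1.0, p)
    width_ms = window_samples * 1000.0 / sampling_rate
    starts_ms = time_ms[starts]
    return SlidingResult(
        window_start_ms=starts_ms,
        window_samples=window_samples,
        window_width_ms=width_ms,
        pvals={"pair": p},
        intervals={"pair": _intervals_from_pvals(p, starts_ms, width_ms, alpha, min_run)},
        alpha=alpha,
        min_run=min_run,
        stats={"pair": t},
    )


def split_interaction_anova(amplitudes: np.ndarray) -> AnovaResult:
    """2 x 2 within-subject ANOVA on subject x {early, late} x {fast, slow}
    mean GFBA amplitudes (the early/late-by-fast/slow crossover test)."""
    y = np.asarray(amplitudes, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise DataError("amplitudes must be subjects x 2 (early/late) x 2 (fast/slow)")
    return rm_anova(y, factor_names=("EARLYLATE", "FASTSLOW"))
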