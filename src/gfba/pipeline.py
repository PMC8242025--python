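"""End-to-end orchestration: simulate -> preprocess -> ERP -> stats ->
splits -> source, with disk artifacts per stage and a machine-readable
report.

Stages communicate only through files in the output directory, so running
them individually (``gfba simulate``, ``gfba preprocess``, ...) composes to
the same result as ``gfba all``.  :func:`simulate_dataset` is the in-memory
fast path used for simulation ensembles (power / null-control /
sign-recovery studies): it runs the same generator and preprocessing code
but keeps only the per-subject condition waveforms.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .config import (
    ANALYZED_TRIAL_TYPES,
    SCHEMA_VERSION,
    EffectParams,
    ParadigmConfig,
    PipelineConfig,
    PreprocessParams,
    pipeline_config_to_dict,
)
from .erp import (
    Waveform,
    average_condition,
    difference_wave,
    grand_average,
    mean_amplitude,
    pool_channels,
)
from .errors import DataError, StageError
from .preprocess import (
    baseline_correct,
    extract_epochs,
    filter_behavior,
    reject_artifacts,
    rereference,
    summarize_behavior,
)
from .source import (
    ROI,
    apply_inverse,
    default_lambda,
    make_toy_leadfield,
    mnls_operator,
    reposition_sensors,
    roi_waveform,
)
from .splits import median_rt_split, quartile_rt_split, repetition_split, split_trial_ids
from .stats import corrected_alpha, rm_anova, sliding_anova, split_interaction_anova
from .synth import design_trials, simulate_behavior, synthesize_recording

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# subject-level helpers


def preprocess_subject(
    recording, trials_subject: pd.DataFrame, pp: PreprocessParams
):
    """Re-reference, epoch, reject artifacts, and baseline one subject."""
    reref = rereference(recording, weight=pp.mastoid_weight)
    epochs = extract_epochs(reref, trials_subject, window_ms=pp.epoch_window_ms)
    kept, report = reject_artifacts(epochs, threshold_uv=pp.reject_threshold_uv)
    clean = baseline_correct(kept, baseline_ms=pp.baseline_ms)
    return clean, report


def subject_cell_waveforms(
    epochs, trials_subject: pd.DataFrame, tasks, analysis_channels
):
    """Pooled-channel condition averages for every task x trial-type cell.

    Returns (cells, counts): cells is (2, 3, n_samples) in the order
    tasks x (PC, DC, nontarget); counts the contributing trial numbers.
    """
    n_samp = len(epochs.time_ms)
    cells = np.zeros((len(tasks), len(ANALYZED_TRIAL_TYPES), n_samp))
    counts = np.zeros((len(tasks), len(ANALYZED_TRIAL_TYPES)), dtype=int)
    for i, task in enumerate(tasks):
        for j, ttype in enumerate(ANALYZED_TRIAL_TYPES):
            w = average_condition(epochs, trials_subject, task, ttype)
            pooled = pool_channels(w, analysis_channels)
            cells[i, j] = pooled.data[0]
            counts[i, j] = w.n_trials
    return cells, counts


def _pooled_mean_over(epochs, trial_ids, analysis_channels, time_mask):
    sub = epochs.select(trial_ids)
    if sub.n_epochs == 0:
        return np.nan, 0
    ch_idx = [sub.channel_index(c) for c in analysis_channels]
    return float(sub.data[:, ch_idx][:, :, time_mask].mean()), sub.n_epochs


def subject_split_amplitudes(
    epochs,
    trials_subject: pd.DataFrame,
    effects: EffectParams,
    analysis_channels,
    tie_policy: str = "exclude",
):
    """Early/late x fast/slow mean GFBA amplitudes for color-task DC trials.

    For each RT-median bin the distractor-color minus non-target difference
    is averaged in the early and late windows (the bin's own non-target
    trials serve as reference).  Returns a (2, 2) array, rows (early, late),
    columns (fast, slow), NaN where a bin is empty.
    """
    assign = median_rt_split(trials_subject, tie_policy=tie_policy)
    tagged = trials_subject.merge(assign[["trial_id", "tag"]], on="trial_id")
    color = tagged[tagged["task"] == "color"]
    windows = {
        "early": effects.early_dc_window,
        "late": effects.late_pc_window,
    }
    out = np.full((2, 2), np.nan)
    for col, tag in enumerate(("fast", "slow")):
        bin_trials = color[color["tag"] == tag]
        dc_ids = bin_trials.loc[bin_trials["trial_type"] == "DC", "trial_id"].to_numpy()
        nt_ids = bin_trials.loc[
            bin_trials["trial_type"] == "nontarget", "trial_id"
        ].to_numpy()
        for row, wname in enumerate(("early", "late")):
            lo, hi = windows[wname]
            mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
            dc, n_dc = _pooled_mean_over(epochs, dc_ids, analysis_channels, mask)
            nt, n_nt = _pooled_mean_over(epochs, nt_ids, analysis_channels, mask)
            if n_dc and n_nt:
                out[row, col] = dc - nt
    return out


# ---------------------------------------------------------------------------
# in-memory dataset simulation (ensembles)


@dataclass
class DatasetResult:
    """Per-subject condition waveforms (and optional split amplitudes)."""

    cells: np.ndarray  # (n_subjects, 2 tasks, 3 types, n_samples)
    time_ms: np.ndarray
    counts: np.ndarray  # (n_subjects, 2, 3)
    trials: pd.DataFrame  # all subjects, with behavior + eligibility flags
    split_amplitudes: np.ndarray | None = None  # (n_subjects, 2, 2)
    rejection_fractions: list = field(default_factory=list)


def simulate_dataset(
    paradigm: ParadigmConfig,
    effects: EffectParams,
    seed: int = 0,
    pp: PreprocessParams | None = None,
    with_splits: bool = False,
) -> DatasetResult:
    """Simulate and preprocess one full multi-subject dataset in memory."""
    pp = pp or PreprocessParams()
    trials = design_trials(paradigm, seed=seed)
    trials = simulate_behavior(trials, effects, seed=seed)
    trials = filter_behavior(trials, rt_min_ms=pp.rt_min_ms, rt_max_ms=pp.rt_max_ms)
    cells_list, counts_list, split_list, rej = [], [], [], []
    time_ms = None
    for subject, sub_trials in trials.groupby("subject", sort=True):
        rec = synthesize_recording(sub_trials, effects, paradigm, seed=seed)
        epochs, report = preprocess_subject(rec, sub_trials, pp)
        time_ms = epochs.time_ms
        cells, counts = subject_cell_waveforms(
            epochs, sub_trials, paradigm.tasks, paradigm.analysis_channels
        )
        cells_list.append(cells)
        counts_list.append(counts)
        rej.append(report.rejection_fraction)
        if with_splits:
            split_list.append(
                subject_split_amplitudes(
                    epochs, sub_trials, effects, paradigm.analysis_channels
                )
            )
    return DatasetResult(
        cells=np.stack(cells_list),
        time_ms=time_ms,
        counts=np.stack(counts_list),
        trials=trials,
        split_amplitudes=np.stack(split_list) if with_splits else None,
        rejection_fractions=rej,
    )


# ---------------------------------------------------------------------------
# disk stages


def _subdir(out_dir, name: str) -> Path:
    p = Path(out_dir) / name
    p.mkdir(parents=True, exist_ok=True)
    return p


def _rec_path(out_dir, subject: int) -> Path:
    return _subdir(out_dir, "recordings") / f"sub-{subject:02d}.h5"


def _epo_path(out_dir, subject: int) -> Path:
    return _subdir(out_dir, "epochs") / f"sub-{subject:02d}.h5"


def stage_simulate(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gio.save_config(cfg, out_dir / "config.yaml")
    trials = design_trials(cfg.paradigm, seed=cfg.seed)
    trials = simulate_behavior(trials, cfg.effects, seed=cfg.seed)
    gio.write_trials(trials, out_dir / "trials.tsv")
    for subject, sub_trials in trials.groupby("subject", sort=True):
        rec = synthesize_recording(sub_trials, cfg.effects, cfg.paradigm, seed=cfg.seed)
        gio.write_recording(rec, _rec_path(out_dir, subject))
    summary = {
        "n_subjects": int(trials["subject"].nunique()) if len(trials) else 0,
        "n_trials": int(len(trials)),
        "trial_type_counts": trials["trial_type"].value_counts().to_dict()
        if len(trials)
        else {},
    }
    gio.write_report(summary, out_dir / "simulate.json")
    return summary


def stage_preprocess(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    trials = gio.read_trials(out_dir / "trials.tsv")
    pp = cfg.preprocess
    trials = filter_behavior(trials, rt_min_ms=pp.rt_min_ms, rt_max_ms=pp.rt_max_ms)
    gio.write_trials(trials, out_dir / "trials_flagged.tsv")
    behavior = summarize_behavior(trials)
    behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
    rejections = []
    for subject, sub_trials in trials.groupby("subject", sort=True):
        rec = gio.read_recording(_rec_path(out_dir, subject))
        epochs, report = preprocess_subject(rec, sub_trials, pp)
        gio.write_epochs(epochs, _epo_path(out_dir, subject))
        rejections.append({"subject": int(subject), **report.summary()})
    summary = {
        "n_eligible": int(trials["erp_eligible"].sum()),
        "n_anticipatory": int(trials["anticipatory"].sum()),
        "n_delayed": int(trials["delayed"].sum()),
        "n_incorrect": int(trials["incorrect"].sum()),
        "rejection": rejections,
        "mean_rejection_fraction": float(
            np.mean([r["rejection_fraction"] for r in rejections])
        )
        if rejections
        else 0.0,
        "behavior": behavior.to_dict(orient="records"),
    }
    gio.write_report(summary, out_dir / "preprocess.json")
    return summary


def _read_cells(out_dir):
    path = Path(out_dir) / "cells.h5"
    with h5py.File(path, "r") as f:
        return f["data"][()], f["time_ms"][()], f["counts"][()]


def stage_erp(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    trials = gio.read_trials(out_dir / "trials_flagged.tsv")
    tasks = cfg.paradigm.tasks
    cells_list, counts_list = [], []
    time_ms = None
    sfreq = cfg.paradigm.sampling_rate
    for subject, sub_trials in trials.groupby("subject", sort=True):
        epochs = gio.read_epochs(_epo_path(out_dir, subject))
        time_ms = epochs.time_ms
        cells, counts = subject_cell_waveforms(
            epochs, sub_trials, tasks, cfg.paradigm.analysis_channels
        )
        cells_list.append(cells)
        counts_list.append(counts)
    cells = np.stack(cells_list)
    counts = np.stack(counts_list)
    with h5py.File(out_dir / "cells.h5", "w") as f:
        f.create_dataset("data", data=cells)
        f.create_dataset("time_ms", data=time_ms)
        f.create_dataset("counts", data=counts)
        f.attrs["tasks"] = list(tasks)
        f.attrs["trial_types"] = list(ANALYZED_TRIAL_TYPES)
        f.attrs["schema_version"] = SCHEMA_VERSION

    pooled_name = "+".join(cfg.paradigm.analysis_channels)
    amplitudes = {}
    for i, task in enumerate(tasks):
        grand = {
            ttype: Waveform(
                data=cells[:, i, j].mean(axis=0)[None, :],
                time_ms=time_ms,
                channels=(pooled_name,),
                sampling_rate=sfreq,
                n_trials=cells.shape[0],
                label=f"grand({task}/{ttype})",
            )
            for j, ttype in enumerate(ANALYZED_TRIAL_TYPES)
        }
        for ttype in ("DC", "PC"):
            diff = difference_wave(grand[ttype], grand["nontarget"])
            gio.write_waveform_tsv(
                diff, out_dir / f"diff_{task}_{ttype}_minus_nontarget.tsv"
            )
            amplitudes[f"{task}/{ttype}-nontarget"] = {
                "early_uv": mean_amplitude(diff, cfg.effects.early_dc_window),
                "late_uv": mean_amplitude(diff, cfg.effects.late_pc_window),
            }
    summary = {
        "n_subjects": int(cells.shape[0]),
        "mean_trials_per_cell": counts.mean(axis=0).tolist(),
        "difference_amplitudes": amplitudes,
    }
    gio.write_report(summary, out_dir / "erp.json")
    try:
        from .plotting import plot_condition_waveforms

        plot_condition_waveforms(
            cells, time_ms, tasks, ANALYZED_TRIAL_TYPES, out_dir / "erp_grand.png"
        )
    except Exception as exc:  # plotting must never kill an analysis run
        logger.warning("plotting failed: %s", exc)
    return summary


def stage_stats(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    cells, time_ms, _ = _read_cells(out_dir)
    sp = cfg.stats
    fs = cfg.paradigm.sampling_rate
    alpha = corrected_alpha(sp.alpha0, sp.lowpass_fc_hz, fs)
    result = sliding_anova(
        cells,
        time_ms,
        range_ms=sp.range_ms,
        window_samples=sp.window_samples,
        alpha=alpha,
        sampling_rate=fs,
        min_run=sp.min_run,
        use_gg=sp.use_gg,
    )
    pvals_df = pd.DataFrame(
        {"window_start_ms": result.window_start_ms, **result.pvals}
    )
    pvals_df.to_csv(out_dir / "sliding_pvals.tsv", sep="\t", index=False)
    summary = {
        "alpha": alpha,
        "alpha0": sp.alpha0,
        "lowpass_fc_hz": sp.lowpass_fc_hz,
        "sampling_rate": fs,
        "window_samples": sp.window_samples,
        "window_width_ms": result.window_width_ms,
        "min_run": sp.min_run,
        "tested_range_ms": list(sp.range_ms),
        "canonical_windows_ms": {
            "early": list(cfg.effects.early_dc_window),
            "late": list(cfg.effects.late_pc_window),
        },
        "intervals": {
            eff: [
                {
                    "onset_ms": iv.onset_ms,
                    "offset_ms": iv.offset_ms,
                    "onset_sample": iv.onset_sample,
                    "offset_sample": iv.offset_sample,
                }
                for iv in ivs
            ]
            for eff, ivs in result.intervals.items()
        },
    }
    gio.write_report(summary, out_dir / "stats.json")
    return summary


def stage_splits(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    trials = gio.read_trials(out_dir / "trials_flagged.tsv")
    assigns = [
        median_rt_split(trials, tie_policy=cfg.splits.median_tie_policy),
        quartile_rt_split(trials),
        repetition_split(trials),
    ]
    pd.concat(assigns, ignore_index=True).to_csv(
        out_dir / "splits.tsv", sep="\t", index=False
    )

    # repetition benefit on eligible analyzed trials
    rep = assigns[2].merge(trials, on="trial_id")
    rep = rep[rep["erp_eligible"] & rep["trial_type"].isin(ANALYZED_TRIAL_TYPES)]
    rt_by_tag = rep.groupby("tag")["rt_ms"].mean()
    benefit = float(rt_by_tag.get("switch", np.nan) - rt_by_tag.get("repeat", np.nan))

    # early/late x fast/slow GFBA amplitudes per subject + interaction test
    split_amps = []
    for subject, sub_trials in trials.groupby("subject", sort=True):
        epochs = gio.read_epochs(_epo_path(out_dir, subject))
        split_amps.append(
            subject_split_amplitudes(
                epochs,
                sub_trials,
                cfg.effects,
                cfg.paradigm.analysis_channels,
                tie_policy=cfg.splits.median_tie_policy,
            )
        )
    split_amps = np.stack(split_amps)
    summary: dict = {
        "repetition_benefit_ms": benefit,
        "rt_by_repetition_tag": {k: float(v) for k, v in rt_by_tag.items()},
        "split_amplitudes_mean": np.nanmean(split_amps, axis=0).tolist(),
        "split_amplitude_axes": {
            "rows": ["early", "late"],
            "cols": ["fast", "slow"],
        },
    }
    if np.all(np.isfinite(split_amps)) and split_amps.shape[0] >= 2:
        anova = split_interaction_anova(split_amps)
        inter = anova["EARLYLATE:FASTSLOW"]
        summary["earlylate_by_fastslow"] = {
            "F": inter.F,
            "df": [inter.df_num, inter.df_den],
            "epsilon": inter.epsilon,
            "p_gg": inter.p_gg,
        }
    gio.write_report(summary, out_dir / "splits.json")
    return summary


def stage_source(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    sp = cfg.source
    L = make_toy_leadfield(sp.n_sensors, sp.n_sources, mode=sp.mode, seed=cfg.seed)
    gio.write_leadfield(L, out_dir / "leadfield.h5")
    lam = sp.lam if sp.lam is not None else default_lambda(L)

    # a single active source with a smooth time course stands in for the
    # grand-average data the inverse is applied to
    t = np.arange(0.0, 300.0, 4.0)
    s_true = np.zeros((sp.n_sources, t.size))
    s_true[sp.active_source] = np.exp(-0.5 * ((t - 150.0) / 30.0) ** 2)
    x = L.gain @ s_true

    W = mnls_operator(L, lam)
    est = apply_inverse(W, x, time_ms=t, lam=lam)
    gio.write_source_estimate(est, out_dir / "source_estimate.h5")
    strength = np.abs(est.amplitudes).mean(axis=1)
    peak = int(np.argmax(strength))
    n = sp.n_sources
    err_steps = min((peak - sp.active_source) % n, (sp.active_source - peak) % n)

    roi = ROI(
        label="around_peak",
        source_indices=[
            (peak + k) % n for k in range(-sp.roi_halfwidth, sp.roi_halfwidth + 1)
        ],
    )
    roi_tc = roi_waveform(est, roi)

    # sensor-repositioning round trip onto a rotated copy of the array
    rng = np.random.default_rng([19, cfg.seed])
    perm = np.roll(np.arange(sp.n_sensors), 1)
    L_ind = type(L)(
        gain=L.gain[perm], sensor_names=L.sensor_names, source_locations=L.source_locations
    )
    x_ind = L_ind.gain @ s_true
    x_canon = reposition_sensors(x_ind, L_ind, L, lam=lam)
    repos_err = float(
        np.linalg.norm(x_canon - x) / max(np.linalg.norm(x), 1e-30)
    )
    del rng
    summary = {
        "lambda": lam,
        "localization_error_steps": int(err_steps),
        "roi_peak_strength": float(roi_tc.max()),
        "repositioning_rel_error": repos_err,
    }
    gio.write_report(summary, out_dir / "source.json")
    return summary


def stage_report(cfg: PipelineConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    report: dict = {
        "software_version": __version__,
        "config_hash": config_hash(cfg),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "reject_threshold_uv": cfg.preprocess.reject_threshold_uv,
            "mastoid_weight": cfg.preprocess.mastoid_weight,
            "alignment": cfg.stats.alignment,
            "median_tie_policy": cfg.splits.median_tie_policy,
            "use_gg": cfg.stats.use_gg,
        },
    }
    for stage in ("simulate", "preprocess", "erp", "stats", "splits", "source"):
        path = out_dir / f"{stage}.json"
        if path.exists():
            report[stage] = gio.read_report(path)
    gio.write_report(report, out_dir / "report.json")
    return report


def config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(pipeline_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "erp": stage_erp,
    "stats": stage_stats,
    "splits": stage_splits,
    "source": stage_source,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir) -> dict:
    try:
        return _STAGES[name](cfg, out_dir)
    except KeyError:
        raise StageError(name, "unknown stage") from None
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage in order and return the merged report."""
    stages = ["simulate", "preprocess", "erp", "stats", "splits"]
    if cfg.run_source_stage:
        stages.append("source")
    stages.append("report")
    report = {}
    for name in stages:
        logger.info("running stage %s", name)
        report = run_stage(name, cfg, out_dir)
    return report
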