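"""Configuration objects for the unattended-probe paradigm and its simulation.

Two blocks describe a study: :class:`ParadigmConfig` fixes the trial
structure (tasks, target-color pairs, probe colors, block and trial counts,
timing, montage), :class:`EffectParams` fixes the behavioral and
electrophysiological effect geometry injected by the generator (effect
windows and amplitudes, RT model, noise, blinks).  :class:`PipelineConfig`
nests both together with preprocessing, statistics, split, and source
parameters so a whole run is one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any

from .errors import ConfigError

SCHEMA_VERSION = "1"

TASKS = ("color", "orientation")
TRIAL_TYPES = ("PC", "DC", "nontarget", "magenta")
ANALYZED_TRIAL_TYPES = ("PC", "DC", "nontarget")
MASTOID_LEFT = "M1"
MASTOID_RIGHT = "M2"


@dataclass
class ParadigmConfig:
    """Trial/stimulus structure of the two-task unattended-probe design."""

    n_subjects: int = 22
    blocks_per_task: int = 6
    trials_per_block: int = 180
    tasks: tuple[str, ...] = TASKS
    target_color_pairs: tuple[tuple[str, str], ...] = (
        ("red", "green"),
        ("blue", "yellow"),
    )
    probe_colors: tuple[str, ...] = ("red", "green", "blue", "yellow", "magenta")
    sampling_rate: float = 254.31
    stimulus_duration: float = 300.0
    isi_range: tuple[float, float] = (1000.0, 1200.0)
    channels: tuple[str, ...] = (
        "PO3",
        "PO7",
        "PO4",
        "PO8",
        "Oz",
        MASTOID_LEFT,
        MASTOID_RIGHT,
    )
    analysis_channels: tuple[str, ...] = ("PO3", "PO7")
    block_gap_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.tasks = tuple(self.tasks)
        self.target_color_pairs = tuple(tuple(p) for p in self.target_color_pairs)
        self.probe_colors = tuple(self.probe_colors)
        self.channels = tuple(self.channels)
        self.analysis_channels = tuple(self.analysis_channels)
        self.isi_range = tuple(self.isi_range)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.blocks_per_task < 0 or self.trials_per_block < 0:
            raise ConfigError("block/trial counts must be >= 0")
        if len(self.tasks) != 2:
            raise ConfigError("exactly two tasks are required")
        if not (1 <= len(self.target_color_pairs) <= 2):
            raise ConfigError("one or two target color pairs are required")
        pair_colors = [c for p in self.target_color_pairs for c in p]
        if len(set(pair_colors)) != len(pair_colors):
            raise ConfigError("target color pairs must not share colors")
        extra = set(self.probe_colors) - set(pair_colors)
        if not set(self.probe_colors) >= set(pair_colors) or len(extra) != 1:
            raise ConfigError(
                "probe_colors must be the target colors plus exactly one "
                "extra (never-target) color"
            )
        if self.isi_range[0] > self.isi_range[1]:
            raise ConfigError("isi_range min must be <= max")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        for m in (MASTOID_LEFT, MASTOID_RIGHT):
            if m not in self.channels:
                raise ConfigError(f"channel list must include mastoid '{m}'")
        for c in self.analysis_channels:
            if c not in self.channels:
                raise ConfigError(f"analysis channel '{c}' not in channel list")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channel names must be unique")

    @property
    def extra_probe_color(self) -> str:
        pair_colors = {c for p in self.target_color_pairs for c in p}
        return next(c for c in self.probe_colors if c not in pair_colors)

    @property
    def trial_duration_mean_s(self) -> float:
        isi = 0.5 * (self.isi_range[0] + self.isi_range[1])
        return (self.stimulus_duration + isi) / 1000.0


@dataclass
class EffectParams:
    """Effect geometry injected into behavior and EEG.

    Amplitudes are in µV (negative = the attention-related negativity),
    windows in ms relative to stimulus onset, RT quantities in ms.
    ``early_amp_rt_coupling`` (ms per µV) links the per-trial early
    distractor-color amplitude deviate to RT: positive coupling means a
    larger-magnitude (more negative) early negativity speeds the response.
    """

    early_dc_window: tuple[float, float] = (73.0, 96.0)
    early_dc_amp: float = -0.6
    late_pc_window: tuple[float, float] = (167.0, 254.0)
    late_pc_amp: float = -1.2
    late_dc_amp: float = -0.5
    orientation_task_pc_scale: float = 0.5
    rt_base_mean: float = 400.0
    rt_base_sd: float = 60.0
    dc_rt_cost: float = 12.0
    repetition_benefit: float = 40.0
    early_amp_rt_coupling: float = 50.0
    early_amp_jitter_sd: float = 0.8
    accuracy_rate: float = 0.95
    noise_white_sd: float = 6.0
    noise_pink_sd: float = 3.0
    noise_pink_exponent: float = 1.0
    blink_rate: float = 0.05
    blink_amp: float = 120.0

    def __post_init__(self):
        self.early_dc_window = tuple(self.early_dc_window)
        self.late_pc_window = tuple(self.late_pc_window)
        self.validate()

    def validate(self) -> None:
        for name in ("early_dc_window", "late_pc_window"):
            lo, hi = getattr(self, name)
            if not (-200.0 <= lo <= hi <= 700.0):
                raise ConfigError(f"{name} must lie within [-200, 700] ms")
        for name in ("rt_base_sd", "early_amp_jitter_sd", "noise_white_sd",
                     "noise_pink_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("accuracy_rate", "blink_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if not 0.0 <= self.orientation_task_pc_scale <= 1.0:
            raise ConfigError("orientation_task_pc_scale must be in [0, 1]")


@dataclass
class PreprocessParams:
    """Behavioral filters, epoch window, rejection threshold, baseline."""

    rt_min_ms: float = 200.0
    rt_max_ms: float = 1300.0
    epoch_window_ms: tuple[float, float] = (-200.0, 700.0)
    reject_threshold_uv: float = 100.0
    baseline_ms: tuple[float, float] = (-150.0, 0.0)
    mastoid_weight: float = 0.5

    def __post_init__(self):
        self.epoch_window_ms = tuple(self.epoch_window_ms)
        self.baseline_ms = tuple(self.baseline_ms)
        if self.reject_threshold_uv <= 0:
            raise ConfigError("reject_threshold_uv must be > 0")


@dataclass
class StatsParams:
    """Sliding-scan settings: test range, window width, alpha rule."""

    range_ms: tuple[float, float] = (0.0, 300.0)
    window_samples: int = 3
    alpha0: float = 0.05
    lowpass_fc_hz: float = 50.0
    min_run: int = 5
    use_gg: bool = True
    alignment: str = "left"

    def __post_init__(self):
        self.range_ms = tuple(self.range_ms)
        if self.window_samples < 1:
            raise ConfigError("window_samples must be >= 1")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if self.alignment not in ("left", "center"):
            raise ConfigError("alignment must be 'left' or 'center'")


@dataclass
class SplitParams:
    median_tie_policy: str = "exclude"  # or "slow"

    def __post_init__(self):
        if self.median_tie_policy not in ("exclude", "slow"):
            raise ConfigError("median_tie_policy must be 'exclude' or 'slow'")


@dataclass
class SourceParams:
    """Toy forward model and inverse settings for the source stage."""

    n_sensors: int = 16
    n_sources: int = 40
    mode: str = "ring_geometry"
    lam: float | None = None  # None -> default trace-scaled regularization
    active_source: int = 10
    roi_halfwidth: int = 1


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the YAML file structure."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    effects: EffectParams = field(default_factory=EffectParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    stats: StatsParams = field(default_factory=StatsParams)
    splits: SplitParams = field(default_factory=SplitParams)
    source: SourceParams = field(default_factory=SourceParams)
    run_source_stage: bool = True
    seed: int = 0
    schema_version: str = SCHEMA_VERSION


_SECTION_TYPES = {
    "paradigm": ParadigmConfig,
    "effects": EffectParams,
    "preprocess": PreprocessParams,
    "stats": StatsParams,
    "splits": SplitParams,
    "source": SourceParams,
}


def _build_section(cls, mapping: dict[str, Any], section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in config section '{section}': {sorted(unknown)}"
        )
    try:
        return cls(**mapping)
    except TypeError as exc:  # wrong value shapes
        raise ConfigError(f"invalid '{section}' section: {exc}") from exc


def pipeline_config_from_dict(d: dict[str, Any]) -> PipelineConfig:
    """Build a validated PipelineConfig from a (YAML-loaded) mapping.

    Unknown keys anywhere are rejected rather than silently ignored.
    """
    if not isinstance(d, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {f.name for f in fields(PipelineConfig)}
    unknown = set(d) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in d.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    if str(cfg.schema_version) != SCHEMA_VERSION:
        raise ConfigError(
            f"config schema_version {cfg.schema_version!r} != {SCHEMA_VERSION!r}"
        )
    return cfg


def pipeline_config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = asdict(cfg)

    def _listify(x):
        if isinstance(x, tuple):
            return [_listify(v) for v in x]
        if isinstance(x, dict):
            return {k: _listify(v) for k, v in x.items()}
        return x

    return _listify(d)
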