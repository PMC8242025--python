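"""RT-based and repetition-based trial splits for conditional averaging.

To keep color- and response-specific influences out of the comparison, RT
splits are computed within every unique stimulus display — the combination
of task, target-color pair, target color, target orientation, and probe
color — and the tags are then pooled across displays within trial type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Columns identifying one unique stimulus display (within subject).
DISPLAY_KEY = [
    "subject",
    "task",
    "color_pair",
    "target_color",
    "target_orientation",
    "probe_color",
]


def _eligible(trials: pd.DataFrame) -> pd.DataFrame:
    if "erp_eligible" not in trials.columns:
        raise DataError("trials lack eligibility flags; run filter_behavior first")
    return trials[trials["erp_eligible"]]


def median_rt_split(trials: pd.DataFrame, tie_policy: str = "exclude") -> pd.DataFrame:
    """Tag each eligible trial fast/slow relative to its display's median RT.

    Trials strictly below the median are ``fast``, strictly above ``slow``.
    Trials exactly at the median are ``excluded`` by default (only
    "slower" and "faster" trials are tagged); ``tie_policy="slow"``
    assigns them to the slow bin instead.  Display groups with fewer than
    two trials are excluded entirely.
    """
    if tie_policy not in ("exclude", "slow"):
        raise ConfigError("tie_policy must be 'exclude' or 'slow'")
    elig = _eligible(trials)
    tags = pd.Series("excluded", index=elig.index, dtype=object)
    n_small = 0
    for _, grp in elig.groupby(DISPLAY_KEY, sort=False):
        if len(grp) < 2:
            n_small += 1
            continue
        med = grp["rt_ms"].median()
        tags.loc[grp.index[grp["rt_ms"] < med]] = "fast"
        tags.loc[grp.index[grp["rt_ms"] > med]] = "slow"
        if tie_policy == "slow":
            tags.loc[grp.index[grp["rt_ms"] == med]] = "slow"
    if n_small:
        logger.warning("%d display group(s) with < 2 trials excluded", n_small)
    return pd.DataFrame(
        {"trial_id": elig["trial_id"].to_numpy(), "split": "median_rt", "tag": tags.to_numpy()}
    )


def quartile_rt_split(trials: pd.DataFrame) -> pd.DataFrame:
    """Rank-based RT quartiles within each display group (1 = fastest).

    Ranks split at n/4 boundaries; boundary ties resolve by rank order
    (stable sort on RT), which keeps bins integer-sized and deterministic.
    Groups with fewer than four trials are excluded.
    """
    elig = _eligible(trials)
    tags = pd.Series("excluded", index=elig.index, dtype=object)
    n_small = 0
    for _, grp in elig.groupby(DISPLAY_KEY, sort=False):
        n = len(grp)
        if n < 4:
            n_small += 1
            continue
        order = grp["rt_ms"].to_numpy().argsort(kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        quart = ranks * 4 // n + 1
        tags.loc[grp.index] = [f"q{q}" for q in quart]
    if n_small:
        logger.warning("%d display group(s) with < 4 trials excluded", n_small)
    return pd.DataFrame(
        {"trial_id": elig["trial_id"].to_numpy(), "split": "quartile_rt", "tag": tags.to_numpy()}
    )


def repetition_split(trials: pd.DataFrame) -> pd.DataFrame:
    """Tag trials by whether the target color repeats from the previous
    trial of the same block (repeat/switch; block-first trials undefined).

    Recomputed from the target-color sequence rather than trusting the
    generator's tag, so the split also works on imported trial tables.
    Input must be ordered by trial within block.
    """
    required = {"subject", "block", "trial", "target_color"}
    if not required <= set(trials.columns):
        raise DataError(f"trials missing columns {sorted(required - set(trials.columns))}")
    tags = pd.Series("undefined", index=trials.index, dtype=object)
    for _, grp in trials.groupby(["subject", "block"], sort=False):
        if not grp["trial"].is_monotonic_increasing:
            raise DataError("trials must be ordered by trial index within block")
        tgt = grp["target_color"].to_numpy()
        rep = np.where(
            np.concatenate([["?"], tgt[:-1]]) == tgt, "repeat", "switch"
        ).astype(object)
        rep[0] = "undefined"
        tags.loc[grp.index] = rep
    return pd.DataFrame(
        {"trial_id": trials["trial_id"].to_numpy(), "split": "repetition", "tag": tags.to_numpy()}
    )


def split_trial_ids(assignment: pd.DataFrame, tag: str) -> np.ndarray:
    """Trial ids carrying the given tag in a split assignment."""
    return assignment.loc[assignment["tag"] == tag, "trial_id"].to_numpy()
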