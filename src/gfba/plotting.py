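"""Minimal PNG line plots of condition and difference waveforms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_STYLES = {"PC": "k-", "DC": "0.5", "nontarget": "k--"}


def plot_condition_waveforms(
    cells: np.ndarray, time_ms, tasks, trial_types, path, intervals_ms=None
) -> None:
    """Grand-average condition waveforms per task, one panel per task.

    ``cells``: subjects x tasks x types x samples.  ``intervals_ms`` may
    mark significant windows as shaded spans.
    """
    grand = cells.mean(axis=0)
    fig, axes = plt.subplots(1, len(tasks), figsize=(5 * len(tasks), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for i, (ax, task) in enumerate(zip(axes, tasks)):
        for j, ttype in enumerate(trial_types):
            ax.plot(time_ms, grand[i, j], _STYLES.get(ttype, "-"), label=ttype, lw=1.2)
        if intervals_ms:
            for lo, hi in intervals_ms:
                ax.axvspan(lo, hi, color="tab:orange", alpha=0.2, lw=0)
        ax.axhline(0.0, color="0.8", lw=0.5)
        ax.axvline(0.0, color="0.8", lw=0.5)
        ax.set_title(f"{task} task")
        ax.set_xlabel("time (ms)")
        ax.invert_yaxis()  # negativity up, the field's plotting convention
    axes[0].set_ylabel("amplitude (µV)")
    axes[-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_difference_waves(diffs: dict, time_ms, path, intervals_ms=None) -> None:
    """Difference waveforms (label -> 1-D array) in a single panel."""
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    for label, wave in diffs.items():
        ax.plot(time_ms, np.ravel(wave), label=label, lw=1.2)
    if intervals_ms:
        for lo, hi in intervals_ms:
            ax.axvspan(lo, hi, color="tab:orange", alpha=0.2, lw=0)
    ax.axhline(0.0, color="0.8", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("difference (µV)")
    ax.invert_yaxis()
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
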