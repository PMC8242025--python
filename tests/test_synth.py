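"""Generator: trial design combinatorics, behavior model, EEG synthesis."""

import numpy as np
import pandas as pd
import pytest

from gfba.config import EffectParams, ParadigmConfig, PreprocessParams
from gfba.errors import ConfigError, DataError
from gfba.pipeline import preprocess_subject, subject_cell_waveforms
from gfba.preprocess import filter_behavior, reject_artifacts
from gfba.synth import design_trials, simulate_behavior, synthesize_recording

from conftest import TEST_CHANNELS, quiet_effects, tiny_paradigm


class TestDesignTrials:
    def test_default_counts_per_task(self):
        para = ParadigmConfig(n_subjects=1)
        trials = design_trials(para, seed=0)
        per_task = trials.groupby("task").size()
        assert per_task.to_dict() == {"color": 1080, "orientation": 1080}
        # expected present-target-color count per task: probe uniform over 5
        assert len(trials) / 2 / len(para.probe_colors) == 216
        pc = trials[trials.trial_type == "PC"].groupby("task").size()
        sd = np.sqrt(1080 * 0.2 * 0.8)
        for task in ("color", "orientation"):
            assert abs(pc[task] - 216) < 4 * sd

    def test_zero_blocks_gives_empty_table(self):
        trials = design_trials(tiny_paradigm(blocks_per_task=0), seed=0)
        assert len(trials) == 0

    def test_invalid_color_sets_rejected(self):
        with pytest.raises(ConfigError):
            ParadigmConfig(probe_colors=("red", "green", "blue", "yellow"))
        with pytest.raises(ConfigError):
            ParadigmConfig(target_color_pairs=(("red", "green"), ("red", "blue")))

    def test_display_counts_within_one_pair(self):
        # 3 of 6 color-task blocks share a pair: 540 trials over 20 unique
        # displays (2 targets x 2 orientations x 5 probes) -> 27 each
        para = ParadigmConfig(n_subjects=1)
        trials = design_trials(para, seed=1)
        one = trials[(trials.task == "color") & (trials.color_pair == "red_green")]
        assert len(one) == 540
        counts = one.groupby(
            ["target_color", "target_orientation", "probe_color"]
        ).size()
        assert len(one) / 20 == 27
        sd = np.sqrt(540 * (1 / 20) * (19 / 20))
        assert counts.reindex(
            pd.MultiIndex.from_product(
                [list(para.target_color_pairs[0]), ["left", "right"], list(para.probe_colors)]
            ),
            fill_value=0,
        ).sub(27).abs().max() < 3.3 * sd

    def test_trial_type_invariants(self):
        trials = design_trials(tiny_paradigm(blocks_per_task=4), seed=2)
        pair = trials.color_pair.str.split("_", expand=True)
        other = np.where(trials.target_color == pair[0], pair[1], pair[0])
        assert ((trials.trial_type == "PC") == (trials.probe_color == trials.target_color)).all()
        assert ((trials.trial_type == "DC") == (trials.probe_color == other)).all()
        assert ((trials.trial_type == "magenta") == (trials.probe_color == "magenta")).all()
        first = trials.trial == 0
        assert (trials.loc[first, "repetition"] == "undefined").all()
        assert (trials.loc[~first, "repetition"] != "undefined").all()

    def test_trial_type_proportions(self):
        trials = design_trials(ParadigmConfig(n_subjects=4), seed=3)
        n = len(trials)
        props = {"PC": 0.2, "DC": 0.2, "nontarget": 0.4, "magenta": 0.2}
        counts = trials.trial_type.value_counts()
        for ttype, p in props.items():
            band = 3.3 * np.sqrt(n * p * (1 - p))  # binomial 99.9%
            assert abs(counts[ttype] - n * p) < band

    def test_block_schedule_constraints(self):
        trials = design_trials(ParadigmConfig(n_subjects=4), seed=4)
        for subject, sub in trials.groupby("subject"):
            blocks = sub.groupby("block")[["task", "color_pair"]].first()
            assert (blocks.groupby("task").size() == 6).all()
            # target pair never repeats on subsequent blocks
            assert (blocks.color_pair.values[1:] != blocks.color_pair.values[:-1]).all()

    def test_onsets_cumulate_timing(self):
        para = tiny_paradigm()
        trials = design_trials(para, seed=5)
        block = trials[(trials.subject == 0) & (trials.block == 0)]
        gaps = np.diff(block.onset_s.to_numpy()) * 1000 - para.stimulus_duration
        assert (gaps >= para.isi_range[0] - 1e-9).all()
        assert (gaps <= para.isi_range[1] + 1e-9).all()

    def test_determinism(self):
        para = tiny_paradigm()
        a = design_trials(para, seed=7)
        b = design_trials(para, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = design_trials(para, seed=8)
        assert not a.equals(c)


class TestSimulateBehavior:
    def test_degenerate_generator_constant_rt(self):
        trials = design_trials(tiny_paradigm(), seed=0)
        eff = quiet_effects()
        out = simulate_behavior(trials, eff, seed=0)
        assert (out.rt_ms == eff.rt_base_mean).all()
        assert out.correct.all()

    def test_repetition_benefit_monte_carlo(self):
        # > 10k trials; the generator's own closed form says the
        # switch-minus-repeat RT difference equals repetition_benefit
        para = ParadigmConfig(n_subjects=5)
        eff = EffectParams(repetition_benefit=40.0)
        trials = simulate_behavior(design_trials(para, seed=1), eff, seed=1)
        t = trials[trials.repetition != "undefined"]
        g = t.groupby("repetition")["rt_ms"]
        diff = g.mean()["switch"] - g.mean()["repeat"]
        se = np.sqrt(sum(g.var()[k] / g.size()[k] for k in ("switch", "repeat")))
        assert abs(diff - 40.0) < 3 * se

    def test_default_calibration_fast_and_accurate(self):
        # every task x trial-type cell: mean RT < 410 ms, accuracy > 92%
        trials = simulate_behavior(
            design_trials(ParadigmConfig(n_subjects=4), seed=2), EffectParams(), seed=2
        )
        cells = trials.groupby(["task", "trial_type"])
        assert (cells["rt_ms"].mean() < 410).all()
        assert (cells["correct"].mean() > 0.92).all()

    def test_deviates_only_on_color_task_dc_trials(self):
        trials = simulate_behavior(
            design_trials(tiny_paradigm(blocks_per_task=2), seed=3), EffectParams(), seed=3
        )
        is_dc_color = (trials.trial_type == "DC") & (trials.task == "color")
        assert (trials.loc[~is_dc_color, "early_amp_dev_uv"] == 0).all()
        assert (trials.loc[is_dc_color, "early_amp_dev_uv"] != 0).any()


class TestSynthesizeRecording:
    def _subject_cells(self, para, eff, seed=0):
        trials = filter_behavior(
            simulate_behavior(design_trials(para, seed=seed), eff, seed=seed)
        )
        rec = synthesize_recording(trials, eff, para, seed=seed)
        epochs, _ = preprocess_subject(rec, trials, PreprocessParams())
        cells, counts = subject_cell_waveforms(
            epochs, trials, para.tasks, para.analysis_channels
        )
        return trials, epochs, cells, counts

    def test_no_contrast_when_no_effects(self):
        para = tiny_paradigm(blocks_per_task=2)
        _, _, cells, _ = self._subject_cells(para, quiet_effects())
        # PC, DC, nontarget averages identical sample for sample
        for i in range(2):
            np.testing.assert_allclose(cells[i, 0], cells[i, 1], atol=1e-9)
            np.testing.assert_allclose(cells[i, 0], cells[i, 2], atol=1e-9)

    def test_exact_recovery_of_injected_early_amplitude(self):
        para = tiny_paradigm(blocks_per_task=2)
        eff = quiet_effects(early_dc_amp=-0.8)
        _, epochs, cells, _ = self._subject_cells(para, eff)
        mask = (epochs.time_ms >= 73) & (epochs.time_ms < 96)
        diff = cells[0, 1] - cells[0, 2]  # color task, DC - nontarget
        assert np.mean(diff[mask]) == pytest.approx(-0.8, abs=1e-9)
        # orientation task carries no early effect
        diff_ori = cells[1, 1] - cells[1, 2]
        assert np.mean(diff_ori[mask]) == pytest.approx(0.0, abs=1e-9)

    def test_blink_trials_are_exactly_the_rejected_ones(self):
        para = tiny_paradigm(blocks_per_task=2)
        eff = quiet_effects(blink_rate=0.3, blink_amp=150.0)
        trials = filter_behavior(
            simulate_behavior(design_trials(para, seed=6), eff, seed=6)
        )
        rec = synthesize_recording(trials, eff, para, seed=6)
        from gfba.preprocess import extract_epochs, rereference

        epochs = extract_epochs(rereference(rec), trials)
        # planted blinks are the only way past 100 µV in a noiseless record
        kept, report = reject_artifacts(epochs, threshold_uv=100.0)
        planted = set(
            epochs.trial_ids[(epochs.data.max(axis=(1, 2)) > 100.0)].tolist()
        )
        flagged = set(report.p2p.index[report.rejected].tolist())
        assert flagged == planted
        assert 0 < len(planted) < epochs.n_epochs
        _, report_hi = reject_artifacts(epochs, threshold_uv=300.0)
        assert not report_hi.rejected.any()

    def test_mastoids_carry_no_template(self):
        para = tiny_paradigm()
        eff = quiet_effects(early_dc_amp=-0.8)
        trials = filter_behavior(
            simulate_behavior(design_trials(para, seed=1), eff, seed=1)
        )
        rec = synthesize_recording(trials, eff, para, seed=1)
        for name in ("M1", "M2"):
            assert np.allclose(rec.data[rec.channel_index(name)], 0.0)

    def test_window_outside_epoch_is_config_error(self):
        para = tiny_paradigm()
        eff = quiet_effects()
        eff.early_dc_window = (-100.0, -50.0)
        trials = simulate_behavior(design_trials(para, seed=0), quiet_effects(), seed=0)
        with pytest.raises(ConfigError):
            synthesize_recording(trials, eff, para, seed=0)

    def test_recording_determinism(self):
        para = tiny_paradigm()
        eff = EffectParams()
        trials = simulate_behavior(design_trials(para, seed=9), eff, seed=9)
        a = synthesize_recording(trials, eff, para, seed=9)
        b = synthesize_recording(trials, eff, para, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.events, b.events)

    def test_multiple_subjects_rejected(self):
        trials = simulate_behavior(
            design_trials(tiny_paradigm(n_subjects=2), seed=0), quiet_effects(), seed=0
        )
        with pytest.raises(DataError):
            synthesize_recording(trials, quiet_effects(), tiny_paradigm(n_subjects=2))
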