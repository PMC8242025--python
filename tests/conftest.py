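import numpy as np
import pytest

from gfba.config import EffectParams, ParadigmConfig, PreprocessParams

#: compact montage used throughout the tests (analysis pair + mastoids)
TEST_CHANNELS = ("PO3", "PO7", "M1", "M2")


def tiny_paradigm(**kw) -> ParadigmConfig:
    base = dict(
        n_subjects=1,
        blocks_per_task=1,
        trials_per_block=40,
        channels=TEST_CHANNELS,
    )
    base.update(kw)
    return ParadigmConfig(**base)


def quiet_effects(**kw) -> EffectParams:
    """No noise, no blinks, no effects, no RT variability unless overridden."""
    base = dict(
        early_dc_amp=0.0,
        late_pc_amp=0.0,
        late_dc_amp=0.0,
        noise_white_sd=0.0,
        noise_pink_sd=0.0,
        blink_rate=0.0,
        rt_base_sd=0.0,
        early_amp_jitter_sd=0.0,
        early_amp_rt_coupling=0.0,
        dc_rt_cost=0.0,
        repetition_benefit=0.0,
        accuracy_rate=1.0,
    )
    base.update(kw)
    return EffectParams(**base)


@pytest.fixture(scope="session")
def quiet_subject():
    """One noiseless subject: trials (flagged) + clean baselined epochs."""
    from gfba.pipeline import preprocess_subject
    from gfba.preprocess import filter_behavior
    from gfba.synth import design_trials, simulate_behavior, synthesize_recording

    para = tiny_paradigm(blocks_per_task=2)
    eff = quiet_effects(early_dc_amp=-0.8, late_pc_amp=-1.2, late_dc_amp=-0.5)
    trials = design_trials(para, seed=3)
    trials = simulate_behavior(trials, eff, seed=3)
    trials = filter_behavior(trials)
    rec = synthesize_recording(trials, eff, para, seed=3)
    epochs, _ = preprocess_subject(rec, trials, PreprocessParams())
    return para, eff, trials, epochs
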