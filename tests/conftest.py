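import numpy as np
import pytest

from ratseiz import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """Short 4-channel recording at a desk-friendly rate, with seizures."""
    cfg = SynthConfig(
        duration=240.0,
        sampling_rate=256.0,
        seizure_rate_per_hour=45.0,
        seizure_duration_range=(4.0, 20.0),
        seed=42,
    )
    rec, track, meta = generate_recording(cfg)
    return rec, track, meta


@pytest.fixture(scope="session")
def default_recording_30min():
    """30-min recording under the generator's default (study-like) conditions."""
    cfg = SynthConfig(duration=1800.0, seed=1)
    rec, track, meta = generate_recording(cfg)
    return rec, track, meta


@pytest.fixture(scope="session")
def e2e_experiment():
    """Scaled-down train/evaluate experiment shared by the acceptance tests.

    Training record: 20 min with an ictal fraction inside the 1-10%
    training-window criterion.  Evaluation record: 60 min under the default
    simulator conditions.  Both image modes are trained and scored.
    """
    from ratseiz import TrainingConfig, run_detection_experiment

    train_cfg = SynthConfig(
        duration=1200.0,
        seizure_rate_per_hour=12.0,
        seizure_duration_range=(4.0, 20.0),
        seed=101,
    )
    eval_cfg = SynthConfig(duration=3600.0, seed=202)
    train_rec, train_track, _ = generate_recording(train_cfg)
    eval_rec, eval_track, _ = generate_recording(eval_cfg)
    results = run_detection_experiment(
        train_rec,
        train_track,
        eval_rec,
        eval_track,
        TrainingConfig(seed=7),
    )
    return {
        "results": results,
        "train_track": train_track,
        "train_duration": train_rec.duration,
        "eval_track": eval_track,
        "eval_duration": eval_rec.duration,
    }
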