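"""Shared fixtures: small synthetic trials and the default evaluation suite.

Everything is generated at test time from fixed seeds; nothing is loaded
from disk.
"""
import numpy as np
import pytest

from sonokin.pipeline import ExperimentConfig, run_experiment
from sonokin.synthetic import TrialConfig, generate_trial


def small_config(**kw) -> TrialConfig:
    """A short trial that exercises every pipeline stage quickly."""
    base = dict(duration_s=16.0, frame_shape=(32, 32), pulse_times=(2.0, 12.0),
                seed=0)
    base.update(kw)
    return TrialConfig(**base)


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(small_config(seed=4))


@pytest.fixture(scope="session")
def small_fes_trial():
    return generate_trial(small_config(seed=5, fes_condition="ON"))


@pytest.fixture(scope="session")
def default_trial():
    """Full-length trial at the default (noise-on) study conditions."""
    return generate_trial(TrialConfig(seed=3))


@pytest.fixture(scope="session")
def noise_free_trials():
    """Fixed-seed noise-free suite: one trial per joint × FES condition."""
    trials = []
    for i, (joint, cond) in enumerate(
        [("wrist", "OFF"), ("wrist", "ON"), ("ankle", "OFF"), ("ankle", "ON")]
    ):
        cfg = TrialConfig(joint=joint, fes_condition=cond,
                          seed=100 + i).noise_free()
        trials.append(generate_trial(cfg))
    return trials


@pytest.fixture(scope="session")
def default_suite_report():
    """The default 40-trial experiment (2 joints × 2 conditions × 10)."""
    report, failures = run_experiment(
        ExperimentConfig(trials_per_cell=10, global_seed=1)
    )
    assert not failures
    return report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
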