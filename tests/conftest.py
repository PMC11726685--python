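import numpy as np
import pytest

from nordiceval import SimConfig, generate_design, generate_ground_truth, synthesize_run

#: reduced design that fits a short (120-volume) run: 10 trials
SMALL_TRIALS = {"PredH": 3, "PredL": 3, "MispredH": 1, "MispredL": 1,
                "UnpredH": 1, "UnpredL": 1}


def small_config(**overrides) -> SimConfig:
    kwargs = dict(
        grid_shape=(16, 12, 12),
        n_volumes=120,
        n_noise_scans=5,
        trials_per_condition=dict(SMALL_TRIALS),
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_run():
    """One short simulated run shared by read-only tests."""
    cfg = small_config()
    truth = generate_ground_truth(cfg)
    design = generate_design(cfg)
    ts = synthesize_run(design, truth, cfg)
    return cfg, truth, design, ts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
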