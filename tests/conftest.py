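import dataclasses

import pytest

from targetmet.simulate import SimulationConfig, simulate_experiment


def noiseless_config(**overrides) -> SimulationConfig:
    """Zero mass error, zero RT jitter, zero sample noise, no baseline."""
    base = dict(
        seed=11,
        n_metabolites=10,
        n_samples_per_group=3,
        n_blanks=2,
        mass_error_ppm_sd=0.0,
        rt_jitter_sd_s=0.0,
        sample_cv=0.0,
        baseline_level=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def noiseless_experiment():
    return simulate_experiment(noiseless_config())


@pytest.fixture(scope="session")
def noisy_experiment():
    """Realistic noise levels: 2 ppm mass error, 2 s RT jitter, 20% CV."""
    config = SimulationConfig(
        seed=5,
        n_metabolites=12,
        n_samples_per_group=6,
        n_blanks=2,
        true_log2fc={"glucose": 1.0, "lactate": -1.0},
    )
    return simulate_experiment(config)


@pytest.fixture()
def replace_config():
    return dataclasses.replace
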