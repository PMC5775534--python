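"""Shared fixtures: a small simulated dataset reused across test modules."""

import pytest

from retrosilence.simulate import SimulationConfig, build_toy_genome


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=11,
        n_classes=3,
        copies_per_class=4,
        copy_length_range=(1000, 6500),
        inter_copy_divergence=0.02,
        read_length=50,
        library_sizes={
            "control_1": 8000,
            "control_2": 8000,
            "control_3": 8000,
            "depleted_1": 8000,
            "depleted_2": 8000,
            "depleted_3": 8000,
        },
        n_peaks=100,
        bs_reads_per_treatment=500,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def toy_genome(sim_config):
    return build_toy_genome(sim_config)
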