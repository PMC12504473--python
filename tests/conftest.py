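"""Shared fixtures: small, fast simulation artifacts reused across tests."""

import pytest

from pulmoflow.evaluation import HyperparameterGrid
from pulmoflow.pipeline import ExperimentConfig, generate_dataset
from pulmoflow.simulator import BASELINE_PARAMETERS, run_simulation


@pytest.fixture(scope="session")
def baseline_lf():
    """Baseline-parameter low-fidelity simulation (solution, response)."""
    return run_simulation(BASELINE_PARAMETERS, "L", cloud_seed=11)


@pytest.fixture(scope="session")
def baseline_hf():
    """Baseline-parameter high-fidelity simulation (solution, response)."""
    return run_simulation(BASELINE_PARAMETERS, "H", cloud_seed=12)


@pytest.fixture(scope="session")
def tiny_config():
    """Scaled-down experiment used for fast pipeline tests."""
    return ExperimentConfig(
        n_high=8,
        n_low=30,
        n_high_train=6,
        seed=3,
        epochs=200,
        n_el={"H": 16, "L": 4},
        cloud_size={"H": 80, "L": 30},
        waveform_steps=24,
        grid=HyperparameterGrid(
            lambdas=(1e-3,), n_neurons=(16,), n_layers=(2,), activations=("tanh",)
        ),
        cost_times=(2.9, 162.0),
    )


@pytest.fixture(scope="session")
def tiny_datasets(tiny_config):
    """(high, low) datasets for the tiny experiment."""
    return (
        generate_dataset(tiny_config, "H"),
        generate_dataset(tiny_config, "L"),
    )


@pytest.fixture(scope="session")
def table1_box_draws():
    """100 Latin-hypercube parameter draws from the sampling box."""
    from pulmoflow.pipeline import sample_parameter_space

    return sample_parameter_space(100, seed=7)
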