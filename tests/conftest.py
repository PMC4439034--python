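"""Shared fixtures: small synthetic datasets with known planted structure."""

import numpy as np
import pytest

from sigselect import ExpressionDataset, SimulationSpec, generate_progression


@pytest.fixture(scope="session")
def planted():
    """Planted 3-stage dataset (strong signal, no redundancy) + truth list."""
    spec = SimulationSpec(
        n_genes=60,
        n_informative=6,
        n_samples_per_class=8,
        effect_size=1.0,
        noise_sd=0.5,
        n_redundant_blocks=0,
        seed=11,
    )
    return generate_progression(spec)


@pytest.fixture(scope="session")
def planted_dataset(planted):
    return planted[0]


@pytest.fixture(scope="session")
def planted_truth(planted):
    return planted[1]


@pytest.fixture()
def tiny_two_class():
    """Hand-built 3-gene x 6-sample dataset where g0 separates the classes."""
    values = np.array(
        [
            [-2.0, -1.8, -2.2, 2.0, 1.9, 2.1],  # perfect separator
            [0.1, -0.2, 0.3, 0.2, -0.1, 0.0],  # noise
            [1.0, 1.1, 0.9, 1.0, 1.05, 0.95],  # near-constant
        ]
    )
    samples = tuple(f"s{i}" for i in range(6))
    labels = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
    return ExpressionDataset(("g0", "g1", "g2"), samples, values, labels)
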