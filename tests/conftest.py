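"""Shared fixtures: a small-scale synthetic study used across test modules."""

import numpy as np
import pytest

from theriacomp import SimulationConfig, generate_truth, export_fixture


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down study design: same structure, ~600 genes for speed."""
    defaults = dict(
        n_genes=600,
        organ_program_size=40,
        early_program_size=40,
        late_program_size=12,
        coopted_size=15,
        eutherian_only_size=15,
        n_de_genes=20,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(small_sim_config(seed=0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_truth):
    """An exported fixture tree for the small synthetic study."""
    directory = tmp_path_factory.mktemp("fixture")
    export_fixture(small_truth, directory)
    return directory


def nb_counts(rng: np.random.Generator, mu, alpha):
    """NB(mu, alpha) with variance mu + alpha * mu^2 (test-side sampler)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    size = 1.0 / np.maximum(alpha, 1e-12)
    return rng.negative_binomial(size, size / (size + mu))
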