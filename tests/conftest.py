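"""Shared fixtures.

Heavier simulated fixtures are session-scoped so several test modules
can reuse one simulation.
"""

from __future__ import annotations

import pytest

from demosmc.demography import (
    MODEL_A_BEST_FIT,
    ModelSpec,
    ParameterVector,
    SampleConfig,
)


@pytest.fixture(scope="session")
def model_a_spec() -> ModelSpec:
    return ModelSpec("A")


@pytest.fixture(scope="session")
def best_fit_params(model_a_spec) -> ParameterVector:
    return ParameterVector("A", MODEL_A_BEST_FIT)


@pytest.fixture(scope="session")
def canonical_samples(model_a_spec) -> SampleConfig:
    return SampleConfig.canonical_csfs(model_a_spec)


@pytest.fixture(scope="session")
def pseudo_observed_a():
    """Pseudo-observed Model-A fixture at 50 Mb (shared by correlation,
    recovery, and acceptance checks)."""
    from demosmc.synthetic_data import make_pseudo_observed

    params = ParameterVector("A", MODEL_A_BEST_FIT)
    return make_pseudo_observed("A", params, 50e6, seed=424, chunk_length=10e6)


@pytest.fixture(scope="session")
def model_a_chunk(model_a_spec, best_fit_params, canonical_samples):
    """One 5 Mb simulated chunk under best-fit model A."""
    from demosmc.demography import build_demography
    from demosmc.simulate import SimulationPlan, simulate_genomes

    dem = build_demography(model_a_spec, best_fit_params)
    return list(simulate_genomes(
        dem, canonical_samples, SimulationPlan(5e6, 5e6, base_seed=99)))
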