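import hypothesis
import pytest

import urnball as ub

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def conditions():
    return ub.PAPER_CONDITIONS


@pytest.fixture(scope="session")
def fixture_data():
    """Full factorial synthetic dataset (16 x 4 x 50) plus truth sidecar."""
    return ub.paper_design_fixture(seed=11)


@pytest.fixture(scope="session")
def small_pooled_data():
    """Small single-condition dataset generated by the pooled model."""
    cfg = ub.GeneratorConfig(
        n_participants=4,
        n_trials=25,
        conditions=(ub.PAPER_CONDITIONS["PuLu"],),
        generative_model="weighted_pooled",
        true_params=ub.WeightingParams(0.7, 0.4),
        seed=5,
    )
    trials, truth = ub.generate_experiment(cfg)
    return trials, truth


@pytest.fixture(scope="session")
def tiny_config():
    """Very small sampler config for structural (non-inferential) tests."""
    return ub.SamplerConfig(chains=2, iterations=400, warmup=200, seed=9)
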