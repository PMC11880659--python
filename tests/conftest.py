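"""Shared fixtures: the study-mirror design, scenario truths, and one
moderately sized fitted model reused by the summary-level tests."""

import warnings

import pytest

from covary.design import DesignConfig
from covary.model import ModelSpec, SamplerSettings, build_model
from covary.sampler import sample_posterior
from covary.synthetic import generate_population, known_truth_default


@pytest.fixture(scope="session")
def design():
    """3 treatments x 4 mesocosms x 12 males, 2 behaviours on 3 trials."""
    return DesignConfig(seed=2024)


@pytest.fixture(scope="session")
def paper_like_truth(design):
    return known_truth_default("paper-like", design)


@pytest.fixture(scope="session")
def paper_like_table(design, paper_like_truth):
    return generate_population(design, paper_like_truth, seed=2024)


@pytest.fixture(scope="session")
def model_spec(design):
    return ModelSpec(
        trait_names=design.trait_names,
        repeated_flags=design.repeated_flags,
        treatment_levels=design.treatment_names,
    )


@pytest.fixture(scope="session")
def fitted_draws(model_spec, paper_like_table):
    """One short fit on paper-like data, shared by summary tests."""
    model = build_model(model_spec, paper_like_table)
    settings = SamplerSettings(chains=2, iterations=700, warmup=250, thin=1, seed=99)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sample_posterior(model, settings)
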