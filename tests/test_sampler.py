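"""Sampler correctness: conjugate closed forms, prior-predictive agreement,
determinism, draw-count arithmetic and row-order exchangeability."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covary.errors import ConfigError
from covary.model import ModelSpec, PriorSet, SamplerSettings, build_model
from covary.sampler import sample_posterior
from covary.synthetic import generate_population


def _single_trait_table(y):
    return pd.DataFrame(
        {
            "individual_id": [f"i{j}" for j in range(len(y))],
            "mesocosm_id": "m1",
            "treatment": "control",
            "trait": "x",
            "occasion": 1,
            "value": y,
        }
    )


def _toy_spec(sigma2, priors=None):
    return ModelSpec(
        trait_names=("x",),
        repeated_flags=(False,),
        include_mesocosm=False,
        include_individual=False,
        fixed_resid_var=sigma2,
        priors=priors or PriorSet.flat(),
    )


def test_conjugate_toy_posterior_matches_closed_form():
    """Known residual variance, near-flat prior: mu | y ~ N(ybar, sigma2/n)."""
    rng = np.random.default_rng(17)
    n, sigma2 = 30, 0.8
    y = rng.normal(0.9, np.sqrt(sigma2), n)
    prior_prec = 1.0 / PriorSet.flat().fixed_scale**2
    post_prec = n / sigma2 + prior_prec
    exact_mean = (y.sum() / sigma2) / post_prec
    exact_sd = np.sqrt(1.0 / post_prec)

    model = build_model(_toy_spec(sigma2), _single_trait_table(y))
    draws = sample_posterior(
        model, SamplerSettings(chains=2, iterations=3000, warmup=500, thin=1, seed=4)
    )
    mu = draws.flat("mu")[:, 0]
    mc_se = exact_sd / np.sqrt(mu.size)  # draws are iid in this conjugate case
    assert mu.mean() == pytest.approx(exact_mean, abs=3 * mc_se)
    sd_se = exact_sd / np.sqrt(2 * (mu.size - 1))
    assert mu.std(ddof=1) == pytest.approx(exact_sd, abs=3 * sd_se)
    assert draws.metadata["max_rhat"] < 1.01


def test_prior_predictive_group_sd_follows_stated_prior():
    """With the likelihood dropped, sampled mesocosm variances follow the
    inverse-gamma prior (Kolmogorov-Smirnov at 5000 draws)."""
    spec = ModelSpec(
        trait_names=("x",),
        repeated_flags=(False,),
        include_mesocosm=True,
        include_individual=False,
    )
    model = build_model(spec, _single_trait_table(np.zeros(6)))
    draws = sample_posterior(
        model,
        SamplerSettings(chains=1, iterations=6000, warmup=1000, thin=1, seed=8),
        prior_only=True,
    )
    v = draws.flat("sigma2_meso")[:, 0]
    pri = spec.priors
    ks = stats.kstest(v, stats.invgamma(pri.var_shape, scale=pri.var_rate).cdf)
    assert ks.pvalue > 0.01


def test_same_seed_reruns_are_bit_identical(model_spec, paper_like_table):
    model = build_model(model_spec, paper_like_table)
    settings = SamplerSettings(chains=2, iterations=60, warmup=20, thin=2, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = sample_posterior(model, settings)
        b = sample_posterior(model, settings)
        c = sample_posterior(
            model, SamplerSettings(chains=2, iterations=60, warmup=20, thin=2, seed=6)
        )
    for name in ("mu", "beta", "gamma", "sigma2_meso", "Sigma_B", "sigma2_W"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
    assert not np.array_equal(a.mu, c.mu)


def test_draw_count_equals_chains_times_kept_over_thin(model_spec, paper_like_table):
    model = build_model(model_spec, paper_like_table)
    settings = SamplerSettings(chains=3, iterations=50, warmup=19, thin=2, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        draws = sample_posterior(model, settings)
    expected = 3 * int(np.ceil((50 - 19) / 2))
    assert draws.n_draws == expected == settings.total_draws
    assert draws.mu.shape == (3, 16, 8)


def test_full_settings_arithmetic_and_toy_convergence():
    """At the full run settings (4 chains, 8000 iterations, 3000 warmup,
    thinning 2) the sampler retains 10000 draws; on a conjugate toy it
    converges with split-Rhat at 1."""
    y = np.random.default_rng(2).normal(size=20)
    model = build_model(_toy_spec(1.0), _single_trait_table(y))
    settings = SamplerSettings(seed=3)  # defaults are the full-length run
    assert settings.total_draws == 10000
    draws = sample_posterior(model, settings)
    assert draws.n_draws == 10000
    assert draws.metadata["max_rhat"] <= 1.01
    assert draws.metadata["converged"]


def test_row_order_exchangeability(model_spec, paper_like_table):
    """Permuting input rows leaves the draws unchanged (canonical sort)."""
    shuffled = paper_like_table.sample(frac=1.0, random_state=3)
    settings = SamplerSettings(chains=2, iterations=60, warmup=20, thin=1, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = sample_posterior(build_model(model_spec, paper_like_table), settings)
        b = sample_posterior(build_model(model_spec, shuffled), settings)
    np.testing.assert_array_equal(a.Sigma_B, b.Sigma_B)
    np.testing.assert_array_equal(a.mu, b.mu)


def test_prior_robustness_on_study_mirror_data(design, paper_like_truth, model_spec):
    """Weakly-informative vs flat priors shift fixed-effect posterior
    means by < 0.1 SD units on study-mirror synthetic data."""
    table = generate_population(design, paper_like_truth, seed=31)
    settings = SamplerSettings(chains=4, iterations=1500, warmup=300, thin=1, seed=13)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        weak = sample_posterior(build_model(model_spec, table), settings)
        flat = sample_posterior(
            build_model(model_spec.with_priors(PriorSet.flat()), table), settings
        )
    for name in ("mu", "beta", "gamma"):
        delta = np.abs(
            weak.flat(name).mean(axis=0) - flat.flat(name).mean(axis=0)
        )
        assert float(np.max(delta)) < 0.1


def test_settings_require_seed_and_valid_warmup():
    with pytest.raises(ConfigError):
        SamplerSettings(seed=None)
    with pytest.raises(ConfigError):
        SamplerSettings(iterations=100, warmup=100, seed=1)


def test_correlation_draws_are_valid_matrices(fitted_draws):
    corr = fitted_draws.corr_B()
    diag = np.einsum("...ii->...i", corr)
    assert np.allclose(diag, 1.0)
    assert np.all(corr <= 1.0 + 1e-9) and np.all(corr >= -1.0 - 1e-9)
    eigs = np.linalg.eigvalsh(corr.reshape(-1, 8, 8))
    assert eigs.min() > -1e-8
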