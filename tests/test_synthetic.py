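"""Generator contracts: design arithmetic, degenerate limits, moment
matching against the law of total variance, and seed determinism."""

import numpy as np
import pandas as pd
import pytest

from covary.design import DesignConfig, ParameterSet, is_psd
from covary.errors import ConfigError, ValidationError
from covary.synthetic import SCENARIOS, generate_population, known_truth_default


def test_study_mirror_row_counts(design, paper_like_table):
    # 2 behaviours x 3 trials x 144 + 6 single traits x 144 = 1728 rows
    assert design.n_individuals == 144
    assert len(paper_like_table) == 1728
    assert paper_like_table["individual_id"].nunique() == 144
    assert paper_like_table["mesocosm_id"].nunique() == 12
    assert set(paper_like_table["treatment"]) == {"control", "low", "high"}


def test_single_measure_traits_have_one_occasion(design, paper_like_table):
    counts = paper_like_table.groupby(["individual_id", "trait"])["occasion"].count()
    for trait, repeated in zip(design.trait_names, design.repeated_flags):
        per_trait = counts.xs(trait, level="trait")
        expected = design.n_trials_behaviour if repeated else 1
        assert (per_trait == expected).all()


def test_degenerate_generator_returns_trait_means(design):
    k, t = design.n_traits, design.n_treatments
    mu = np.arange(k, dtype=float)
    truth = ParameterSet(
        mu=mu,
        beta_treat=np.zeros((t - 1, k)),
        gamma_trial=np.zeros(2),
        sigma_mesocosm=np.zeros(k),
        Sigma_B=np.zeros((t, k, k)),
        sigma_W=np.zeros((t, 2)),
        sigma_fixed=0.0,
    )
    table = generate_population(design, truth, seed=1)
    for ki, trait in enumerate(design.trait_names):
        assert (table.loc[table["trait"] == trait, "value"] == mu[ki]).all()


def test_between_individual_variance_of_means_matches_total_variance_law():
    """With Sigma_B = I and sigma_W = 1, the variance of per-individual
    behaviour means is 1 + 1/n_trials."""
    config = DesignConfig(
        n_treatments=1,
        n_mesocosms_per_treatment=1,
        n_individuals_per_mesocosm=2000,
        seed=5,
    )
    k = config.n_traits
    truth = ParameterSet(
        mu=np.zeros(k),
        beta_treat=np.zeros((0, k)),
        gamma_trial=np.zeros(2),
        sigma_mesocosm=np.zeros(k),
        Sigma_B=np.eye(k)[None],
        sigma_W=np.ones((1, 2)),
        sigma_fixed=0.0,
    )
    table = generate_population(config, truth, seed=5)
    expected = 1.0 + 1.0 / config.n_trials_behaviour
    tol = 4.0 * expected * np.sqrt(2.0 / 2000)  # ~4 SEs of a variance estimate
    for trait in ("activity", "refuge_use"):
        means = (
            table[table["trait"] == trait].groupby("individual_id")["value"].mean()
        )
        assert means.var(ddof=1) == pytest.approx(expected, abs=tol)


def test_seed_determinism_and_seed_sensitivity(design, paper_like_truth):
    a = generate_population(design, paper_like_truth, seed=42)
    b = generate_population(design, paper_like_truth, seed=42)
    c = generate_population(design, paper_like_truth, seed=43)
    pd.testing.assert_frame_equal(a, b)
    assert not np.allclose(a["value"], c["value"])


@pytest.mark.parametrize("scenario", SCENARIOS)
def test_all_scenarios_produce_valid_psd_truth(scenario, design):
    truth = known_truth_default(scenario, design)
    truth.validate(design)
    for mat in truth.Sigma_B:
        assert is_psd(mat)


def test_null_scenario_is_truly_null(design):
    truth = known_truth_default("null", design)
    assert not truth.beta_treat.any()
    assert not truth.gamma_trial.any()
    for mat in truth.Sigma_B:
        off = mat - np.diag(np.diag(mat))
        assert not off.any()


def test_paper_like_within_variance_ordering(design):
    """Control males are more behaviourally variable than exposed ones."""
    truth = known_truth_default("paper-like", design)
    control, low, high = truth.sigma_W
    assert (control > low).all()
    assert (control > high).all()


def test_paper_like_activity_refuge_syndrome_negative(design):
    truth = known_truth_default("paper-like", design)
    i = design.trait_names.index("activity")
    j = design.trait_names.index("refuge_use")
    for mat in truth.Sigma_B:
        assert mat[i, j] < 0


def test_unknown_scenario_rejected(design):
    with pytest.raises(ConfigError):
        known_truth_default("made-up", design)


def test_dimension_mismatch_rejected(design):
    truth = known_truth_default("null", design)
    truth.mu = truth.mu[:-1]
    with pytest.raises(ConfigError):
        generate_population(design, truth, seed=0)


def test_non_psd_sigma_b_rejected(design):
    truth = known_truth_default("null", design)
    bad = truth.Sigma_B.copy()
    bad[0, 0, 1] = bad[0, 1, 0] = 5.0  # correlation > 1 given unit-ish SDs
    truth.Sigma_B = bad
    with pytest.raises(ValidationError):
        generate_population(design, truth, seed=0)
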