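"""Posterior summaries: credible intervals, dV contrasts, correlations,
repeatability and report tables as pure functions of draws."""

import numpy as np
import pytest

from covary.errors import InvalidRequestError
from covary.summaries import (
    between_individual_correlations,
    ci_excludes_zero,
    credible_interval,
    delta_v,
    delta_v_table,
    repeatability,
    summarize_fixed_effects,
    variance_component_table,
)


def test_credible_interval_standard_normal_89():
    rng = np.random.default_rng(0)
    draws = rng.standard_normal(1_000_000)
    lo, hi = credible_interval(draws, 0.89)
    assert lo == pytest.approx(-1.598, abs=0.01)
    assert hi == pytest.approx(1.598, abs=0.01)


def test_credible_interval_constant_draws():
    lo, hi = credible_interval(np.full(500, 3.25), 0.89)
    assert (lo, hi) == (3.25, 3.25)


def test_credible_interval_nesting():
    rng = np.random.default_rng(1)
    draws = rng.gamma(2.0, size=5000)
    lo89, hi89 = credible_interval(draws, 0.89)
    lo95, hi95 = credible_interval(draws, 0.95)
    assert lo95 <= lo89 <= hi89 <= hi95


def test_credible_interval_warns_on_few_draws():
    with pytest.warns(UserWarning, match="draws"):
        credible_interval(np.arange(20.0), 0.89)


@pytest.mark.parametrize(
    "interval,expected",
    [((0.1, 0.5), True), ((-0.1, 0.5), False), ((-0.5, -0.1), True), ((0.0, 0.5), False)],
)
def test_ci_excludes_zero(interval, expected):
    assert ci_excludes_zero(interval) is expected


def test_delta_v_of_group_with_itself_is_zero(fitted_draws):
    c = delta_v(fitted_draws, "activity", "within", "low", "low")
    assert np.all(c.draws == 0.0)
    assert c.mean == 0.0


def test_delta_v_antisymmetry(fitted_draws):
    ab = delta_v(fitted_draws, "activity", "within", "control", "low")
    ba = delta_v(fitted_draws, "activity", "within", "low", "control")
    np.testing.assert_allclose(ab.draws, -ba.draws)
    assert ab.ci89[0] == pytest.approx(-ba.ci89[1])


def test_delta_v_within_rejected_for_once_measured_trait(fitted_draws):
    with pytest.raises(InvalidRequestError):
        delta_v(fitted_draws, "coloration", "within", "control", "low")


def test_delta_v_recovers_within_variance_ordering(fitted_draws):
    """Generating truth has control within-activity variance 0.65 vs low
    0.34: the contrast posterior should sit near +0.31 and be supported."""
    c = delta_v(fitted_draws, "activity", "within", "control", "low")
    assert c.mean == pytest.approx(0.31, abs=0.25)
    assert c.mean > 0


def test_correlation_summary_structure(fitted_draws):
    summ = between_individual_correlations(fitted_draws, "control")
    assert summ.mean_matrix.shape == (8, 8)
    np.testing.assert_allclose(np.diag(summ.mean_matrix), 1.0)
    np.testing.assert_allclose(summ.mean_matrix, summ.mean_matrix.T, atol=1e-12)
    assert len(summ.table) == 28  # unique pairs of 8 traits
    assert summ.table["ci89_low"].between(-1, 1).all()
    assert summ.table["ci89_high"].between(-1, 1).all()


def test_activity_refuge_syndrome_recovered_negative(fitted_draws):
    summ = between_individual_correlations(fitted_draws, "control")
    row = summ.table[
        (summ.table["trait_a"] == "activity") & (summ.table["trait_b"] == "refuge_use")
    ].iloc[0]
    assert row["mean"] < 0  # generating truth is -0.4


def test_repeatability_definition_and_bounds(fitted_draws):
    r = repeatability(fitted_draws, "activity", "control")
    assert 0.0 < r["mean"] < 1.0
    assert 0.0 <= r["ci89_low"] <= r["ci89_high"] <= 1.0
    # behaviour truth: V_B = 0.35, V_W = 0.65 for control activity
    assert r["mean"] == pytest.approx(0.35, abs=0.2)
    with pytest.raises(InvalidRequestError):
        repeatability(fitted_draws, "coloration", "control")


def test_repeatability_half_when_variances_equal(fitted_draws):
    vb = fitted_draws.flat("Sigma_B")[:, 0, 0, 0]
    vw = fitted_draws.flat("sigma2_W")[:, 0, 0]
    r = vb / (vb + vw)
    # direct identity check: if V_B == V_W every draw gives exactly 0.5
    np.testing.assert_allclose(vb / (vb + vb), 0.5)
    assert np.all((r > 0) & (r < 1))


def test_fixed_effect_table_layout(fitted_draws):
    tab = summarize_fixed_effects(fitted_draws)
    # 8 intercepts + 8 traits x 2 treatment terms + 2 trial slopes
    assert len(tab) == 8 + 16 + 2
    assert set(tab.columns) >= {"trait", "term", "mean", "ci89_low", "ci95_high", "supported"}
    trial = tab[tab["term"] == "trial"]
    assert set(trial["trait"]) == {"activity", "refuge_use"}


def test_trial_slope_recovered(fitted_draws):
    tab = summarize_fixed_effects(fitted_draws)
    row = tab[(tab["trait"] == "activity") & (tab["term"] == "trial")].iloc[0]
    assert row["mean"] == pytest.approx(-0.22, abs=0.1)  # generating truth


def test_delta_v_table_covers_all_contrasts(fitted_draws):
    tab = delta_v_table(fitted_draws)
    # between: 8 traits x 3 pairs; within: 2 behaviours x 3 pairs
    assert len(tab) == 8 * 3 + 2 * 3
    assert set(tab["level"]) == {"between", "within"}


def test_variance_component_table(fitted_draws):
    tab = variance_component_table(fitted_draws)
    # between: 8 traits x 3 treatments; within: 2 x 3
    assert len(tab) == 24 + 6
    assert (tab["ci89_low"] >= 0).all()
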