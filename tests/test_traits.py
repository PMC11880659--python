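"""Trait derivation: worked examples, a brute-force SMA oracle, and
algebraic invariants fuzzed with hypothesis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covary.errors import ConfigError, DegenerateDataError, DomainError
from covary.traits import (
    EjaculateRecord,
    MorphometricRecord,
    SmiParams,
    coloration_proportion,
    derive_trait_table,
    fit_sma_slope,
    mean_vcl,
    scaled_mass_index,
    sperm_count,
    sperm_vitality,
    standardize,
    unstandardize,
)

finite = st.floats(
    min_value=0.1, max_value=100.0, allow_nan=False, allow_infinity=False
)


# ---- scaled mass index ----------------------------------------------------


def test_sma_slope_is_three_on_cubic_data():
    lengths = np.array([10.0, 14.0, 17.0, 21.0, 25.0])
    assert fit_sma_slope(lengths**3, lengths) == pytest.approx(3.0, abs=1e-12)


def test_sma_slope_matches_brute_force_oracle():
    """OLS-slope / Pearson-r recomputed from first-principle sums."""
    rng = np.random.default_rng(7)
    ln_l = np.log(17.43) + rng.standard_normal(50) * 0.1
    ln_m = -11.4 + 3.2 * ln_l + rng.standard_normal(50) * 0.05
    masses, lengths = np.exp(ln_m), np.exp(ln_l)

    x, y = np.log(lengths), np.log(masses)
    n = len(x)
    sx, sy, sxx, syy, sxy = x.sum(), y.sum(), (x * x).sum(), (y * y).sum(), (x * y).sum()
    b_ols = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    assert fit_sma_slope(masses, lengths) == pytest.approx(b_ols / r, abs=1e-10)


def test_sma_slope_rejects_bad_inputs():
    with pytest.raises(DomainError):
        fit_sma_slope([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateDataError):
        fit_sma_slope([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    with pytest.raises(DomainError):
        fit_sma_slope([1.0, 2.0], [1.0, 2.0])


@given(scale=finite)
@settings(max_examples=50, deadline=None)
def test_sma_slope_invariant_to_mass_rescaling(scale):
    lengths = np.array([11.0, 13.0, 16.0, 19.0, 23.0])
    masses = lengths**2.9 * np.array([1.05, 0.97, 1.02, 0.99, 1.01])
    base = fit_sma_slope(masses, lengths)
    assert fit_sma_slope(masses * scale, lengths) == pytest.approx(base, rel=1e-9)


@pytest.mark.parametrize(
    "mass,length,params,expected",
    [
        (2.0, 10.0, SmiParams(3.0, 20.0), 16.0),     # 2 * (20/10)^3
        (0.5, 17.43, SmiParams(3.203, 17.43), 0.5),  # at reference length
        (0.5, 12.0, SmiParams(0.0, 17.43), 0.5),     # zero exponent
    ],
)
def test_scaled_mass_index_examples(mass, length, params, expected):
    assert scaled_mass_index(mass, length, params) == pytest.approx(expected)


@given(mass=finite, length=finite, k=finite)
@settings(max_examples=50, deadline=None)
def test_smi_scale_equivariant_in_mass(mass, length, k):
    params = SmiParams(3.203, 17.43)
    assert scaled_mass_index(k * mass, length, params) == pytest.approx(
        k * scaled_mass_index(mass, length, params), rel=1e-9
    )


def test_smi_rejects_nonpositive():
    with pytest.raises(DomainError):
        scaled_mass_index(-1.0, 10.0, SmiParams(3.0, 20.0))


# ---- coloration -----------------------------------------------------------


def _morpho(orange, black, body=100.0):
    return MorphometricRecord("m1", 0.5, 17.0, 3.5, body, orange, black)


@pytest.mark.parametrize(
    "orange,black,expected", [(10.0, 5.0, 0.15), (0.0, 0.0, 0.0), (60.0, 40.0, 1.0)]
)
def test_coloration_proportion_examples(orange, black, expected):
    assert coloration_proportion(_morpho(orange, black)) == pytest.approx(expected)


def test_coloration_exceeding_body_area_rejected():
    with pytest.raises(DomainError):
        _morpho(80.0, 30.0)


# ---- ejaculate traits -----------------------------------------------------


def _ejac(live, dead, vcl=((100.0, 50),), dilution=1.0, volume=1.0):
    return EjaculateRecord("m1", tuple(vcl), tuple(live), tuple(dead), dilution, volume)


@pytest.mark.parametrize(
    "live,dead,expected",
    [
        ((20, 30, 25), (0, 0, 0), 1.0),
        ((10, 10, 10), (10, 10, 10), 0.5),
        ((12, 8, 10), (3, 2, 5), 0.75),
    ],
)
def test_sperm_vitality_examples(live, dead, expected):
    assert sperm_vitality(_ejac(live, dead)) == pytest.approx(expected)


def test_sperm_vitality_undefined_on_zero_total():
    with pytest.raises(DegenerateDataError):
        sperm_vitality(_ejac((0, 0, 0), (0, 0, 0)))


@pytest.mark.parametrize(
    "live,dead,dilution,volume,expected",
    [
        ((50, 50, 50), (0, 0, 0), 1.0, 1.0, 50.0),
        ((40, 50, 60), (0, 0, 0), 10.0, 1.0, 500.0),
        ((0, 0, 0), (0, 0, 0), 10.0, 1.0, 0.0),
    ],
)
def test_sperm_count_examples(live, dead, dilution, volume, expected):
    assert sperm_count(_ejac(live, dead, dilution=dilution, volume=volume)) == pytest.approx(expected)


def test_sperm_count_requires_dilution_factor():
    with pytest.raises(ConfigError):
        sperm_count(_ejac((10, 10, 10), (1, 1, 1), dilution=None))


@pytest.mark.parametrize(
    "samples,expected",
    [
        (((100.0, 50), (100.0, 80)), 100.0),
        (((90.0, 30), (120.0, 60)), 110.0),  # (90*30 + 120*60)/90
        (((75.0, 40),), 75.0),
    ],
)
def test_mean_vcl_weighted_examples(samples, expected):
    assert mean_vcl(_ejac((1,), (0,), vcl=samples)) == pytest.approx(expected)


@given(
    live=st.lists(st.integers(0, 500), min_size=1, max_size=3),
    dead=st.lists(st.integers(0, 500), min_size=3, max_size=3),
)
@settings(max_examples=100, deadline=None)
def test_vitality_bounds_on_fuzzed_counts(live, dead):
    dead = dead[: len(live)]
    if sum(live) + sum(dead) == 0:
        return
    v = sperm_vitality(_ejac(tuple(live), tuple(dead)))
    assert 0.0 <= v <= 1.0
    assert sperm_count(_ejac(tuple(live), tuple(dead), dilution=7.0)) >= 0.0


# ---- standardization ------------------------------------------------------


def test_standardize_zscores_and_left_centres(paper_like_table):
    std, params = standardize(paper_like_table)
    assert set(std["occasion"]) == {0, 1, 2}
    assert sorted(set(paper_like_table["occasion"])) == [1, 2, 3]
    for trait, grp in std.groupby("trait"):
        assert grp["value"].mean() == pytest.approx(0.0, abs=1e-12)
        assert grp["value"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)


def test_standardize_round_trip(paper_like_table):
    std, params = standardize(paper_like_table)
    back = unstandardize(std, params)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), paper_like_table.reset_index(drop=True)
    )


def test_standardize_rejects_constant_trait(paper_like_table):
    broken = paper_like_table.copy()
    broken.loc[broken["trait"] == "coloration", "value"] = 0.3
    with pytest.raises(DegenerateDataError, match="coloration"):
        standardize(broken)


# ---- wide-table derivation ------------------------------------------------


def test_derive_trait_table_from_synthetic_raw_measurements():
    from covary.synthetic import simulate_ejaculates, simulate_morphometrics

    morpho = simulate_morphometrics(60, seed=3)
    ej = simulate_ejaculates(60, seed=4)
    derived = derive_trait_table(morpho, ej)
    assert len(derived) == 60
    assert set(derived.columns) >= {
        "body_condition",
        "coloration",
        "gonopodium_length",
        "sperm_vitality",
        "sperm_velocity",
        "sperm_count",
    }
    assert derived["coloration"].between(0, 1).all()
    assert derived["sperm_vitality"].between(0, 1).all()
    assert (derived["sperm_count"] >= 0).all()
    # recovered allometric exponent close to the generating value
    slope = fit_sma_slope(morpho["body_mass"], morpho["standard_length"])
    assert slope == pytest.approx(3.203, abs=0.25)
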