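"""Simulation-based validation: parameter recovery and null calibration.

These studies close the loop between the generator and the sampler: data
are simulated from known truth at the full experimental design (144
males, 3 trials), refitted, and the posterior checked against the
generating values.  Replicate fits use shortened chains (2 x 800
iterations, 300 warmup); the full-length settings are reserved for
single production fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, ParameterSet
from .model import ModelSpec, SamplerSettings, build_model
from .sampler import PosteriorDraws, sample_posterior
from .summaries import credible_interval
from .synthetic import generate_population, known_truth_default

REPLICATE_SETTINGS = dict(chains=2, iterations=800, warmup=300, thin=1)


def _corr(truth: ParameterSet, g: int, i: int, j: int) -> float:
    s = truth.Sigma_B[g]
    return float(s[i, j] / np.sqrt(s[i, i] * s[j, j]))


def generating_parameters(
    truth: ParameterSet, config: DesignConfig
) -> list[tuple[str, float]]:
    """The named generating values checked for credible-interval coverage.

    Covers fixed effects, between-individual variances, within-individual
    variances, mesocosm SDs and the activity-refuge syndrome correlation
    in each treatment.
    """
    names = config.trait_names
    levels = config.treatment_names
    ia = names.index("activity")
    ir = names.index("refuge_use")
    out = []
    for ki, name in enumerate(names):
        out.append((f"mu:{name}", float(truth.mu[ki])))
    for gi, level in enumerate(levels[1:]):
        for ki, name in enumerate(names):
            out.append((f"beta:{level}:{name}", float(truth.beta_treat[gi, ki])))
    for bi, name in enumerate(config.repeated_traits):
        out.append((f"gamma:{name}", float(truth.gamma_trial[bi])))
    for ki, name in enumerate(names):
        out.append((f"sd_meso:{name}", float(truth.sigma_mesocosm[ki])))
    for gi, level in enumerate(levels):
        for ki, name in enumerate(names):
            out.append((f"v_between:{level}:{name}", float(truth.Sigma_B[gi, ki, ki])))
        for bi, name in enumerate(config.repeated_traits):
            out.append((f"v_within:{level}:{name}", float(truth.sigma_W[gi, bi] ** 2)))
        out.append((f"corr_act_ref:{level}", _corr(truth, gi, ia, ir)))
    return out


def posterior_draws_for(
    name: str, draws: PosteriorDraws, config: DesignConfig
) -> np.ndarray:
    """Flat posterior draws of one named generating parameter."""
    kind, *rest = name.split(":")
    names = list(config.trait_names)
    levels = list(config.treatment_names)
    beh = list(config.repeated_traits)
    if kind == "mu":
        return draws.flat("mu")[:, names.index(rest[0])]
    if kind == "beta":
        level, trait = rest
        gi = list(draws.treatment_levels).index(level) - 1
        return draws.flat("beta")[:, gi, names.index(trait)]
    if kind == "gamma":
        return draws.flat("gamma")[:, beh.index(rest[0])]
    if kind == "sd_meso":
        return np.sqrt(draws.flat("sigma2_meso")[:, names.index(rest[0])])
    if kind == "v_between":
        level, trait = rest
        gi = list(draws.treatment_levels).index(level)
        ki = names.index(trait)
        return draws.flat("Sigma_B")[:, gi, ki, ki]
    if kind == "v_within":
        level, trait = rest
        gi = list(draws.treatment_levels).index(level)
        return draws.flat("sigma2_W")[:, gi, beh.index(trait)]
    if kind == "corr_act_ref":
        gi = list(draws.treatment_levels).index(rest[0])
        ia, ir = names.index("activity"), names.index("refuge_use")
        sb = draws.flat("Sigma_B")[:, gi]
        return sb[:, ia, ir] / np.sqrt(sb[:, ia, ia] * sb[:, ir, ir])
    raise KeyError(name)


def _replicate_fit(config, truth, seed, settings_kwargs):
    table = generate_population(config, truth, seed=seed)
    spec = ModelSpec(
        trait_names=config.trait_names,
        repeated_flags=config.repeated_flags,
        treatment_levels=config.treatment_names,
    )
    model = build_model(spec, table)
    settings = SamplerSettings(seed=seed, **settings_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # short-chain ESS flags
        return sample_posterior(model, settings)


@dataclass
class RecoveryResult:
    table: pd.DataFrame          # one row per replicate x parameter
    coverage_95: float           # overall fraction of 95% CIs covering truth
    syndrome_sign_correct: int   # replicates with negative control act-ref corr
    n_replicates: int


def run_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    scenario: str = "paper-like",
    settings_kwargs: dict | None = None,
) -> RecoveryResult:
    """Replicated simulate-refit coverage check at the full design size."""
    config = DesignConfig(seed=seed)
    truth = known_truth_default(scenario, config)
    params = generating_parameters(truth, config)
    settings_kwargs = settings_kwargs or REPLICATE_SETTINGS
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    sign_ok = 0
    for rep, rep_seed in enumerate(seeds):
        draws = _replicate_fit(config, truth, int(rep_seed), settings_kwargs)
        for name, true_val in params:
            post = posterior_draws_for(name, draws, config)
            lo, hi = credible_interval(post, 0.95)
            rows.append(
                {
                    "replicate": rep,
                    "parameter": name,
                    "truth": true_val,
                    "post_mean": float(post.mean()),
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "covered": bool(lo <= true_val <= hi),
                }
            )
        control_corr = posterior_draws_for("corr_act_ref:control", draws, config)
        if control_corr.mean() < 0:
            sign_ok += 1
    table = pd.DataFrame(rows)
    return RecoveryResult(
        table=table,
        coverage_95=float(table["covered"].mean()),
        syndrome_sign_correct=sign_ok,
        n_replicates=n_replicates,
    )


@dataclass
class CalibrationResult:
    table: pd.DataFrame
    exclusion_rate_89: float     # fraction of null treatment effects "supported"
    n_tests: int
    n_replicates: int


def run_calibration_study(
    n_replicates: int = 20,
    seed: int = 1,
    settings_kwargs: dict | None = None,
) -> CalibrationResult:
    """Type-I-like calibration: under the null scenario, how often does an
    89% CI on a treatment fixed effect exclude zero?  Nominally ~11%."""
    config = DesignConfig(seed=seed)
    truth = known_truth_default("null", config)
    settings_kwargs = settings_kwargs or REPLICATE_SETTINGS
    seeds = np.random.SeedSequence(seed + 10_000).generate_state(n_replicates) % (2**31)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        draws = _replicate_fit(config, truth, int(rep_seed), settings_kwargs)
        beta = draws.flat("beta")
        for gi, level in enumerate(draws.treatment_levels[1:]):
            for ki, trait in enumerate(config.trait_names):
                lo, hi = credible_interval(beta[:, gi, ki], 0.89)
                rows.append(
                    {
                        "replicate": rep,
                        "treatment": level,
                        "trait": trait,
                        "ci89_low": lo,
                        "ci89_high": hi,
                        "excluded_zero": bool(lo > 0 or hi < 0),
                    }
                )
    table = pd.DataFrame(rows)
    return CalibrationResult(
        table=table,
        exclusion_rate_89=float(table["excluded_zero"].mean()),
        n_tests=len(table),
        n_replicates=n_replicates,
    )
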