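"""Posterior summaries: credible intervals, variance contrasts (dV),
between-individual correlations, repeatability and fixed-effect tables.

All summaries are pure functions of the stored draws, so regenerating a
report from serialized draws is bit-identical.  Inference follows the
89%-credible-interval rule (an effect is "supported" when its 89%
equal-tailed interval excludes zero), with the 95% interval reported
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidRequestError
from .sampler import PosteriorDraws

LEVELS = (0.89, 0.95)


def credible_interval(draws, level: float) -> tuple[float, float]:
    """Equal-tailed posterior quantile interval at ``level``."""
    arr = np.asarray(draws, dtype=float).ravel()
    if not 0 < level < 1:
        raise InvalidRequestError("credible level must lie in (0, 1)")
    if arr.size < 100:
        warnings.warn(
            f"only {arr.size} draws; credible interval endpoints are imprecise",
            UserWarning,
            stacklevel=2,
        )
    alpha = (1 - level) / 2
    lo, hi = np.quantile(arr, [alpha, 1 - alpha])
    return float(lo), float(hi)


def ci_excludes_zero(interval) -> bool:
    """True iff the interval lies strictly on one side of zero."""
    lo, hi = interval
    return bool(lo > 0 or hi < 0)


def _summ(arr) -> dict:
    arr = np.asarray(arr, dtype=float).ravel()
    ci89 = credible_interval(arr, 0.89)
    ci95 = credible_interval(arr, 0.95)
    return {
        "mean": float(arr.mean()),
        "ci89_low": ci89[0],
        "ci89_high": ci89[1],
        "ci95_low": ci95[0],
        "ci95_high": ci95[1],
        "supported": ci_excludes_zero(ci89),
    }


def _trait_index(draws: PosteriorDraws, trait: str) -> int:
    try:
        return draws.trait_names.index(trait)
    except ValueError:
        raise InvalidRequestError(f"unknown trait {trait!r}") from None


def _treat_index(draws: PosteriorDraws, treatment: str) -> int:
    try:
        return draws.treatment_levels.index(treatment)
    except ValueError:
        raise InvalidRequestError(f"unknown treatment {treatment!r}") from None


def variance_draws(draws: PosteriorDraws, trait: str, level: str, treatment: str) -> np.ndarray:
    """Flat draws of one variance component.

    ``level`` is ``"between"`` (diagonal of the between-individual
    covariance) or ``"within"`` (residual variance; behaviours only).
    """
    ki = _trait_index(draws, trait)
    ti = _treat_index(draws, treatment)
    if level == "between":
        return draws.flat("Sigma_B")[:, ti, ki, ki]
    if level == "within":
        if trait not in draws.behaviours:
            raise InvalidRequestError(
                f"within-individual variance is undefined for once-measured trait {trait!r}"
            )
        return draws.flat("sigma2_W")[:, ti, draws.behaviours.index(trait)]
    raise InvalidRequestError(f"level must be 'between' or 'within', got {level!r}")


@dataclass
class VarianceContrast:
    """Posterior contrast V(group_a) - V(group_b) for one trait and level.

    Both group labels are explicit: the sign convention is always
    minuend (group_a) minus subtrahend (group_b).
    """

    trait: str
    level: str
    group_a: str
    group_b: str
    draws: np.ndarray
    mean: float
    ci89: tuple[float, float]
    ci95: tuple[float, float]

    @property
    def supported(self) -> bool:
        return ci_excludes_zero(self.ci89)


def delta_v(
    draws: PosteriorDraws, trait: str, level: str, group_a: str, group_b: str
) -> VarianceContrast:
    """Draw-wise difference of two variance components (dV).

    dVA contrasts between-individual variances (any trait); dVW contrasts
    within-individual variances (behaviours only).
    """
    va = variance_draws(draws, trait, level, group_a)
    vb = variance_draws(draws, trait, level, group_b)
    diff = va - vb
    return VarianceContrast(
        trait=trait,
        level=level,
        group_a=group_a,
        group_b=group_b,
        draws=diff,
        mean=float(diff.mean()),
        ci89=credible_interval(diff, 0.89),
        ci95=credible_interval(diff, 0.95),
    )


def delta_v_table(draws: PosteriorDraws) -> pd.DataFrame:
    """All pairwise dV contrasts: between-level for every trait, within-level
    for behaviours, for each ordered treatment pair (a earlier than b)."""
    rows = []
    levels = draws.treatment_levels
    for trait in draws.trait_names:
        for lev in ("between", "within"):
            if lev == "within" and trait not in draws.behaviours:
                continue
            for i, a in enumerate(levels):
                for b in levels[i + 1 :]:
                    c = delta_v(draws, trait, lev, a, b)
                    rows.append(
                        {
                            "trait": trait,
                            "level": lev,
                            "group_a": a,
                            "group_b": b,
                            "mean": c.mean,
                            "ci89_low": c.ci89[0],
                            "ci89_high": c.ci89[1],
                            "ci95_low": c.ci95[0],
                            "ci95_high": c.ci95[1],
                            "supported": c.supported,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class CorrelationSummary:
    """Posterior between-individual correlation structure for one treatment."""

    treatment: str
    trait_names: tuple[str, ...]
    mean_matrix: np.ndarray
    table: pd.DataFrame  # one row per unique off-diagonal pair


def between_individual_correlations(
    draws: PosteriorDraws, treatment: str
) -> CorrelationSummary:
    """Posterior mean and CIs for every unique between-individual trait pair."""
    ti = _treat_index(draws, treatment)
    corr_all = draws.corr_B()
    corr = corr_all.reshape((-1,) + corr_all.shape[2:])[:, ti]
    k = len(draws.trait_names)
    mean_matrix = corr.mean(axis=0)
    np.fill_diagonal(mean_matrix, 1.0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            s = _summ(corr[:, i, j])
            rows.append(
                {"trait_a": draws.trait_names[i], "trait_b": draws.trait_names[j], **s}
            )
    return CorrelationSummary(
        treatment=treatment,
        trait_names=draws.trait_names,
        mean_matrix=mean_matrix,
        table=pd.DataFrame(rows),
    )


def repeatability(draws: PosteriorDraws, trait: str, treatment: str) -> dict:
    """Posterior of V_B / (V_B + V_W): the share of total behavioural
    variance due to stable individual differences."""
    if trait not in draws.behaviours:
        raise InvalidRequestError(
            f"repeatability is undefined for once-measured trait {trait!r}"
        )
    vb = variance_draws(draws, trait, "between", treatment)
    vw = variance_draws(draws, trait, "within", treatment)
    r = vb / (vb + vw)
    out = _summ(r)
    out["draws"] = r
    return out


def summarize_fixed_effects(draws: PosteriorDraws) -> pd.DataFrame:
    """Per trait x coefficient: posterior mean, 89%/95% CIs, supported flag."""
    rows = []
    for ki, trait in enumerate(draws.trait_names):
        rows.append({"trait": trait, "term": "intercept", **_summ(draws.flat("mu")[:, ki])})
        for gi, level in enumerate(draws.treatment_levels[1:]):
            rows.append(
                {"trait": trait, "term": f"treatment[{level}]", **_summ(draws.flat("beta")[:, gi, ki])}
            )
        if trait in draws.behaviours:
            bi = draws.behaviours.index(trait)
            rows.append({"trait": trait, "term": "trial", **_summ(draws.flat("gamma")[:, bi])})
    return pd.DataFrame(rows)


def variance_component_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summaries of every variance component per treatment."""
    rows = []
    for trait in draws.trait_names:
        for treatment in draws.treatment_levels:
            rows.append(
                {
                    "trait": trait,
                    "treatment": treatment,
                    "level": "between",
                    **_summ(variance_draws(draws, trait, "between", treatment)),
                }
            )
            if trait in draws.behaviours:
                rows.append(
                    {
                        "trait": trait,
                        "treatment": treatment,
                        "level": "within",
                        **_summ(variance_draws(draws, trait, "within", treatment)),
                    }
                )
    return pd.DataFrame(rows)
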