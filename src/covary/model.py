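"""Bayesian multivariate mixed model: specification, data build, log density.

The observation model, per individual i (treatment t(i), mesocosm m(i)),
trait k, occasion o:

    y_iko = mu_k + beta_{t(i),k} + gamma_k * trial_o   [behaviours only]
            + a_{m(i),k} + u_{i,k} + eps_iko

    u_i     ~ MVN(0, Sigma_B^{t(i)})       between-individual, per treatment
    a_{m,k} ~ N(0, sigma_meso_k^2)         mesocosm intercept, per trait
    eps     ~ N(0, sigma_W_{t,k}^2)        behaviours: free, per treatment
    eps     ~ N(0, 0.01)                   once-measured traits: pinned

Residuals are independent across traits within an occasion; all
between-trait association is carried by Sigma_B.  Priors are a conjugate
family (Gaussian fixed effects, inverse-gamma variances, inverse-Wishart
covariances) so the posterior admits exact block-Gibbs updates; draws of
Sigma_B are reported as SD vectors plus correlation matrices.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import FIXED_RESIDUAL_SD
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class PriorSet:
    """Conjugate prior family.

    ``fixed_scale``: SD of the Normal(0, s^2) prior on each fixed effect
    (standardized scale).  ``var_shape``/``var_rate``: inverse-gamma prior
    on scalar variances (mesocosm, within-individual); the default
    IG(0.35, 0.02) puts the implied SD's central 90% mass on roughly
    (0.1, 12) so that small group variances (the mesocosm component has
    only 12 levels to inform it) are not pushed upward by the prior.
    ``wishart_df_margin``: inverse-Wishart df = n_traits + margin; margin 2
    keeps a proper prior with near-uniform marginal correlations.
    ``wishart_scale_diag``: diagonal of the inverse-Wishart scale matrix.
    """

    flavour: str = "weakly-informative"
    fixed_scale: float = 1.0
    var_shape: float = 0.35
    var_rate: float = 0.02
    wishart_df_margin: float = 2.0
    wishart_scale_diag: float = 1.0

    @classmethod
    def weakly_informative(cls) -> "PriorSet":
        return cls()

    @classmethod
    def flat(cls) -> "PriorSet":
        """Very diffuse flavour for the prior-robustness check."""
        return cls(
            flavour="flat",
            fixed_scale=100.0,
            var_shape=0.001,
            var_rate=0.001,
            wishart_df_margin=1.0,
            wishart_scale_diag=0.001,
        )


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.  Defaults are the full-length run:
    4 chains, 8000 iterations with 3000 warmup, thinning 2 (10000 retained
    draws in total)."""

    chains: int = 4
    iterations: int = 8000
    warmup: int = 3000
    thin: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 1 or self.thin < 1:
            raise ConfigError("chains, iterations and thin must be >= 1")
        if not 0 <= self.warmup < self.iterations:
            raise ConfigError("warmup must satisfy 0 <= warmup < iterations")
        if self.seed is None:
            raise ConfigError("a seed is required for every stochastic step")

    @property
    def draws_per_chain(self) -> int:
        return int(np.ceil((self.iterations - self.warmup) / self.thin))

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


@dataclass(frozen=True)
class ModelSpec:
    """Trait roster, design structure and priors of the multivariate model."""

    trait_names: tuple[str, ...]
    repeated_flags: tuple[bool, ...]
    treatment_levels: tuple[str, ...] | None = None  # first level is the reference
    include_mesocosm: bool = True
    include_individual: bool = True
    fixed_resid_var: float = FIXED_RESIDUAL_SD**2
    priors: PriorSet = field(default_factory=PriorSet)

    def __post_init__(self):
        if len(self.trait_names) != len(self.repeated_flags):
            raise ConfigError("trait_names and repeated_flags lengths differ")
        if self.fixed_resid_var <= 0:
            raise ConfigError("fixed_resid_var must be > 0")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def behaviours(self) -> tuple[str, ...]:
        return tuple(t for t, f in zip(self.trait_names, self.repeated_flags) if f)

    def with_priors(self, priors: PriorSet) -> "ModelSpec":
        return replace(self, priors=priors)


class ModelData:
    """Compiled design arrays and index maps for one dataset.

    Rows are canonicalized (sorted by individual, trait, occasion) before
    compilation, so posterior results are invariant to input row order.
    """

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        self.spec = spec
        required = {"individual_id", "mesocosm_id", "treatment", "trait", "occasion", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"long table is missing columns: {sorted(missing)}")

        trait_order = {t: i for i, t in enumerate(spec.trait_names)}
        unknown = set(table["trait"]) - set(spec.trait_names)
        if unknown:
            rows = table.index[table["trait"].isin(unknown)][:5].tolist()
            raise ValidationError(f"unknown traits {sorted(unknown)} (rows {rows})")

        df = table.copy()
        df["_trait_idx"] = df["trait"].map(trait_order)
        df = df.sort_values(
            ["individual_id", "_trait_idx", "occasion"], kind="mergesort"
        ).reset_index(drop=True)

        # individuals and their grouping
        ind_ids = pd.unique(df["individual_id"])
        ind_index = {v: i for i, v in enumerate(ind_ids)}
        per_ind = df.drop_duplicates("individual_id")[
            ["individual_id", "treatment", "mesocosm_id"]
        ]
        amb = (
            df.groupby("individual_id")[["treatment", "mesocosm_id"]]
            .nunique()
            .pipe(lambda g: g[(g > 1).any(axis=1)])
        )
        if len(amb):
            raise ValidationError(
                f"individuals assigned to multiple treatments/mesocosms: {amb.index.tolist()}"
            )

        if spec.treatment_levels is not None:
            levels = tuple(spec.treatment_levels)
            extra = set(per_ind["treatment"]) - set(levels)
            if extra:
                raise ValidationError(f"treatments not in spec levels: {sorted(extra)}")
        else:
            present = list(pd.unique(per_ind["treatment"]))
            if "control" in present:
                levels = ("control",) + tuple(sorted(t for t in present if t != "control"))
            else:
                levels = tuple(sorted(present))
        if levels[0] not in set(per_ind["treatment"]):
            raise ValidationError(f"reference treatment {levels[0]!r} absent from data")
        treat_index = {v: i for i, v in enumerate(levels)}

        meso_ids = tuple(sorted(pd.unique(df["mesocosm_id"])))
        meso_index = {v: i for i, v in enumerate(meso_ids)}

        # occasion structure validation
        occ_counts = df.groupby(["individual_id", "trait"])["occasion"].agg(["count", "nunique"])
        dup = occ_counts[occ_counts["count"] != occ_counts["nunique"]]
        if len(dup):
            raise ValidationError(f"duplicate (individual, trait, occasion) rows: {dup.index.tolist()[:5]}")
        repeated = dict(zip(spec.trait_names, spec.repeated_flags))
        bad = [
            key
            for key, row in occ_counts.iterrows()
            if not repeated[key[1]] and row["count"] > 1
        ]
        if bad:
            raise ValidationError(
                "repeated measures supplied for fixed-residual (once-measured) "
                f"traits: {bad[:5]}"
            )

        vals = pd.to_numeric(df["value"], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()][:5].tolist()
            raise ValidationError(f"non-numeric trait values at rows {rows}")

        self.table = df[["individual_id", "mesocosm_id", "treatment", "trait", "occasion", "value"]]
        self.y = vals.to_numpy(dtype=float)
        self.n_obs = len(df)
        self.trait_obs = df["_trait_idx"].to_numpy(dtype=np.int64)
        self.ind_obs = df["individual_id"].map(ind_index).to_numpy(dtype=np.int64)
        occ = df["occasion"].to_numpy(dtype=float)
        self.trial_obs = occ - occ.min()  # left-centred trial covariate

        self.individual_ids = tuple(ind_ids)
        self.n_ind = len(ind_ids)
        self.treatment_levels = levels
        self.n_treat = len(levels)
        self.mesocosm_ids = meso_ids
        self.n_meso = len(meso_ids)
        self.ind_treat = per_ind["treatment"].map(treat_index).to_numpy(dtype=np.int64)
        self.ind_meso = per_ind["mesocosm_id"].map(meso_index).to_numpy(dtype=np.int64)
        self.treat_obs = self.ind_treat[self.ind_obs]
        self.meso_obs = self.ind_meso[self.ind_obs]

        k = spec.n_traits
        self.n_traits = k
        rep = np.asarray(spec.repeated_flags, dtype=bool)
        self.repeated = rep
        self.n_beh = int(rep.sum())
        beh_of_trait = np.full(k, -1, dtype=np.int64)
        beh_of_trait[np.flatnonzero(rep)] = np.arange(self.n_beh)
        self.beh_of_trait = beh_of_trait
        self.beh_obs = beh_of_trait[self.trait_obs]  # -1 => fixed residual

        # per-(individual, trait) observation counts, for the u-update
        counts = np.zeros((self.n_ind, k), dtype=np.int64)
        np.add.at(counts, (self.ind_obs, self.trait_obs), 1)
        self.obs_counts = counts

        # batching key for the u-update: individuals sharing a treatment and
        # a missingness pattern share a conditional precision matrix
        pattern_keys = [
            (self.ind_treat[i],) + tuple(counts[i]) for i in range(self.n_ind)
        ]
        groups: dict[tuple, list[int]] = {}
        for i, key in enumerate(pattern_keys):
            groups.setdefault(key, []).append(i)
        self.u_groups = [
            (key[0], np.asarray(key[1:], dtype=float), np.asarray(members))
            for key, members in sorted(groups.items())
        ]

        # per-trait fixed-effect designs: intercept, treatment dummies, trial
        self.trait_slices = []
        self.X_by_trait = []
        order = np.argsort(self.trait_obs, kind="stable")
        self._trait_sorted = order
        for ki in range(k):
            idx = np.flatnonzero(self.trait_obs == ki)
            cols = [np.ones(idx.size)]
            for g in range(1, self.n_treat):
                cols.append((self.treat_obs[idx] == g).astype(float))
            if rep[ki]:
                cols.append(self.trial_obs[idx])
            self.trait_slices.append(idx)
            self.X_by_trait.append(np.column_stack(cols) if idx.size else np.zeros((0, len(cols))))

        self.data_hash = hashlib.sha256(
            self.table.to_csv(index=False, float_format="%.12g").encode()
        ).hexdigest()

    # ---- parameter bookkeeping -------------------------------------------

    def init_state(self) -> dict:
        """All-zeros / prior-scale starting state for one chain."""
        k, t, nb = self.n_traits, self.n_treat, self.n_beh
        return {
            "mu": np.zeros(k),
            "beta": np.zeros((t - 1, k)),
            "gamma": np.zeros(nb),
            "meso": np.zeros((self.n_meso, k)),
            "sigma2_meso": np.full(k, 0.25),
            "u": np.zeros((self.n_ind, k)),
            "Sigma_B": np.broadcast_to(np.eye(k) * 0.5, (t, k, k)).copy(),
            "sigma2_W": np.full((t, nb), 0.5),
        }

    def resid_var_obs(self, state: dict) -> np.ndarray:
        """Per-observation residual variance under the current state."""
        var = np.full(self.n_obs, self.spec.fixed_resid_var)
        beh = self.beh_obs >= 0
        if beh.any():
            var[beh] = state["sigma2_W"][self.treat_obs[beh], self.beh_obs[beh]]
        return var

    def mean_obs(self, state: dict) -> np.ndarray:
        """Per-observation conditional mean under the current state."""
        k = self.n_traits
        beta_p = np.vstack([np.zeros(k), state["beta"]])
        gamma_full = np.zeros(k)
        gamma_full[np.flatnonzero(self.repeated)] = state["gamma"]
        mean = (
            state["mu"][self.trait_obs]
            + beta_p[self.treat_obs, self.trait_obs]
            + gamma_full[self.trait_obs] * self.trial_obs
        )
        if self.spec.include_mesocosm:
            mean = mean + state["meso"][self.meso_obs, self.trait_obs]
        if self.spec.include_individual:
            mean = mean + state["u"][self.ind_obs, self.trait_obs]
        return mean


def build_model(spec: ModelSpec, table: pd.DataFrame) -> ModelData:
    """Validate a long table against the model spec and compile design arrays."""
    return ModelData(spec, table)


def log_density(state: dict, model: ModelData, include_prior: bool = True) -> float:
    """Joint log posterior density (up to additive constants shared by states).

    Gaussian observation terms + Gaussian random-effect terms + prior
    terms.  Non-positive-definite covariance values return -inf rather
    than raising, so samplers can reject them.
    """
    spec = model.spec
    pri = spec.priors
    var = model.resid_var_obs(state)
    if (var <= 0).any():
        return -np.inf
    resid = model.y - model.mean_obs(state)
    lp = float(-0.5 * np.sum(np.log(2 * np.pi * var) + resid**2 / var))

    if spec.include_mesocosm:
        s2 = state["sigma2_meso"]
        if (s2 <= 0).any():
            return -np.inf
        lp += float(
            np.sum(stats.norm.logpdf(state["meso"], scale=np.sqrt(s2)[None, :]))
        )
    if spec.include_individual:
        for g in range(model.n_treat):
            members = np.flatnonzero(model.ind_treat == g)
            sig = state["Sigma_B"][g]
            sign, logdet = np.linalg.slogdet(sig)
            if sign <= 0:
                return -np.inf
            u = state["u"][members]
            sol = np.linalg.solve(sig, u.T)
            quad = float(np.sum(u.T * sol))
            lp += -0.5 * (
                members.size * (model.n_traits * np.log(2 * np.pi) + logdet) + quad
            )

    if not include_prior:
        return lp

    # priors
    for arr in (state["mu"], state["beta"], state["gamma"]):
        lp += float(np.sum(stats.norm.logpdf(arr, scale=pri.fixed_scale)))
    ig = stats.invgamma(pri.var_shape, scale=pri.var_rate)
    if spec.include_mesocosm:
        lp += float(np.sum(ig.logpdf(state["sigma2_meso"])))
    if model.n_beh:
        lp += float(np.sum(ig.logpdf(state["sigma2_W"])))
    if spec.include_individual:
        k = model.n_traits
        df = k + pri.wishart_df_margin
        scale = np.eye(k) * pri.wishart_scale_diag
        for g in range(model.n_treat):
            sig = state["Sigma_B"][g]
            if np.linalg.slogdet(sig)[0] <= 0:
                return -np.inf
            lp += float(stats.invwishart.logpdf(sig, df=df, scale=scale))
    return lp
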