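"""Independent brute-force oracles used by the model and acceptance tests.

Everything here is coded from first principles (explicit loops, scipy
densities) and never calls the implementation paths it checks."""

import numpy as np
import pandas as pd
from scipy import stats

from covary.model import ModelSpec, build_model

def brute_force_log_density(state, model, include_prior=True):
    """Term-by-term log posterior, coded independently of the model module:
    explicit loops over observations, mesocosm effects, individual effect
    vectors and priors, using scipy densities throughout."""
    spec = model.spec
    pri = spec.priors
    k = model.n_traits
    lp = 0.0
    beta_p = np.vstack([np.zeros(k), state["beta"]])
    gamma_full = np.zeros(k)
    gamma_full[np.flatnonzero(model.repeated)] = state["gamma"]
    for o in range(model.n_obs):
        ki = model.trait_obs[o]
        ti = model.treat_obs[o]
        mean = state["mu"][ki] + beta_p[ti, ki] + gamma_full[ki] * model.trial_obs[o]
        if spec.include_mesocosm:
            mean += state["meso"][model.meso_obs[o], ki]
        if spec.include_individual:
            mean += state["u"][model.ind_obs[o], ki]
        bi = model.beh_of_trait[ki]
        var = state["sigma2_W"][ti, bi] if bi >= 0 else spec.fixed_resid_var
        lp += stats.norm.logpdf(model.y[o], loc=mean, scale=np.sqrt(var))
    if spec.include_mesocosm:
        for m in range(model.n_meso):
            for ki in range(k):
                lp += stats.norm.logpdf(
                    state["meso"][m, ki], scale=np.sqrt(state["sigma2_meso"][ki])
                )
    if spec.include_individual:
        for i in range(model.n_ind):
            lp += stats.multivariate_normal.logpdf(
                state["u"][i], mean=np.zeros(k), cov=state["Sigma_B"][model.ind_treat[i]]
            )
    if include_prior:
        for arr in (state["mu"], state["beta"], state["gamma"]):
            for v in np.ravel(arr):
                lp += stats.norm.logpdf(v, scale=pri.fixed_scale)
        ig = stats.invgamma(pri.var_shape, scale=pri.var_rate)
        if spec.include_mesocosm:
            lp += sum(ig.logpdf(v) for v in state["sigma2_meso"])
        if model.n_beh:
            lp += sum(ig.logpdf(v) for v in np.ravel(state["sigma2_W"]))
        if spec.include_individual:
            for g in range(model.n_treat):
                lp += stats.invwishart.logpdf(
                    state["Sigma_B"][g],
                    df=k + pri.wishart_df_margin,
                    scale=np.eye(k) * pri.wishart_scale_diag,
                )
    return lp


def random_tiny_instance(rng, n_ind=3, n_traits=2):
    """A random small dataset + random valid parameter state."""
    traits = ("activity", "sperm_count")[:n_traits]
    repeated = (True, False)[:n_traits]
    rows = []
    for i in range(n_ind):
        treat = ("control", "low")[i % 2]
        meso = f"{treat}_m1"
        for ki, trait in enumerate(traits):
            n_occ = 3 if repeated[ki] else 1
            for o in range(1, n_occ + 1):
                rows.append(
                    {
                        "individual_id": f"i{i}",
                        "mesocosm_id": meso,
                        "treatment": treat,
                        "trait": trait,
                        "occasion": o,
                        "value": rng.standard_normal(),
                    }
                )
    table = pd.DataFrame(rows)
    spec = ModelSpec(trait_names=traits, repeated_flags=repeated)
    model = build_model(spec, table)
    k, t, nb = model.n_traits, model.n_treat, model.n_beh
    a = rng.standard_normal((t, k, k)) * 0.5
    sigma_b = a @ a.transpose(0, 2, 1) + np.eye(k)[None] * 0.2
    state = {
        "mu": rng.standard_normal(k),
        "beta": rng.standard_normal((t - 1, k)),
        "gamma": rng.standard_normal(nb),
        "meso": rng.standard_normal((model.n_meso, k)) * 0.3,
        "sigma2_meso": rng.uniform(0.05, 1.0, k),
        "u": rng.standard_normal((model.n_ind, k)),
        "Sigma_B": sigma_b,
        "sigma2_W": rng.uniform(0.1, 1.0, (t, nb)),
    }
    return model, state


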