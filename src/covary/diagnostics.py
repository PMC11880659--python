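"""MCMC convergence diagnostics: split-Rhat and bulk effective sample size.

Split potential-scale-reduction is implemented in-repo (it is the
statistic the inference rule depends on); bulk ESS is delegated to arviz.
A fit is flagged when any split-Rhat exceeds 1.01 or any bulk ESS falls
below 400.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateDataError
from .sampler import ESS_THRESHOLD, RHAT_THRESHOLD, PosteriorDraws


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in
    half, then the classic between/within variance ratio is computed over
    the 2*n_chains half-chains.  Values are >= 1 up to floating error.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DegenerateDataError("split-Rhat requires >= 2 chains of draws")
    if arr.shape[1] < 10:
        raise DegenerateDataError("split-Rhat requires >= 10 draws per chain")
    n = arr.shape[1] // 2
    halves = np.concatenate([arr[:, :n], arr[:, arr.shape[1] - n :]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def rhat(draws: PosteriorDraws, parameter: str) -> float:
    """Split-Rhat for one named scalar parameter (e.g. ``"mu[0]"``)."""
    chains = draws.scalar_chains()
    if parameter not in chains:
        raise KeyError(
            f"unknown parameter {parameter!r}; available: {sorted(chains)[:8]}..."
        )
    return split_rhat(chains[parameter])


def bulk_ess(chains: np.ndarray) -> float:
    """Bulk effective sample size via arviz."""
    import arviz as az

    return float(az.ess(np.asarray(chains, dtype=float)))


def convergence_report(draws: PosteriorDraws) -> dict:
    """Max split-Rhat and min bulk ESS over all free scalar parameters.

    Parameters that never move (e.g. a random-effect block excluded from
    the model) are skipped.  With a single chain Rhat is unavailable and
    only the ESS criterion applies.
    """
    import arviz as az

    chains = draws.scalar_chains()
    live = {
        name: arr
        for name, arr in chains.items()
        if np.ptp(arr) > 0  # constant => structurally fixed, not sampled
    }
    max_rhat = None
    if draws.n_chains >= 2 and live:
        max_rhat = max(split_rhat(arr) for arr in live.values())
    min_ess = None
    if live:
        ds = az.convert_to_dataset({k.replace("[", "_").replace("]", ""): v for k, v in live.items()})
        ess = az.ess(ds, method="bulk")
        min_ess = float(min(ess[v].values.min() for v in ess.data_vars))
    converged = True
    if max_rhat is not None and max_rhat > RHAT_THRESHOLD:
        converged = False
    if min_ess is not None and min_ess < ESS_THRESHOLD:
        converged = False
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "converged": converged,
        "n_parameters_checked": len(live),
    }
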