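"""Monte-Carlo simulation of the full generative process.

Drifts are drawn from the prior, endpoints from the exact endpoint law
``x_i ~ Normal(mu_i t_i, sigma^2 t_i)`` — the endpoint is the sufficient
statistic of the diffusion, so no path discretization enters the estimates.
These simulations are the independent oracle against which every quadrature
and closed form in the package is cross-checked. A Euler-Maruyama path
simulator is included only for illustration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .priors import NoiseModel, PriorSpec, posterior_mean, sample_drifts
from .utility import Allocation, UtilityEstimate

__all__ = ["TrialBatch", "MonteCarloUtility", "simulate_batch",
           "mc_expected_utility", "simulate_paths", "batch_to_frame"]


@dataclass(frozen=True)
class TrialBatch:
    """Seeded batch of simulated trials.

    ``drifts`` and ``endpoints`` are (n_trials, n_options); endpoints of
    unsampled options (t_i = 0) are NaN.
    """

    drifts: np.ndarray
    endpoints: np.ndarray
    allocation: Allocation
    seed: int

    @property
    def n_trials(self) -> int:
        return self.drifts.shape[0]


@dataclass(frozen=True)
class MonteCarloUtility:
    """MC expected utility: chosen posterior mean, and the realized true drift."""

    estimate: UtilityEstimate
    realized: UtilityEstimate
    n_trials: int
    seed: int


def simulate_batch(prior: PriorSpec, alloc: Allocation, noise: NoiseModel,
                   n_trials: int, seed: int) -> TrialBatch:
    """Sample drifts from the prior and endpoints from their exact law."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    t = alloc.times
    d = t.size
    mu = sample_drifts(prior, (n_trials, d), rng)
    x = np.full((n_trials, d), np.nan)
    pos = t > 0
    x[:, pos] = mu[:, pos] * t[pos] + noise.sigma * np.sqrt(t[pos]) * \
        rng.standard_normal((n_trials, int(pos.sum())))
    return TrialBatch(mu, x, alloc, seed)


def _batch_posterior_means(prior: PriorSpec, batch: TrialBatch, noise: NoiseModel) -> np.ndarray:
    """Posterior-mean estimates per trial and option; -inf for unsampled options."""
    t = batch.allocation.times
    mh = np.full_like(batch.endpoints, -np.inf)
    for i, ti in enumerate(t):
        if ti > 0:
            mh[:, i] = posterior_mean(prior, batch.endpoints[:, i], ti, noise)
    return mh


def mc_expected_utility(prior: PriorSpec, alloc: Allocation, noise: NoiseModel,
                        n_trials: int = 100_000, seed: int = 0) -> MonteCarloUtility:
    """Monte-Carlo E[max_i muhat_i] and the realized drift of the chosen option.

    By the tower property both quantities have the same expectation; the
    realized estimate is noisier.
    """
    batch = simulate_batch(prior, alloc, noise, n_trials, seed)
    mh = _batch_posterior_means(prior, batch, noise)
    chosen = np.argmax(mh, axis=1)
    idx = np.arange(n_trials)
    u = mh[idx, chosen]
    r = batch.drifts[idx, chosen]
    return MonteCarloUtility(
        UtilityEstimate(float(u.mean()), float(u.std(ddof=1) / np.sqrt(n_trials)), "monte_carlo"),
        UtilityEstimate(float(r.mean()), float(r.std(ddof=1) / np.sqrt(n_trials)), "monte_carlo"),
        n_trials, seed)


def simulate_paths(prior: PriorSpec, alloc: Allocation, noise: NoiseModel,
                   n_steps: int = 1000, seed: int = 0) -> dict[int, np.ndarray]:
    """Euler discretization of the diffusion paths (illustration only)."""
    rng = np.random.default_rng(seed)
    out = {}
    for i, ti in enumerate(alloc.times):
        if ti <= 0:
            continue
        mu = float(sample_drifts(prior, (), rng))
        dt = ti / n_steps
        inc = mu * dt + noise.sigma * np.sqrt(dt) * rng.standard_normal(n_steps)
        out[i] = np.concatenate([[0.0], np.cumsum(inc)])
    return out


def batch_to_frame(prior: PriorSpec, batch: TrialBatch, noise: NoiseModel) -> pd.DataFrame:
    """Long-format view of a batch: one row per (trial, sampled option)."""
    mh = _batch_posterior_means(prior, batch, noise)
    chosen = np.argmax(mh, axis=1)
    t = batch.allocation.times
    rows = []
    for i, ti in enumerate(t):
        if ti <= 0:
            continue
        rows.append(pd.DataFrame({
            "trial": np.arange(batch.n_trials),
            "option": i,
            "t": ti,
            "mu": batch.drifts[:, i],
            "x": batch.endpoints[:, i],
            "mu_hat": mh[:, i],
            "chosen": chosen == i,
        }))
    return pd.concat(rows, ignore_index=True).sort_values(["trial", "option"]).reset_index(drop=True)
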