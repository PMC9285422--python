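"""Expected utility of even and uneven capacity allocations.

The agent divides a total sampling time ``T`` over ``M`` accumulators, observes
their endpoints, and picks the option with the highest posterior-mean drift.
The value of an allocation is the expected posterior mean of the chosen option.

The dimensionless capacity ``C = sigma0^2 T / sigma^2`` measures the precision
of the whole sampling budget relative to the precision of the prior; every
result depends on ``(T, sigma, sigma0)`` only through the per-option capacities
``c_i = sigma0^2 t_i / sigma^2``. Dividing time at fixed noise and dividing
precision at fixed time are therefore equivalent (the time-precision duality).

For an even allocation over M options the expected utility reduces to a single
integral over the maximum endpoint; with a Gaussian prior it has the closed
form ``U = mu0 + sigma0 / sqrt(1 + M/C) * E[max of M standard normals]``.
For uneven allocations the maximum is taken over posterior means whose
distributions differ across options, and the integral runs over the estimate
variable with per-option CDFs composed with inverse estimate maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import log_ndtr

from .priors import (
    NoiseModel,
    PriorSpec,
    _phi,
    evidence_log_cdf,
    evidence_marginal_mean_var,
    evidence_marginal_pdf,
    posterior_mean,
)

__all__ = [
    "CapacityParams",
    "Allocation",
    "PrecisionAllocation",
    "UtilityEstimate",
    "capacity",
    "per_option_capacity",
    "duality_convert",
    "duality_invert",
    "expected_max_std_normal",
    "expected_utility_even",
    "expected_utility_uneven",
    "expected_utility_with_default",
    "pmax_pdf",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapacityParams:
    """Sampling budget ``T``, diffusion noise ``sigma``, prior SD ``sigma0``."""

    T: float
    sigma: float = 1.0
    sigma0: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be nonnegative")
        if not self.sigma > 0 or not self.sigma0 > 0:
            raise ValueError("sigma and sigma0 must be positive")

    @property
    def capacity(self) -> float:
        return self.sigma0**2 * self.T / self.sigma**2

    @staticmethod
    def from_capacity(C: float, sigma: float = 1.0, sigma0: float = 1.0) -> "CapacityParams":
        """Budget T implied by a target capacity: T = C sigma^2 / sigma0^2."""
        if C < 0:
            raise ValueError("C must be nonnegative")
        return CapacityParams(C * sigma**2 / sigma0**2, sigma, sigma0)

    @staticmethod
    def for_prior(prior: PriorSpec, *, T: float | None = None, C: float | None = None,
                  sigma: float = 1.0) -> "CapacityParams":
        """Capacity parameters whose sigma0 is the prior's actual overall SD."""
        if (T is None) == (C is None):
            raise ValueError("give exactly one of T or C")
        if T is None:
            return CapacityParams.from_capacity(C, sigma, prior.sd)
        return CapacityParams(T, sigma, prior.sd)


def capacity(params: CapacityParams) -> float:
    """Total dimensionless capacity C = sigma0^2 T / sigma^2."""
    return params.capacity


def per_option_capacity(t_i, sigma: float, sigma0: float):
    """Capacity allocated to one option: c_i = sigma0^2 t_i / sigma^2."""
    return sigma0**2 * np.asarray(t_i, dtype=float) / sigma**2


@dataclass(frozen=True)
class Allocation:
    """Nonnegative sampling times summing to the budget T."""

    times: np.ndarray
    T: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a nonempty 1-D vector")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        total = float(t.sum())
        if self.T is None:
            object.__setattr__(self, "T", total)
        elif abs(total - self.T) > 1e-12 * max(abs(self.T), 1.0):
            raise ValueError(f"times sum to {total}, not the stated budget {self.T}")
        if self.active_count < 1:
            raise ValueError("allocation must have at least one active option")

    @property
    def active_count(self) -> int:
        return int(np.count_nonzero(self.times > 0))

    @property
    def active_times(self) -> np.ndarray:
        return self.times[self.times > 0]

    @staticmethod
    def even(M: int, T: float, dims: int | None = None) -> "Allocation":
        """T/M to each of the first M options, zero to the rest."""
        if M < 1:
            raise ValueError("M must be >= 1")
        d = dims if dims is not None else M
        t = np.zeros(d)
        t[:M] = T / M
        return Allocation(t, T)


@dataclass(frozen=True)
class PrecisionAllocation:
    """Dual view: per-option precisions 1/sigma_i^2 under a common sampling time."""

    precisions: np.ndarray
    common_time: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "precisions", np.asarray(self.precisions, dtype=float))


def duality_convert(alloc: Allocation, sigma: float) -> PrecisionAllocation:
    """Time allocation at fixed noise -> precision allocation at fixed time.

    Preserves each option's capacity: with common time T, precision_i =
    t_i / (sigma^2 T), so sigma0^2 T * precision_i = sigma0^2 t_i / sigma^2.
    """
    T = alloc.T
    if not T > 0:
        raise ValueError("duality conversion needs a positive budget")
    return PrecisionAllocation(alloc.times / (sigma**2 * T), T)


def duality_invert(prec: PrecisionAllocation, sigma: float) -> Allocation:
    """Inverse of :func:`duality_convert` (exact round trip)."""
    return Allocation(prec.precisions * sigma**2 * prec.common_time, None)


@dataclass(frozen=True)
class UtilityEstimate:
    """Expected utility with provenance: method tag and MC standard error."""

    value: float
    stderr: float = 0.0
    method: str = "quadrature"

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be nonnegative")


# ---------------------------------------------------------------------------
# Quadrature backbone
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _gl_grid(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = _leggauss(n)
    return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * w


def _z_range(M: int) -> tuple[float, float]:
    # upper edge widened with M: the maximum endpoint drifts into the tail
    return -9.0, 8.0 + np.sqrt(2.0 * np.log(max(M, 2)))


def expected_max_std_normal(M: int, n: int = 800) -> float:
    """E[max of M iid standard normals] = M int y phi(y) Phi(y)^(M-1) dy."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if M == 1:
        return 0.0
    lo, hi = _z_range(M)
    y, w = _gl_grid(lo, hi, n)
    f = M * y * _phi(y) * np.exp((M - 1) * log_ndtr(y))
    return float(f @ w)


def pmax_pdf(prior: PriorSpec, M: int, t: float, noise: NoiseModel, y) -> np.ndarray:
    """Density of the maximum endpoint among M evenly sampled accumulators."""
    if M < 1:
        raise ValueError("M must be >= 1")
    y = np.asarray(y, dtype=float)
    logF = evidence_log_cdf(prior, y, t, noise)
    p = evidence_marginal_pdf(prior, y, t, noise)
    return M * np.exp((M - 1) * logF) * p


def _even_quadrature(prior: PriorSpec, M: int, t: float, noise: NoiseModel,
                     n: int = 600, transform=None) -> float:
    """M int F^(M-1) p muhat dy over a standardized grid."""
    mean, var = evidence_marginal_mean_var(prior, t, noise)
    sd = np.sqrt(var)
    zlo, zhi = _z_range(M)
    y, w = _gl_grid(mean + zlo * sd, mean + zhi * sd, n)
    muhat = posterior_mean(prior, y, t, noise)
    if transform is not None:
        muhat = transform(muhat)
    return float((pmax_pdf(prior, M, t, noise, y) * muhat) @ w)


def expected_utility_even(prior: PriorSpec, M: int, params: CapacityParams,
                          noise: NoiseModel | None = None) -> UtilityEstimate:
    """Expected utility of giving T/M time to each of M options.

    Gaussian prior: closed form through E[max of M standard normals].
    Other families: one-dimensional quadrature over the maximum endpoint.
    M = 1 and C = 0 are exact special cases equal to the prior mean.
    """
    if not isinstance(M, (int, np.integer)) or M < 1:
        raise ValueError("M must be an integer >= 1")
    noise = noise or NoiseModel(params.sigma)
    C = prior.variance * params.T / noise.sigma**2
    if M == 1 or C == 0.0:
        return UtilityEstimate(prior.mu0, 0.0, "closed_form")
    if prior.family == "gaussian":
        val = prior.mu0 + prior.sigma0 / np.sqrt(1.0 + M / C) * expected_max_std_normal(M)
        return UtilityEstimate(float(val), 0.0, "closed_form")
    val = _even_quadrature(prior, M, params.T / M, noise)
    return UtilityEstimate(val, 0.0, "quadrature")


def expected_utility_with_default(prior: PriorSpec, M: int, params: CapacityParams,
                                  noise: NoiseModel | None = None) -> UtilityEstimate:
    """Even-allocation utility when an unsampled fallback worth mu0 is choosable.

    The agent picks ``max(mu0, max_i muhat_i)``; always at least the
    no-default utility. ``M = 0`` means taking the fallback outright.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    noise = noise or NoiseModel(params.sigma)
    C = prior.variance * params.T / noise.sigma**2
    if M == 0 or C == 0.0:
        return UtilityEstimate(prior.mu0, 0.0, "closed_form")
    mu0 = prior.mu0
    val = _even_quadrature(prior, M, params.T / M, noise,
                           transform=lambda mh: np.maximum(mh, mu0))
    return UtilityEstimate(val, 0.0, "quadrature")


# ---------------------------------------------------------------------------
# Uneven allocations
# ---------------------------------------------------------------------------

def _estimate_inverse_tables(prior: PriorSpec, ts: np.ndarray, noise: NoiseModel,
                             zmax: float, n_table: int = 4001):
    """Per-option monotone tables x -> muhat(x, t_j), used to invert estimates."""
    tables = []
    for t in ts:
        mean, var = evidence_marginal_mean_var(prior, t, noise)
        sd = np.sqrt(var)
        xg = np.linspace(mean - zmax * sd, mean + zmax * sd, n_table)
        ug = posterior_mean(prior, xg, t, noise)
        tables.append((xg, ug))
    return tables


def expected_utility_uneven(prior: PriorSpec, alloc: Allocation,
                            noise: NoiseModel | None = None,
                            n: int = 800) -> UtilityEstimate:
    """Expected utility of an arbitrary allocation: E[max_i muhat_i].

    Evaluated as a product-rule sum over the active options,
    ``sum_i int p(x|t_i) prod_{j != i} P(muhat_j <= muhat_i(x)) muhat_i(x) dx``,
    where each factor is the endpoint CDF of option j composed with the inverse
    of its monotone estimate map. Reduces exactly to the even-allocation
    integral when all active times are equal. Zero-time options are unsampled
    and cannot be chosen.
    """
    noise = noise or NoiseModel()
    ts = alloc.active_times
    M = ts.size
    if M == 0:
        raise ValueError("allocation must have at least one active option")
    if M == 1:
        return UtilityEstimate(prior.mu0, 0.0, "closed_form")
    zlo, zhi = _z_range(M)
    gaussian = prior.family == "gaussian"
    tables = None if gaussian else _estimate_inverse_tables(prior, ts, noise, zmax=-zlo + 6.0)
    total = 0.0
    for i, ti in enumerate(ts):
        mean_i, var_i = evidence_marginal_mean_var(prior, ti, noise)
        sd_i = np.sqrt(var_i)
        x, w = _gl_grid(mean_i + zlo * sd_i, mean_i + zhi * sd_i, n)
        u = posterior_mean(prior, x, ti, noise)
        log_prod = np.zeros_like(x)
        for j, tj in enumerate(ts):
            if j == i:
                continue
            if tj == ti:
                xj = x  # equal times share the estimate map: inverse is the identity
            elif gaussian:
                # muhat_j is linear in x: invert exactly
                xj = ((noise.sigma**2 + prior.sigma0**2 * tj) * u
                      - prior.mu0 * noise.sigma**2) / prior.sigma0**2
            else:
                xg, ug = tables[j]
                xj = np.interp(u, ug, xg)
            log_prod += evidence_log_cdf(prior, xj, tj, noise)
        f = evidence_marginal_pdf(prior, x, ti, noise) * np.exp(log_prod) * u
        total += float(f @ w)
    return UtilityEstimate(total, 0.0, "quadrature")
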