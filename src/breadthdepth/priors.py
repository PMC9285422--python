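"""Drift priors and Bayesian inference of a drift from one accumulator's endpoint.

An option's latent quality is its drift ``mu``. Evidence about it accumulates as
a drift-diffusion process ``dx = mu dt + sigma dW``; after sampling for time
``t`` only the endpoint ``x`` is observed, and ``(x, t)`` is sufficient for
``mu`` with Gaussian likelihood ``N(x | mu t, sigma^2 t)``. Three prior
families over drifts are supported: Gaussian, uniform, and an equal-weight
two-Gaussian mixture ("bimodal"). For each, this module provides the marginal
distribution of the endpoint and the posterior mean of the drift, in closed
form wherever conjugacy or truncated-normal algebra allows, with a brute-force
quadrature fallback used by the test suite as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, log_ndtr, logsumexp, ndtr

__all__ = [
    "PriorSpec",
    "NoiseModel",
    "EvidenceObservation",
    "posterior_mean",
    "evidence_marginal_pdf",
    "evidence_cdf",
    "evidence_log_cdf",
    "sample_drifts",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_SQRT3 = np.sqrt(3.0)


def _phi(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI


@dataclass(frozen=True)
class PriorSpec:
    """Prior over drifts.

    Parameters
    ----------
    family : {"gaussian", "uniform", "bimodal"}
    mu0 : float
        Overall prior mean (drift units).
    sigma0 : float
        Scale hyperparameter (drift units). For the Gaussian and uniform
        families this is the overall prior SD; for the bimodal family it is
        the per-mode SD default, and the overall variance is
        ``component_sd**2 + mode_separation**2 / 4``.
    mode_separation : float, optional
        Bimodal only: distance between the two component means (the modes sit
        at ``mu0 +- mode_separation/2``). Default ``2 * sigma0``.
    component_sd : float, optional
        Bimodal only: SD of each mixture component. Default ``sigma0``.
    """

    family: str
    mu0: float
    sigma0: float
    mode_separation: float | None = None
    component_sd: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform", "bimodal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be positive")
        if self.family == "bimodal":
            if self.mode_separation is None:
                object.__setattr__(self, "mode_separation", 2.0 * self.sigma0)
            if self.component_sd is None:
                object.__setattr__(self, "component_sd", self.sigma0)
            if not self.component_sd > 0 or not self.mode_separation >= 0:
                raise ValueError("bimodal shape parameters must be positive")

    # -- convenience constructors -------------------------------------------------
    @staticmethod
    def gaussian(mu0: float, sigma0: float) -> "PriorSpec":
        return PriorSpec("gaussian", mu0, sigma0)

    @staticmethod
    def uniform(mu0: float, sigma0: float) -> "PriorSpec":
        """Uniform on [mu0 - sqrt(3) sigma0, mu0 + sqrt(3) sigma0] (variance sigma0^2)."""
        return PriorSpec("uniform", mu0, sigma0)

    @staticmethod
    def uniform_on(lo: float, hi: float) -> "PriorSpec":
        if not hi > lo:
            raise ValueError("need hi > lo")
        return PriorSpec("uniform", 0.5 * (lo + hi), (hi - lo) / (2.0 * _SQRT3))

    @staticmethod
    def bimodal(
        mu0: float,
        sigma0: float,
        mode_separation: float | None = None,
        component_sd: float | None = None,
    ) -> "PriorSpec":
        return PriorSpec("bimodal", mu0, sigma0, mode_separation, component_sd)

    # -- moments and support ------------------------------------------------------
    @property
    def variance(self) -> float:
        """Actual overall variance of the prior (used to define capacity)."""
        if self.family == "bimodal":
            return self.component_sd**2 + 0.25 * self.mode_separation**2
        return self.sigma0**2

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            half = _SQRT3 * self.sigma0
            return (self.mu0 - half, self.mu0 + half)
        return (-np.inf, np.inf)

    @property
    def component_means(self) -> np.ndarray:
        """Means of the mixture components (bimodal only)."""
        if self.family != "bimodal":
            raise ValueError("component_means is defined for the bimodal family")
        half = 0.5 * self.mode_separation
        return np.array([self.mu0 - half, self.mu0 + half])

    def pdf(self, mu) -> np.ndarray:
        """Prior density over drifts."""
        mu = np.asarray(mu, dtype=float)
        if self.family == "gaussian":
            return _phi((mu - self.mu0) / self.sigma0) / self.sigma0
        if self.family == "uniform":
            lo, hi = self.support
            return np.where((mu >= lo) & (mu <= hi), 1.0 / (hi - lo), 0.0)
        s = self.component_sd
        return 0.5 * sum(_phi((mu - m) / s) / s for m in self.component_means)


@dataclass(frozen=True)
class NoiseModel:
    """Diffusion noise of the accumulators: SD ``sigma`` per sqrt(time)."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class EvidenceObservation:
    """Endpoint ``x`` of one accumulator after sampling time ``t > 0``."""

    x: float
    t: float

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError("t must be positive (t=0 means unsampled)")


def _check_t(t: float) -> None:
    if not t > 0:
        raise ValueError("t must be positive")


def _truncnorm_mean(a, b):
    """Mean of a standard normal truncated to [a, b], stable in far tails.

    Uses erfcx scaling so that both the numerator and denominator carry the
    same dominant exponential factor; reflection handles the lower tail.
    """
    a, b = np.broadcast_arrays(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    flip = (a + b) < 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    d = np.exp(-0.5 * (hi * hi - lo * lo))
    num = (1.0 - d) / _SQRT2PI
    den = 0.5 * (erfcx(lo / np.sqrt(2.0)) - d * erfcx(hi / np.sqrt(2.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = num / den
    # degenerate interval: mean -> midpoint
    m = np.where(den > 0, m, 0.5 * (lo + hi))
    return np.where(flip, -m, m)


def _log_int_phi(u):
    """log of int_{-inf}^{u} Phi(s) ds = log(u Phi(u) + phi(u)), stable for u << 0."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    low = u < -8.0
    ul = u[low]
    # asymptotic G(u) ~ phi(u)/u^2 (1 - 3/u^2 + ...)
    out[low] = -0.5 * ul * ul - np.log(_SQRT2PI) - 2.0 * np.log(-ul) + np.log1p(-3.0 / (ul * ul))
    uh = u[~low]
    out[~low] = np.log(uh * ndtr(uh) + _phi(uh))
    return out


# ---------------------------------------------------------------------------
# Marginal distribution of the endpoint  p(x | t) = int N(x | mu t, sigma^2 t) p(mu) dmu
# ---------------------------------------------------------------------------

def evidence_marginal_mean_var(prior: PriorSpec, t: float, noise: NoiseModel) -> tuple[float, float]:
    """Mean and variance of the endpoint marginal: (mu0 t, Var[prior] t^2 + sigma^2 t)."""
    _check_t(t)
    return prior.mu0 * t, prior.variance * t * t + noise.sigma**2 * t


def evidence_marginal_pdf(prior: PriorSpec, x, t: float, noise: NoiseModel) -> np.ndarray:
    """Density of the observed endpoint ``x`` after sampling time ``t``."""
    _check_t(t)
    x = np.asarray(x, dtype=float)
    sig = noise.sigma
    if prior.family == "gaussian":
        v = prior.sigma0**2 * t * t + sig**2 * t
        return _phi((x - prior.mu0 * t) / np.sqrt(v)) / np.sqrt(v)
    if prior.family == "uniform":
        lo, hi = prior.support
        sl = sig * np.sqrt(t)
        return (ndtr((x - lo * t) / sl) - ndtr((x - hi * t) / sl)) / ((hi - lo) * t)
    s = prior.component_sd
    v = s * s * t * t + sig**2 * t
    return 0.5 * sum(_phi((x - m * t) / np.sqrt(v)) / np.sqrt(v) for m in prior.component_means)


def evidence_log_cdf(prior: PriorSpec, y, t: float, noise: NoiseModel) -> np.ndarray:
    """log F_x(y | t), stable deep into the lower tail.

    A stable log-CDF is what makes ``F^(M-1) = exp((M-1) log F)`` usable for
    M up to 1e4 and beyond.
    """
    _check_t(t)
    y = np.asarray(y, dtype=float)
    sig = noise.sigma
    if prior.family == "gaussian":
        v = prior.sigma0**2 * t * t + sig**2 * t
        return log_ndtr((y - prior.mu0 * t) / np.sqrt(v))
    if prior.family == "uniform":
        lo, hi = prior.support
        sl = sig * np.sqrt(t)
        al = (y - lo * t) / sl
        be = (y - hi * t) / sl
        lga = _log_int_phi(al)
        lgb = _log_int_phi(be)
        pref = np.log(sl / ((hi - lo) * t))
        with np.errstate(invalid="ignore"):
            diff = np.log1p(-np.exp(np.minimum(lgb - lga, -1e-300)))
        return np.minimum(pref + lga + diff, 0.0)
    s = prior.component_sd
    v = s * s * t * t + sig**2 * t
    comps = np.stack([log_ndtr((y - m * t) / np.sqrt(v)) for m in prior.component_means])
    return logsumexp(comps, axis=0) + np.log(0.5)


def evidence_cdf(prior: PriorSpec, y, t: float, noise: NoiseModel) -> np.ndarray:
    """Cumulative distribution F_x(y | t) of the endpoint of one accumulator."""
    return np.exp(evidence_log_cdf(prior, y, t, noise))


# ---------------------------------------------------------------------------
# Posterior mean of the drift
# ---------------------------------------------------------------------------

def posterior_mean(prior: PriorSpec, obs, t: float | None = None, noise: NoiseModel | None = None):
    """E[mu | x, t]: Bayesian point estimate of an option's drift.

    Accepts either ``posterior_mean(prior, EvidenceObservation(x, t), noise=...)``
    or the vectorized form ``posterior_mean(prior, x, t, noise)`` with ``x``
    array-like. Monotone increasing in ``x`` for every family.
    """
    if isinstance(obs, EvidenceObservation):
        x, t = obs.x, obs.t
        scalar = True
    else:
        if t is None:
            raise TypeError("posterior_mean(prior, x, t, noise): t is required")
        x, scalar = obs, np.isscalar(obs)
    noise = noise or NoiseModel()
    _check_t(t)
    x = np.asarray(x, dtype=float)
    sig = noise.sigma
    if prior.family == "gaussian":
        out = (prior.mu0 / prior.sigma0**2 + x / sig**2) / (1.0 / prior.sigma0**2 + t / sig**2)
    elif prior.family == "uniform":
        # posterior = N(x/t, sigma^2/t) truncated to the prior support
        lo, hi = prior.support
        m = x / t
        s = sig / np.sqrt(t)
        out = m + s * _truncnorm_mean((lo - m) / s, (hi - m) / s)
    else:
        # mixture posterior: responsibilities from component marginals,
        # conjugate-normal mean within each component
        s0 = prior.component_sd
        v = s0 * s0 * t * t + sig**2 * t
        means = prior.component_means
        logw = np.stack([-0.5 * (x - m * t) ** 2 / v for m in means])
        w = np.exp(logw - logsumexp(logw, axis=0))
        comp_mean = np.stack(
            [(m / s0**2 + x / sig**2) / (1.0 / s0**2 + t / sig**2) for m in means]
        )
        out = (w * comp_mean).sum(axis=0)
    return float(out) if scalar else out


def posterior_mean_quadrature(
    prior: PriorSpec, x: float, t: float, noise: NoiseModel, n: int = 4001
) -> float:
    """Brute-force E[mu | x, t] on a dense trapezoid grid over the prior.

    Slow reference path; the closed forms above are checked against it.
    """
    _check_t(t)
    lo, hi = prior.support
    if not np.isfinite(lo):
        sd = prior.sd
        lo, hi = prior.mu0 - 10.0 * sd, prior.mu0 + 10.0 * sd
        xc = x / t
        lo, hi = min(lo, xc - 10.0 * noise.sigma / np.sqrt(t)), max(hi, xc + 10.0 * noise.sigma / np.sqrt(t))
    mu = np.linspace(lo, hi, n)
    loglik = -0.5 * (x - mu * t) ** 2 / (noise.sigma**2 * t)
    w = np.exp(loglik - loglik.max()) * prior.pdf(mu)
    z = np.trapezoid(w, mu)
    if not z > 0:
        raise ArithmeticError("quadrature underflow in posterior normalization")
    return float(np.trapezoid(mu * w, mu) / z)


def sample_drifts(prior: PriorSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Draw iid drifts from the prior."""
    if prior.family == "gaussian":
        return prior.mu0 + prior.sigma0 * rng.standard_normal(size)
    if prior.family == "uniform":
        lo, hi = prior.support
        return rng.uniform(lo, hi, size)
    comp = rng.integers(0, 2, size)
    return prior.component_means[comp] + prior.component_sd * rng.standard_normal(size)
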