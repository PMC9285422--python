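"""Search for the optimal breadth and for optimal (possibly uneven) allocations.

Three complementary views of the same optimization:

* :func:`optimal_m` — integer argmax of the even-allocation utility over M
  (dense at small M, geometric grid plus local refinement at large M).
* :func:`simplex_path_utilities` — a one-dimensional path through allocation
  space chaining the straight segments between successive even points
  ``tMe -> t(M+1)e``; every even point is a critical point by permutation
  symmetry, and the profile shows which one dominates.
* :func:`stochastic_gradient_ascent` — projected stochastic gradient ascent
  over a fixed-dimension simplex with a pathwise (reparametrized) Monte-Carlo
  gradient and common random numbers, tracking the coefficient of variation of
  the allocation vector (zero CV = even allocation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import NoiseModel, PriorSpec, posterior_mean, sample_drifts
from .utility import (
    Allocation,
    CapacityParams,
    UtilityEstimate,
    expected_utility_even,
    expected_utility_uneven,
)

__all__ = [
    "MStar",
    "PathProfile",
    "OptimTrace",
    "PowerLawFit",
    "optimal_m",
    "fit_power_law",
    "simplex_path_utilities",
    "project_to_simplex",
    "stochastic_gradient_ascent",
]


# ---------------------------------------------------------------------------
# Optimal breadth by scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MStar:
    """Integer optimal breadth with the scanned (M, utility) table."""

    m: int
    utility: UtilityEstimate
    scan: list[tuple[int, float]]
    bracket_warning: bool = False


def _candidate_grid(m_max: int, dense: int = 32, n_geom: int = 40) -> np.ndarray:
    ms = np.arange(1, min(dense, m_max) + 1)
    if m_max > dense:
        geom = np.unique(np.geomspace(dense, m_max, n_geom).astype(int))
        ms = np.unique(np.concatenate([ms, geom]))
    return ms


def optimal_m(prior: PriorSpec, params: CapacityParams, m_max: int = 64,
              noise: NoiseModel | None = None) -> MStar:
    """Argmax over M of the even-allocation expected utility.

    Scans M densely up to 32 and on a geometric grid beyond, then refines
    every integer in a +-35% window around the coarse argmax. Ties break to
    the smallest M. ``bracket_warning`` is set if the utility is still rising
    at ``m_max``.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")

    def u(M: int) -> float:
        return expected_utility_even(prior, int(M), params, noise).value

    ms = _candidate_grid(m_max)
    us = np.array([u(M) for M in ms])
    best = int(ms[int(np.argmax(us))])
    lo = max(1, int(best * 0.65))
    hi = min(m_max, int(np.ceil(best * 1.45)) + 1)
    refine = np.arange(lo, hi + 1)
    known = dict(zip(ms.tolist(), us.tolist()))
    scan = {int(M): known.get(int(M), None) for M in np.union1d(ms, refine)}
    for M in refine:
        if scan[int(M)] is None:
            scan[int(M)] = u(M)
    items = sorted((M, v) for M, v in scan.items() if v is not None)
    values = np.array([v for _, v in items])
    m_best = items[int(np.argmax(values))][0]  # argmax takes first -> smallest M on ties
    warn = m_best >= m_max and u(m_max) > u(m_max - 1)
    return MStar(m_best, UtilityEstimate(float(values.max()), 0.0, "quadrature"),
                 items, warn)


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    prefactor: float


def fit_power_law(capacities, m_stars) -> PowerLawFit:
    """OLS fit of log M* = a log C + b; returns (a, e^b)."""
    C = np.asarray(capacities, dtype=float)
    M = np.asarray(m_stars, dtype=float)
    if C.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(C <= 0) or np.any(M <= 0):
        raise ValueError("capacities and m_stars must be positive")
    A = np.column_stack([np.log(C), np.ones_like(C)])
    (a, b), *_ = np.linalg.lstsq(A, np.log(M), rcond=None)
    return PowerLawFit(float(a), float(np.exp(b)))


# ---------------------------------------------------------------------------
# Path between symmetric critical points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathProfile:
    """Utility along the chained segments tMe -> t(M+1)e.

    ``best_m`` is the M whose *symmetric* point attains the maximum among the
    even points on the path. ``interior_exceeds_symmetric`` flags grid points
    strictly inside a segment that beat every symmetric point; they arise from
    the discontinuity of the utility at the simplex boundary (an option given
    infinitesimal time immediately becomes a choosable near-prior fallback).
    """

    segment_m: np.ndarray
    fraction: np.ndarray
    utility: np.ndarray
    symmetric_utility: dict[int, float]
    best_m: int
    interior_exceeds_symmetric: bool


def simplex_path_utilities(prior: PriorSpec, params: CapacityParams,
                           m_range=range(1, 10), n_per_segment: int = 11,
                           noise: NoiseModel | None = None) -> PathProfile:
    """Evaluate the uneven-allocation utility along the inter-simplex path.

    For each M in ``m_range`` the path runs on the straight segment from the
    even point over M options (embedded with an extra zero coordinate) to the
    even point over M+1 options; both endpoints reproduce the even-allocation
    utility exactly.
    """
    noise = noise or NoiseModel(params.sigma)
    ms = list(m_range)
    if ms != sorted(ms) or ms[0] < 1 or any(b - a != 1 for a, b in zip(ms, ms[1:])):
        raise ValueError("m_range must be contiguous increasing integers >= 1")
    T = params.T
    seg_m, frac, util = [], [], []
    sym = {M: expected_utility_even(prior, M, params, noise).value for M in ms}
    sym[ms[-1] + 1] = expected_utility_even(prior, ms[-1] + 1, params, noise).value
    for M in ms:
        a = np.zeros(M + 1)
        a[:M] = T / M
        b = np.full(M + 1, T / (M + 1))
        fr = np.linspace(0.0, 1.0, n_per_segment)
        for s in fr[:-1] if M != ms[-1] else fr:
            t = (1.0 - s) * a + s * b
            if s == 0.0:
                val = sym[M]
            elif s == 1.0:
                val = sym[M + 1]
            else:
                val = expected_utility_uneven(prior, Allocation(t, T), noise).value
            seg_m.append(M)
            frac.append(s)
            util.append(val)
    util = np.asarray(util)
    best_m = min(sym, key=lambda M: (-sym[M], M))
    interior = np.array([f not in (0.0, 1.0) for f in frac])
    exceeds = bool(np.any(util[interior] > max(sym.values()) + 1e-12))
    return PathProfile(np.asarray(seg_m), np.asarray(frac), util, sym, best_m, exceeds)


# ---------------------------------------------------------------------------
# Projection and stochastic gradient ascent
# ---------------------------------------------------------------------------

def project_to_simplex(v, T: float) -> np.ndarray:
    """Euclidean projection onto {t >= 0, sum t = T} (sort-and-threshold)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("vector must be finite")
    if not T > 0:
        raise ValueError("T must be positive")
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - T
    k = np.arange(1, v.size + 1)
    rho = np.nonzero(u - css / k > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class OptimTrace:
    """Per-iteration record of projected stochastic gradient ascent."""

    iterates: list[np.ndarray] = field(default_factory=list)
    utilities: list[UtilityEstimate] = field(default_factory=list)
    cv: list[float] = field(default_factory=list)
    cv_active: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    seed: int = 0
    converged: bool = False

    @property
    def final_allocation(self) -> np.ndarray:
        return self.iterates[-1]

    @property
    def final_active_count(self) -> int:
        return int(np.count_nonzero(self.iterates[-1] > 0))


def _cv(t: np.ndarray) -> float:
    m = t.mean()
    return float(t.std() / m) if m > 0 else 0.0


def _muhat_dx_dt(prior: PriorSpec, x: np.ndarray, t: float, noise: NoiseModel):
    """(muhat, d muhat/dx, d muhat/dt); analytic for the Gaussian prior."""
    sig2 = noise.sigma**2
    if prior.family == "gaussian":
        den = 1.0 / prior.sigma0**2 + t / sig2
        mh = (prior.mu0 / prior.sigma0**2 + x / sig2) / den
        dmx = (1.0 / sig2) / den
        dmt = -mh / den / sig2
        return mh, dmx, dmt
    mh = posterior_mean(prior, x, t, noise)
    hx = 1e-5 * (prior.sd * t + noise.sigma * np.sqrt(t)) + 1e-12
    ht = 1e-5 * t
    dmx = (posterior_mean(prior, x + hx, t, noise) - posterior_mean(prior, x - hx, t, noise)) / (2 * hx)
    dmt = (posterior_mean(prior, x, t + ht, noise) - posterior_mean(prior, x, t - ht, noise)) / (2 * ht)
    return mh, dmx, dmt


def stochastic_gradient_ascent(
    prior: PriorSpec,
    params: CapacityParams,
    dims: int = 20,
    seed: int = 0,
    steps: int = 1000,
    batch: int = 10_000,
    eta0: float | None = None,
    kappa: float = 100.0,
    noise: NoiseModel | None = None,
    init: np.ndarray | None = None,
    cv_tol: float = 1e-4,
    cv_window: int = 200,
) -> OptimTrace:
    """Maximize E[max_i muhat_i] over the simplex by projected SGA.

    The gradient is the pathwise (reparametrized) estimator: endpoints are
    written as ``x_i = mu_i t_i + sigma sqrt(t_i) z_i`` with the batch of
    ``(mu, z)`` held fixed within a step, and only the winning option of each
    trial contributes ``d muhat/d t`` through both its endpoint and the
    explicit time dependence. Zero-time options are unsampled and excluded
    from the max. Stops on the step budget or when both recorded CVs (full
    vector and active support) change by less than ``cv_tol`` over
    ``cv_window`` steps; near-flat landscapes at small capacity equilibrate
    slowly, so the plateau window is deliberately long.
    """
    if dims < 2:
        raise ValueError("dims must be >= 2")
    noise = noise or NoiseModel(params.sigma)
    rng = np.random.default_rng(seed)
    T = params.T
    t = project_to_simplex(rng.dirichlet(np.ones(dims)) * T, T) if init is None \
        else project_to_simplex(np.asarray(init, dtype=float), T)
    eta0 = 0.1 * T if eta0 is None else eta0
    trace = OptimTrace(seed=seed)
    sig = noise.sigma
    for k in range(steps):
        mu = sample_drifts(prior, (batch, dims), rng)
        z = rng.standard_normal((batch, dims))
        mh = np.full((batch, dims), -np.inf)
        dmds = np.zeros((batch, dims))
        for i in range(dims):
            ti = t[i]
            if ti <= 0:
                continue
            x = mu[:, i] * ti + sig * np.sqrt(ti) * z[:, i]
            m_i, dmx, dmt = _muhat_dx_dt(prior, x, ti, noise)
            dxdt = mu[:, i] + sig * z[:, i] / (2.0 * np.sqrt(ti))
            mh[:, i] = m_i
            dmds[:, i] = dmx * dxdt + dmt
        winner = np.argmax(mh, axis=1)
        umax = mh[np.arange(batch), winner]
        if not np.all(np.isfinite(umax)):
            trace.converged = False
            break
        g = np.zeros(dims)
        np.add.at(g, winner, dmds[np.arange(batch), winner])
        g /= batch
        eta = eta0 / (1.0 + k / kappa)
        t = project_to_simplex(t + eta * g, T)
        trace.iterates.append(t.copy())
        trace.utilities.append(
            UtilityEstimate(float(umax.mean()), float(umax.std(ddof=1) / np.sqrt(batch)),
                            "monte_carlo"))
        trace.cv.append(_cv(t))
        trace.cv_active.append(_cv(t[t > 0]))
        trace.step_sizes.append(eta)
        plateau = k >= cv_window and \
            abs(trace.cv[-1] - trace.cv[-1 - cv_window]) < cv_tol and \
            abs(trace.cv_active[-1] - trace.cv_active[-1 - cv_window]) < cv_tol
        if plateau:
            trace.converged = True
            break
    else:
        trace.converged = True
    return trace
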