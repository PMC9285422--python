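"""Closed-form small- and large-capacity behavior of the optimal breadth.

At small capacity the expected utility expands as
``U = mu0 + sigma0 sqrt(C) h(M) + O(C)`` with ``h(M) = E[max of M standard
normals]/sqrt(M)`` for *any* prior, so the optimal number of sampled options is
capacity-independent; ``h`` peaks at M = 5. At large capacity the expected
maximum is replaced by its extreme-value scale ``b_M`` and maximizing the
resulting expression gives, to leading order, ``M* log M* = C``, inverted by
the Lambert W function as ``M* = C / W(C)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import lambertw

from .utility import expected_max_std_normal

__all__ = [
    "small_capacity_utility",
    "small_capacity_objective",
    "extreme_value_scale",
    "large_capacity_utility",
    "optimal_m_large_capacity",
]

_LOG4PI = np.log(4.0 * np.pi)


def small_capacity_objective(M: int) -> float:
    """h(M) = E[max of M standard normals] / sqrt(M); h(1) = 0, peak at M = 5."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return expected_max_std_normal(M) / np.sqrt(M)


def small_capacity_utility(M: int, C: float, mu0: float, sigma0: float) -> float:
    """Leading-order utility for C << 1: mu0 + sigma0 sqrt(C) h(M).

    Exact at C = 0; the truncation error is O(C) uniformly in M (in fact
    O(C^{3/2}) for the Gaussian prior).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if C < 0:
        raise ValueError("C must be nonnegative")
    return mu0 + sigma0 * np.sqrt(C) * small_capacity_objective(M)


def extreme_value_scale(M) -> np.ndarray | float:
    """b_M = (2 log M - log log M - log 4 pi)^(1/2).

    Leading asymptotic of the expected maximum of M standard normals. For
    small M the radicand is negative and the formula is meaningless; use the
    exact :func:`~breadthdepth.utility.expected_max_std_normal` there.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 2):
        raise ValueError("b_M needs M >= 2 (log log M must be defined)")
    r = 2.0 * np.log(M) - np.log(np.log(M)) - _LOG4PI
    if np.any(r <= 0):
        raise ValueError(
            "b_M radicand nonpositive at small M; use the exact expected maximum instead"
        )
    out = np.sqrt(r)
    return float(out) if out.ndim == 0 else out


def large_capacity_utility(M, C: float, mu0: float, sigma0: float):
    """Asymptotic utility for M >> 1: mu0 + sigma0 b_M / sqrt(1 + M/C)."""
    if C <= 0:
        raise ValueError("C must be positive")
    M = np.asarray(M, dtype=float)
    out = mu0 + sigma0 * extreme_value_scale(M) / np.sqrt(1.0 + M / C)
    return float(out) if out.ndim == 0 else out


def optimal_m_large_capacity(C) -> np.ndarray | float:
    """Continuous large-capacity optimum M* = C / W(C).

    Solves the leading-order stationarity condition M* log M* = C on the
    principal Lambert branch; intended for C > e so M* > e.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("C must be positive")
    out = C / lambertw(C).real
    return float(out) if out.ndim == 0 else out
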