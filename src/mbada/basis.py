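"""Scaled discrete Tchebichef polynomial bases.

The discrete Tchebichef polynomials :math:`t_n(x)` are orthogonal under
summation over the integer grid :math:`x = 0, \\ldots, N-1`.  Working with
them at image resolutions requires the *scaled* family

.. math::

    \\tilde t_n(x) = t_n(x) / b(n, N), \\qquad b(n, N) = N^n,

whose values stay in a numerically benign range, together with the squared
norms

.. math::

    \\rho(n, N) = \\sum_{x=0}^{N-1} \\tilde t_n(x)^2 ,

which supply the normalisation needed to invert the moment transform.

Two evaluation routes are provided:

* :func:`scaled_polynomial_value` — the closed-form signed binomial sum,
  evaluated in exact integer arithmetic.  It is the reference
  implementation ("oracle") and is only meant for small domains.
* :func:`build_basis` — tabulates a whole basis by a stable recursion in
  the spatial variable ``x``, started from the closed-form values at
  ``x = 0, 1`` and completed by the parity symmetry
  :math:`\\tilde t_n(N-1-x) = (-1)^n \\tilde t_n(x)`.  The more obvious
  three-term recurrence in the order ``n`` loses all accuracy for orders
  beyond roughly ``N/2`` (the desired solution becomes the minimal one),
  so it is deliberately not used.

Bases are cached per ``(N, K)`` within a process, since an image batch
typically reuses a handful of axis lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, exp, factorial, lgamma, log

import numpy as np

__all__ = [
    "TchebichefBasis",
    "scaled_polynomial_value",
    "squared_norm",
    "build_basis",
]


def _check_domain(n: int, N: int, *, what: str = "order") -> None:
    if N < 1:
        raise ValueError(f"domain_length must be >= 1, got {N}")
    if not 0 <= n <= N - 1:
        raise ValueError(
            f"{what} must satisfy 0 <= {what} <= N-1 = {N - 1}, got {n}"
        )


def scaled_polynomial_value(order: int, point: int, domain_length: int) -> float:
    """Evaluate :math:`\\tilde t_n(x)` by the closed-form signed binomial sum.

    .. math::

        \\tilde t_n(x) = \\frac{n!}{N^n} \\sum_{i=0}^{n} (-1)^{n-i}
            \\binom{N-1-i}{n-i} \\binom{n+i}{n} \\binom{x}{i}

    The sum is carried out in exact integer arithmetic, so the only
    rounding is the final division.  Intended as a small-``N`` reference;
    use :func:`build_basis` for whole tables.

    Parameters
    ----------
    order
        Polynomial order ``n`` with ``0 <= n <= N-1``.
    point
        Grid point ``x`` with ``0 <= x <= N-1``.
    domain_length
        Number of grid points ``N``.
    """
    n, x, N = order, point, domain_length
    _check_domain(n, N, what="order")
    _check_domain(x, N, what="point")
    acc = 0
    for i in range(n + 1):
        term = comb(N - 1 - i, n - i) * comb(n + i, n) * comb(x, i)
        acc += -term if (n - i) % 2 else term
    # exact big-int division; Python rounds the quotient correctly
    return (factorial(n) * acc) / (N**n)


def _log_squared_norm(n: int, N: int) -> float:
    # rho(n,N) = [prod_{i=1..n} (N^2 - i^2)] * N / (2n+1) / N^(2n)
    # with prod (N-i)(N+i) = (N-1)!/(N-n-1)! * (N+n)!/N!
    return (
        lgamma(N)
        - lgamma(N - n)
        + lgamma(N + n + 1)
        - lgamma(N + 1)
        + log(N)
        - log(2 * n + 1)
        - 2 * n * log(N)
    )


def squared_norm(order: int, domain_length: int) -> float:
    """Squared norm :math:`\\rho(n, N)` of the scaled polynomial.

    Evaluated through the closed-form product
    :math:`\\rho(n,N) = \\prod_{i=1}^{n}(N^2-i^2) \\cdot N / ((2n+1) N^{2n})`
    in log space, which agrees with the direct sum of squares to machine
    precision while remaining finite for every valid order.
    """
    n, N = order, domain_length
    _check_domain(n, N)
    return exp(_log_squared_norm(n, N))


@dataclass(frozen=True)
class TchebichefBasis:
    """Tabulated scaled Tchebichef polynomials for one axis.

    Attributes
    ----------
    domain_length
        Number of grid points ``N``.
    max_order
        Highest tabulated order ``K`` (``0 <= K <= N-1``).
    values
        ``(K+1, N)`` read-only array, ``values[n, x] = t̃_n(x)``.
    norms
        Length ``K+1`` read-only array of squared norms
        ``norms[n] = Σ_x t̃_n(x)²``.
    """

    domain_length: int
    max_order: int
    values: np.ndarray = field(repr=False)
    norms: np.ndarray = field(repr=False)

    #: scaling rule applied to the classical polynomials
    scaling_constant_rule: str = "b(n, N) = N**n"


def _build_orthonormal(N: int, K: int) -> np.ndarray:
    """Orthonormal rows phi_n(x) = t̃_n(x)/sqrt(rho(n,N)), stable to N ~ 512."""
    P = np.zeros((K + 1, N))
    if N == 1:
        P[0, 0] = 1.0
        return P
    # phi_n(0) by a ratio recurrence (all factors are O(1))
    p0 = np.empty(K + 1)
    p0[0] = 1.0 / np.sqrt(N)
    for n in range(1, K + 1):
        p0[n] = -p0[n - 1] * np.sqrt(
            (N - n) * (2 * n + 1) / ((2 * n - 1) * (N + n))
        )
    half = (N + 1) // 2
    for n in range(K + 1):
        row = np.empty(N)
        row[0] = p0[n]
        row[1] = p0[n] * (1.0 + n * (1 + n) / (1.0 - N))
        lam = n * (n + 1)
        for x in range(2, half):
            a = (2 * (x - 1) * (N - x + 1) + (N + 1 - 2 * x) - lam) / (x * (N - x))
            b = ((x - 1) * (N - x + 1)) / (x * (N - x))
            row[x] = a * row[x - 1] - b * row[x - 2]
        sgn = -1.0 if n % 2 else 1.0
        row[half:] = sgn * row[: N - half][::-1]
        if N % 2 == 1 and n % 2 == 1:
            row[half - 1] = 0.0  # centre point vanishes exactly by parity
        P[n] = row
    return P


@lru_cache(maxsize=64)
def _cached_basis(N: int, K: int) -> TchebichefBasis:
    P = _build_orthonormal(N, K)
    scale = np.exp([0.5 * _log_squared_norm(n, N) for n in range(K + 1)])
    values = P * scale[:, None]
    values[0] = 1.0  # t̃_0 ≡ 1 exactly; avoids a 1-ulp log/exp wobble
    norms = np.einsum("nx,nx->n", values, values)
    values.setflags(write=False)
    norms.setflags(write=False)
    return TchebichefBasis(domain_length=N, max_order=K, values=values, norms=norms)


def build_basis(domain_length: int, max_order: int) -> TchebichefBasis:
    """Construct (or fetch from cache) a basis table for one axis.

    Parameters
    ----------
    domain_length
        Number of grid points ``N >= 1``.
    max_order
        Highest order ``K`` to tabulate; the maximum order is ``N-1``.

    Returns
    -------
    TchebichefBasis
        Satisfies row-0 ≡ 1, the parity symmetry, and orthogonality of
        distinct rows to machine precision relative to
        ``sqrt(norms[p] * norms[q])``.
    """
    N, K = int(domain_length), int(max_order)
    if N < 1:
        raise ValueError(f"domain_length must be >= 1, got {N}")
    if K < 0:
        raise ValueError(f"max_order must be >= 0, got {K}")
    if K > N - 1:
        raise ValueError(
            f"maximum order is N-1 = {N - 1} for domain_length {N}, got {K}"
        )
    return _cached_basis(N, K)
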