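"""Deterministic population-size histories and the coalescent time-scale change.

A genealogy drawn from a population whose (haploid-scale) effective size
``t`` generations before the present is ``N(t)`` can be mapped onto the
standard constant-size coalescent through the time-scale change

    tau = g(t) = int_0^t dsigma / N(sigma).

On the ``tau`` scale the first coalescence among ``j`` lineages is a
unit-rate-scaled exponential with rate ``C(j,2) = j(j-1)/2``, so on the
natural scale its density is

    q_j(t) = C(j,2)/N(t) * exp(-C(j,2) * g(t)).

Three history kinds are supported: ``constant`` (``N(t) = N0``),
``exponential`` growth toward the present (``N(t) = N0*exp(-r*t)``, with
product parameter ``rho = r*N0``), and ``general`` (an arbitrary positive,
piecewise-continuous ``size_fn``).  Units throughout are generations, and
``N0`` is on the coalescent scale on which a pair of lineages coalesces
after a mean waiting time of ``N0`` generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, special

__all__ = [
    "PopulationHistory",
    "population_size",
    "time_scale",
    "inverse_time_scale",
    "first_coalescence_density",
    "expected_first_coalescence_time",
    "exp_scaled_e1",
    "binom2",
]


def binom2(j):
    """Binomial coefficient C(j, 2) = j*(j-1)/2, the pairwise coalescence rate."""
    j = np.asarray(j, dtype=float)
    return j * (j - 1.0) / 2.0


def exp_scaled_e1(x):
    """Scaled exponential integral ``exp(x) * E1(x)`` for x > 0, overflow-free.

    For x <= 30 the direct product with :func:`scipy.special.exp1` is exact to
    machine precision.  Beyond that ``exp(x)`` overflows long before ``E1(x)``
    underflows, so the scaled value is computed from the classical continued
    fraction

        exp(x) E1(x) = 1/(x+1- 1/(x+3- 4/(x+5- 9/(x+7- ...))))

    evaluated by the modified Lentz algorithm.  Accurate to ~1e-15 relative
    over x in [1e-308, 1e300]; used for mean first-coalescence times under
    exponential growth where x = C(j,2)/rho can exceed 1e8.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x <= 0):
        raise ValueError("exp_scaled_e1 requires x > 0")
    out = np.empty_like(x)
    small = x <= 30.0
    out[small] = np.exp(x[small]) * special.exp1(x[small])
    xl = x[~small]
    if xl.size:
        b = xl + 1.0
        c = np.full_like(xl, 1e308)
        d = 1.0 / b
        h = d.copy()
        for i in range(1, 500):
            a = -float(i * i)
            b = b + 2.0
            d = 1.0 / (a * d + b)
            c = b + a / c
            delta = c * d
            h = h * delta
            if np.all(np.abs(delta - 1.0) < 1e-16):
                break
        out[~small] = h
    return out[0] if scalar else out


@dataclass(frozen=True)
class PopulationHistory:
    """A deterministic effective-size trajectory N(t), t >= 0 in generations.

    Construct through :meth:`constant`, :meth:`exponential` or
    :meth:`general`.  ``N0`` is the present-day size; ``r`` the exponential
    growth exponent per generation (the population grew toward the present,
    so looking backwards ``N(t) = N0*exp(-r*t)``).  ``rho = r*N0`` is the
    product parameter that alone controls the shape of the expected
    site-frequency spectrum.
    """

    kind: str
    N0: float = 1.0
    r: float = 0.0
    size_fn: Optional[Callable[[float], float]] = field(default=None, repr=False)
    breakpoints: Optional[Sequence[float]] = None

    @classmethod
    def constant(cls, N0: float) -> "PopulationHistory":
        if N0 <= 0:
            raise ValueError("N0 must be positive")
        return cls(kind="constant", N0=float(N0))

    @classmethod
    def exponential(cls, N0: float, r: float = None, *, rho: float = None) -> "PopulationHistory":
        """Exponential growth; give exactly one of ``r`` or ``rho = r*N0``."""
        if N0 <= 0:
            raise ValueError("N0 must be positive")
        if (r is None) == (rho is None):
            raise ValueError("give exactly one of r or rho")
        if r is None:
            r = rho / N0
        if r < 0:
            raise ValueError("growth exponent r must be >= 0")
        return cls(kind="exponential", N0=float(N0), r=float(r))

    @classmethod
    def general(
        cls,
        size_fn: Callable[[float], float],
        *,
        breakpoints: Optional[Sequence[float]] = None,
    ) -> "PopulationHistory":
        """Arbitrary positive size history given as a black-box function of t.

        ``breakpoints`` (optional) lists discontinuity/kink locations passed
        to the quadrature routines.
        """
        model = cls(
            kind="general",
            N0=float(size_fn(0.0)),
            size_fn=size_fn,
            breakpoints=tuple(breakpoints) if breakpoints else None,
        )
        if model.N0 <= 0:
            raise ValueError("size_fn(0) must be positive")
        return model

    @property
    def rho(self) -> float:
        """Product parameter rho = r*N0 (zero for a constant history)."""
        return self.r * self.N0

    # -- size, time-scale change and its inverse ---------------------------

    def size(self, t):
        return population_size(self, t)

    def g(self, t):
        return time_scale(self, t)

    def g_inv(self, tau):
        return inverse_time_scale(self, tau)


def _check_nonneg(t, name="t"):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{name} must be >= 0")
    return t


def population_size(model: PopulationHistory, t):
    """Evaluate N(t); vectorized over t."""
    t = _check_nonneg(t)
    if model.kind == "constant":
        return np.broadcast_to(model.N0, t.shape).copy() if t.ndim else model.N0
    if model.kind == "exponential":
        return model.N0 * np.exp(-model.r * t)
    val = np.vectorize(model.size_fn, otypes=[float])(t)
    if np.any(val <= 0):
        bad = np.asarray(t)[np.asarray(val) <= 0]
        raise ValueError(f"size_fn evaluated non-positive at t={bad!r}")
    return val if t.ndim else float(val)


def time_scale(model: PopulationHistory, t):
    """Time-scale change tau = g(t) = int_0^t dsigma/N(sigma); vectorized."""
    t = _check_nonneg(t)
    if model.kind == "constant":
        return t / model.N0
    if model.kind == "exponential":
        if model.r == 0.0:
            return t / model.N0
        # (exp(r t) - 1) / (r N0), via expm1 for small r*t
        return np.expm1(model.r * t) / (model.r * model.N0)
    scalar = t.ndim == 0
    tv = np.atleast_1d(t)
    out = np.empty_like(tv)
    pts = list(model.breakpoints) if model.breakpoints else None
    for i, ti in enumerate(tv):
        inner = [p for p in pts if 0 < p < ti] if pts else None
        val, err = integrate.quad(
            lambda s: 1.0 / model.size_fn(s), 0.0, ti, points=inner, limit=500
        )
        if not np.isfinite(val):
            raise ArithmeticError(f"quadrature of 1/N failed on [0, {ti}]")
        out[i] = val
    return float(out[0]) if scalar else out


def inverse_time_scale(model: PopulationHistory, tau):
    """Inverse time-scale change t = g^{-1}(tau); vectorized."""
    tau = _check_nonneg(tau, "tau")
    if model.kind == "constant":
        return tau * model.N0
    if model.kind == "exponential":
        if model.r == 0.0:
            return tau * model.N0
        return np.log1p(model.N0 * model.r * tau) / model.r
    scalar = tau.ndim == 0
    tv = np.atleast_1d(tau)
    out = np.empty_like(tv)

    def g_or_inf(t):
        # shrinking histories can overflow 1/N far in the past; treat any
        # failure there as "beyond tau" (g is increasing)
        try:
            with np.errstate(over="ignore", divide="ignore"):
                val = time_scale(model, t)
        except ArithmeticError:
            return np.inf
        return val

    for i, taui in enumerate(tv):
        if taui == 0.0:
            out[i] = 0.0
            continue
        # grow a bracket, then bisect the monotone equation g(t) = tau
        lo, hi = 0.0, model.N0 * min(max(taui, 1e-6), 1.0)
        for _ in range(200):
            if g_or_inf(hi) >= taui:
                break
            lo, hi = hi, hi * 2.0
        else:
            raise ArithmeticError(
                f"could not bracket g^-1({taui}); g({hi}) = {g_or_inf(hi)}"
            )
        for _ in range(110):
            mid = 0.5 * (lo + hi)
            if g_or_inf(mid) < taui:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-14 * hi:
                break
        out[i] = 0.5 * (lo + hi)
    return float(out[0]) if scalar else out


def first_coalescence_density(model: PopulationHistory, j: int, t):
    """Density q_j(t) of the first coalescence time among j lineages.

    q_j(t) = C(j,2)/N(t) * exp(-C(j,2) * g(t)); non-negative and integrating
    to one over [0, inf).
    """
    if j < 2:
        raise ValueError("need at least j = 2 lineages to coalesce")
    t = _check_nonneg(t)
    lam = binom2(j)
    return lam / population_size(model, t) * np.exp(-lam * time_scale(model, t))


def expected_first_coalescence_time(model: PopulationHistory, j: int) -> float:
    """Mean e_j of the first coalescence time among j lineages.

    Constant history: N0/C(j,2).  Exponential growth: the closed form
    ``e_j = exp(beta) * E1(beta) / r`` with ``beta = C(j,2)/(r*N0)``,
    evaluated through the scaled exponential integral so that no overflow
    occurs however extreme ``beta`` is.  General history: numerical
    quadrature of ``t * q_j(t)``.
    """
    if j < 2:
        raise ValueError("need at least j = 2 lineages to coalesce")
    return float(first_coalescence_means(model, j)[-1])


def first_coalescence_means(model: PopulationHistory, n: int) -> np.ndarray:
    """Vector of means e_j for j = 2..n (ascending j); workhorse for the
    stable expectation formulas, O(n) for constant/exponential histories."""
    if n < 2:
        raise ValueError("n must be >= 2")
    j = np.arange(2, n + 1, dtype=float)
    lam = binom2(j)
    if model.kind == "constant" or (model.kind == "exponential" and model.r == 0.0):
        return model.N0 / lam
    if model.kind == "exponential":
        beta = lam / (model.r * model.N0)
        return exp_scaled_e1(beta) / model.r
    # integrate on the tau scale, e_j = int g^{-1}(tau) C(j,2) e^{-C(j,2) tau} dtau,
    # so the exponential weight is explicit and N(t) is never probed at
    # times carrying negligible mass
    out = np.empty(n - 1)
    for i in range(n - 1):
        lam_i = lam[i]

        def integrand(tau):
            return inverse_time_scale(model, tau) * lam_i * math.exp(-lam_i * tau)

        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
        out[i] = val
    return out
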