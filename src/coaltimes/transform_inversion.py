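"""Marginal densities of coalescence times by inverting the time-scaled
Laplace (Fourier) transform, for arbitrary sample size and size history.

The transform of the T_k marginal with respect to the scaled time
``tau = g(t)`` is a finite product of Lorentzian factors,

    P(s) = prod_{j=k}^{n} C(j,2) / (s + C(j,2)),

i.e. T_k on the tau scale is hypoexponential.  Setting ``s = i*omega`` and
inverting the Fourier integral gives the density on the tau scale (the
constant-size, N0 = 1 density); the change of variables back through
``t = g^{-1}(tau)`` with Jacobian ``1/N(t)`` gives the density on the
natural time scale:

    pi_Tk(t) = 1/N(t) * 1/pi * int_0^inf Re[P(i w) e^{i w g(t)}] dw.

Two inversion paths are provided: adaptive Gauss-Kronrod quadrature of the
Fourier integral (freely placed time points, relative accuracy ~1e-5 or
better) and an inverse-FFT path on a uniform tau grid (much faster, grid
sized from the hypoexponential moments).  A third, classical path — the
signed mixture of first-coalescence densities with partial-fraction
coefficients — is retained as a small-n oracle.

As n -> infinity the product converges to an infinite product expressible
as a quotient of gamma functions, giving the closed-form limit transform of
TMRCA, ``2*pi*i*w / cos(pi*sqrt(1/4 - 2*i*w))``, which is inverted here by
quadrature only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from .exact_expectations import SMALL_N_LIMIT, partial_fraction_coefficients
from .popmodels import (
    PopulationHistory,
    binom2,
    first_coalescence_density,
    inverse_time_scale,
    population_size,
    time_scale,
)

__all__ = [
    "DensityGrid",
    "upsilon_product",
    "log_upsilon_product",
    "hypoexponential_moments",
    "default_time_grid",
    "invert_density_quadrature",
    "invert_density_fft",
    "density_moments",
    "skewness_profile",
    "tmrca_limit_density",
    "marginal_density_partial_fraction",
]

# normalization tolerance per inversion method
_NORM_TOL = {"quadrature": 1e-5, "fft": 1e-3, "partial_fraction": 1e-6, "limit": 1e-3}


@dataclass
class DensityGrid:
    """A tabulated coalescence-time density.

    ``times`` are strictly increasing (generations), ``values`` the density
    there (tiny negative quadrature/FFT ringing is clipped to zero).
    ``method`` is one of quadrature | fft | partial_fraction | limit.
    """

    times: np.ndarray
    values: np.ndarray
    scenario: PopulationHistory
    n: Optional[int]
    k: Optional[int]
    method: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # FFT output rings at the truncation level (~1e-6 of the peak) and
        # the classical signed mixture carries alternating-cancellation
        # noise near n = 50; quadrature should be clean to ~1e-9
        ringing = 1e-4 if self.method in ("fft", "partial_fraction") else 1e-9
        if np.any(self.values < -ringing * max(1e-300, self.values.max())):
            warnings.warn(
                f"density has negative excursions beyond ringing tolerance "
                f"(min {self.values.min():.3e}); check inversion accuracy"
            )
        self.values = np.clip(self.values, 0.0, None)

    def integral(self) -> float:
        return float(integrate.simpson(self.values, x=self.times))


def log_upsilon_product(n: int, k: int, omega) -> np.ndarray:
    """log of the transform product at s = i*omega, summed in log space so
    the value never underflows however many factors there are."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    lam = binom2(np.arange(k, n + 1, dtype=float))
    s = 1j * np.asarray(omega, dtype=float)
    return np.sum(np.log(lam) - np.log(lam + s[..., None]), axis=-1)


def upsilon_product(n: int, k: int, omega):
    """Transform of the T_k marginal on the tau scale, evaluated at
    s = i*omega.  Exactly 1 at omega = 0; modulus <= 1; conjugate-symmetric
    in omega."""
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    val = np.exp(log_upsilon_product(n, k, np.atleast_1d(omega)))
    return complex(val[0]) if scalar else val


def hypoexponential_moments(n: int, k: int):
    """(mean, sd, skewness) of T_k on the tau scale (constant size, N0=1):
    closed forms for a sum of independent exponentials with rates C(j,2)."""
    lam = binom2(np.arange(k, n + 1, dtype=float))
    m1 = np.sum(1.0 / lam)
    var = np.sum(1.0 / lam**2)
    m3 = np.sum(2.0 / lam**3)
    return m1, np.sqrt(var), m3 / var**1.5


def default_time_grid(
    n: int,
    k: int,
    model: PopulationHistory,
    n_points: int = 3000,
    lower_sds: float = 12.0,
    upper_sds: float = 30.0,
) -> np.ndarray:
    """Time grid covering essentially all T_k mass: uniform on the tau scale
    over [mean - lower_sds*sd, mean + upper_sds*sd] (clipped at 0) using the
    hypoexponential moments, mapped back through g^{-1}.  The generous upper
    margin covers the exponential right tail (decay rate C(k,2) per unit
    tau, so 30 sd leaves mass below ~1e-13 even in the single-factor case).
    """
    m1, sd, _ = hypoexponential_moments(n, k)
    tau = np.linspace(max(0.0, m1 - lower_sds * sd), m1 + upper_sds * sd, n_points)
    return inverse_time_scale(model, tau)


def _truncation_frequency(n: int, k: int, tiny: float = 1e-13) -> float:
    """Smallest Omega with |P(i*Omega)| < tiny, by doubling from C(k,2)."""
    Om = max(binom2(k), 1.0)
    for _ in range(200):
        if log_upsilon_product(n, k, np.array([Om]))[0].real < np.log(tiny):
            return Om
        Om *= 2.0
    return Om


def invert_density_quadrature(
    n: int,
    k: int,
    model: PopulationHistory,
    times: Optional[Sequence[float]] = None,
    *,
    epsrel: float = 1e-8,
    n_points: int = 3000,
) -> DensityGrid:
    """T_k density by adaptive Gauss-Kronrod quadrature of the Fourier
    inversion integral, evaluated jointly at all requested time points
    (``times`` defaults to :func:`default_time_grid`).

    The integrand uses only the real part on [0, Omega] (conjugate
    symmetry), with Omega chosen so |P(i*Omega)| < 1e-13.  For k = n the
    transform has a single slowly-decaying factor, so the analytic
    first-coalescence density is returned directly.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if times is None:
        times = default_time_grid(n, k, model, n_points=n_points)
    times = np.asarray(times, dtype=float)
    if k == n:
        vals = first_coalescence_density(model, n, times)
        return DensityGrid(times, vals, model, n, k, "quadrature")
    tau = np.atleast_1d(time_scale(model, times))
    Om = _truncation_frequency(n, k)

    def integrand(w):
        P = np.exp(log_upsilon_product(n, k, np.array([w]))[0])
        return (P * np.exp(1j * w * tau)).real

    I, err = integrate.quad_vec(
        integrand, 0.0, Om, epsabs=1e-12, epsrel=epsrel, limit=10000
    )
    if not np.all(np.isfinite(I)):
        raise ArithmeticError("Fourier-inversion quadrature failed to converge")
    vals = I / np.pi / np.atleast_1d(population_size(model, times))
    return DensityGrid(times, vals, model, n, k, "quadrature")


def invert_density_fft(
    n: int,
    k: int,
    model: PopulationHistory,
    grid_points: int = 1024,
    *,
    margin_sds: float = 12.0,
) -> DensityGrid:
    """T_k density via inverse FFT of the transform on a uniform tau grid.

    The tau range is [0, mean + margin_sds*sd] from the hypoexponential
    moments (the margin absorbs right-tail skewness).  If density mass at
    the grid boundary exceeds 1e-6 the range is doubled (aliasing guard).
    The tau-scale density is mapped to natural time with the 1/N(t)
    Jacobian, so the returned grid is non-uniform in t for growing
    populations.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    m1, sd, _ = hypoexponential_moments(n, k)
    tau_max = m1 + margin_sds * sd
    for _attempt in range(6):
        dtau = tau_max / grid_points
        w = 2.0 * np.pi * np.fft.fftfreq(grid_points, d=dtau)
        P = np.exp(log_upsilon_product(n, k, w))
        pi_tau = np.fft.ifft(P).real / dtau
        boundary = abs(pi_tau[-1]) * dtau
        if boundary <= 1e-6:
            break
        warnings.warn(
            f"FFT inversion: boundary mass {boundary:.2e} > 1e-6, doubling tau range"
        )
        tau_max *= 2.0
        grid_points *= 2
    tau = np.arange(grid_points) * dtau
    # drop tau=0 duplicate issues: grid starts at 0 which maps to t=0
    t = inverse_time_scale(model, tau)
    vals = pi_tau / population_size(model, t)
    return DensityGrid(t, vals, model, n, k, "fft")


def density_moments(grid: DensityGrid):
    """(mean, sd, skewness) of a tabulated density by trapezoidal
    integration; the grid must integrate to 1 within its method tolerance."""
    tol = _NORM_TOL.get(grid.method, 1e-3)
    norm = grid.integral()
    if abs(norm - 1.0) > tol:
        raise ValueError(
            f"density integrates to {norm:.6g}, outside 1 +/- {tol} for "
            f"method {grid.method!r}"
        )
    t, p = grid.times, grid.values / norm
    mean = integrate.simpson(t * p, x=t)
    var = integrate.simpson((t - mean) ** 2 * p, x=t)
    sd = np.sqrt(var)
    skew = integrate.simpson((t - mean) ** 3 * p, x=t) / sd**3
    return float(mean), float(sd), float(skew)


def skewness_profile(
    n: int,
    model: PopulationHistory,
    k_values: Sequence[int],
    *,
    method: str = "fft",
    grid_points: int = 2048,
) -> np.ndarray:
    """Skewness of T_k for each requested k, via inversion + moments.

    The profile decreases with growing rho and rises sharply for k in the
    fourth quartile of 2..n (times near the leaves are dominated by the
    last exponential factor, skewness -> 2 under constant size).
    """
    out = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        if not 2 <= k <= n:
            raise ValueError("k_values must lie in 2..n")
        if k == n:
            grid = invert_density_quadrature(n, k, model)
        elif method == "fft":
            grid = invert_density_fft(n, k, model, grid_points=grid_points)
        else:
            grid = invert_density_quadrature(n, k, model)
        out[i] = density_moments(grid)[2]
    return out


def _limit_kernel(w):
    """Limit transform of TMRCA as n -> inf: 2*pi*i*w / cos(pi*sqrt(1/4-2iw)),
    with the removable omega = 0 singularity set to its analytic value 1."""
    w = np.asarray(w, dtype=float)
    z = np.sqrt(0.25 - 2j * w)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 2.0 * np.pi * 1j * w / np.cos(np.pi * z)
    return np.where(w == 0.0, 1.0 + 0.0j, val)


def tmrca_limit_density(
    model: PopulationHistory,
    times: Optional[Sequence[float]] = None,
    *,
    epsrel: float = 1e-9,
) -> DensityGrid:
    """Limit density of TMRCA as the sample size grows without bound.

    Quadrature of the closed-form limit transform (principal branches of
    the complex square root and cosine).  The kernel decays like
    omega * exp(-pi*sqrt(omega)), so truncation at |kernel| < 1e-14 is
    cheap.  FFT inversion is deliberately not offered for this kernel:
    its slow algebraic onset makes aliasing hard to control.

    ``times`` defaults to a grid covering [0, 20*N0] (the limit mean is
    2*N0 under constant size with an exponential-like right tail).
    """
    if times is None:
        tau = np.linspace(0.0, 20.0, 4000)
        times = inverse_time_scale(model, tau)
    times = np.asarray(times, dtype=float)
    tau = np.atleast_1d(time_scale(model, times))
    Om = 10.0
    while abs(_limit_kernel(np.array([Om]))[0]) > 1e-14:
        Om *= 2.0

    def integrand(w):
        return (_limit_kernel(np.array([w]))[0] * np.exp(1j * w * tau)).real

    I, _ = integrate.quad_vec(
        integrand, 0.0, Om, epsabs=1e-12, epsrel=epsrel, limit=10000
    )
    if not np.all(np.isfinite(I)):
        raise ArithmeticError("limit-density quadrature failed to converge")
    vals = I / np.pi / np.atleast_1d(population_size(model, times))
    return DensityGrid(times, vals, model, None, 2, "limit")


def marginal_density_partial_fraction(
    n: int,
    k: int,
    model: PopulationHistory,
    times: Optional[Sequence[float]] = None,
) -> DensityGrid:
    """Classical T_k density as a signed mixture of first-coalescence
    densities, pi_Tk(t) = sum_{j=k}^n A_jkn q_j(t); kept as the small-n
    oracle (guarded at n <= 50, where the coefficients are still tame)."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if n > SMALL_N_LIMIT:
        raise ValueError(
            f"partial-fraction densities are unstable for n > {SMALL_N_LIMIT}; "
            "use invert_density_quadrature or invert_density_fft"
        )
    if times is None:
        times = default_time_grid(n, k, model)
    times = np.asarray(times, dtype=float)
    A = partial_fraction_coefficients(n, k)
    vals = np.zeros_like(times)
    for off, a in enumerate(A):
        vals += a * first_coalescence_density(model, k + off, times)
    return DensityGrid(times, vals, model, n, k, "partial_fraction")
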