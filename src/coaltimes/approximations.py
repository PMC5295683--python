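"""Closed-form large-sample approximations of expected coalescence times
and spectra (after Chen & Chen), with relative-error reports against the
exact paths and a round-off perturbation study of the spectrum recursion.

The approximations follow from the deterministic limit of the
lineage-count process under exponential growth:

    E(T_k) ~ (1/r) * ln[ 2 r N0 (1/(k-1) - 1/n) + 1 ],
    ETLBT  ~ 2 n N0 / (2 r N0 - n) * ln(2 r N0 / n),

the latter replaced by its limit 2*N0 when n = 2*r*N0 exactly.  At r -> 0
both reduce to the exact constant-size values.  Approximate spectra are
obtained by differencing the approximate E(T_k) into interval means E(S_k)
and substituting them into the standard spectrum formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .exact_expectations import (
    ExpectedSpectrum,
    etlbt_stable,
    etmrca_stable,
    expected_spectrum,
)
from .popmodels import PopulationHistory, first_coalescence_means

__all__ = [
    "ErrorReport",
    "approx_expected_time",
    "approx_etmrca",
    "approx_etlbt",
    "approx_interval_means",
    "approx_spectrum",
    "spectrum_coefficient_log",
    "relative_error_report",
    "roundoff_error_bound",
]


@dataclass
class ErrorReport:
    """One approximate-vs-exact comparison; relative error is
    |approx - exact| / exact."""

    quantity: str
    n: int
    rho: float
    exact: float
    approx: float

    @property
    def relative_error(self) -> float:
        return abs(self.approx - self.exact) / self.exact


def approx_expected_time(n: int, k, N0: float, r: float):
    """Large-sample approximation of E(T_k) under exponential growth;
    the r -> 0 limit returns the exact constant-size value
    2*N0*(1/(k-1) - 1/n).  Vectorized over k."""
    k = np.asarray(k, dtype=float)
    if n < 2 or np.any(k < 2) or np.any(k > n):
        raise ValueError("need n >= 2 and 2 <= k <= n")
    if r < 0:
        raise ValueError("r must be >= 0")
    span = 1.0 / (k - 1.0) - 1.0 / n
    if r == 0.0:
        return 2.0 * N0 * span
    return np.log1p(2.0 * r * N0 * span) / r


def approx_etmrca(n: int, N0: float, r: float) -> float:
    """k = 2 specialization: approximate expected TMRCA."""
    return float(approx_expected_time(n, 2, N0, r))


def approx_etlbt(n: int, N0: float, r: float) -> float:
    """Approximate expected total branch length under exponential growth,
    2*n*N0/(2*r*N0 - n) * ln(2*r*N0/n), with the removable n = 2*r*N0
    singularity replaced by its limit 2*N0.  (This is the reading of the
    published expression that matches the exact path to ~1e-3 in the
    rho > 10, n > 100 regime, and the only one with the stated 2*N0
    limit; pinned by tests.)  Requires r > 0."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if r <= 0:
        raise ValueError("the ETLBT approximation needs r > 0")
    two_rho = 2.0 * r * N0
    if abs(two_rho - n) < 1e-9 * n:
        return 2.0 * N0
    return 2.0 * n * N0 / (two_rho - n) * np.log(two_rho / n)


def approx_interval_means(n: int, N0: float, r: float) -> np.ndarray:
    """Approximate E(S_k), k = 2..n, by differencing the approximate
    E(T_k) (E(T_{n+1}) = 0).  Negative differences (possible at extreme
    parameters) are clipped to zero with a warning."""
    et = approx_expected_time(n, np.arange(2, n + 1), N0, r)
    es = et.copy()
    es[:-1] -= et[1:]
    if np.any(es < 0):
        warnings.warn(
            f"approximate interval means: {int(np.sum(es < 0))} negative "
            "E(S_k) values clipped to 0"
        )
        es = np.clip(es, 0.0, None)
    return es


def spectrum_coefficient_log(n: int, b_values: np.ndarray) -> np.ndarray:
    """log of the non-negative coefficients linking E(S_k) to f_nb:

        f_nb = mu * sum_k coeff(n, b, k) * E(S_k),
        coeff = (n-b-1)! (b-1)! / (n-1)! * C(n-k, b-1) * k (k-1),

    shape (len(b_values), n-1) over k = 2..n; -inf where C(n-k, b-1) = 0.
    Evaluated through gammaln: every term is positive, so log-space
    evaluation is stable at any n.
    """
    gl = special.gammaln
    b = np.asarray(b_values, dtype=float)[:, None]
    k = np.arange(2.0, n + 1)[None, :]
    with np.errstate(invalid="ignore"):
        out = (
            gl(n - b)
            - gl(n)
            + gl(n - k + 1.0)
            - gl(n - k - b + 2.0)
            + np.log(k * (k - 1.0))
        )
    return np.where(k <= n - b + 1.0, out, -np.inf)


def approx_spectrum(n: int, N0: float, r: float, mu: float = 1.0) -> ExpectedSpectrum:
    """Expected allele-frequency spectrum built from the approximate
    interval means; p_nb by normalization (the coefficient identity
    sum_b f_nb = mu * sum_k k E(S_k) gives the exact total)."""
    if mu <= 0:
        raise ValueError("mutation intensity mu must be positive")
    es = approx_interval_means(n, N0, r)
    logc = spectrum_coefficient_log(n, np.arange(1, n))
    f = mu * np.exp(logc) @ es
    k = np.arange(2.0, n + 1)
    total = mu * np.sum(k * es)
    return ExpectedSpectrum(n=n, mu=mu, f=f, p=f / total)


def relative_error_report(
    n: int,
    model: PopulationHistory,
    quantities: Sequence[str] = ("ETMRCA", "ETLBT"),
    k_values: Optional[Sequence[int]] = None,
) -> list:
    """Pair each requested approximation with its exact counterpart.

    ``quantities`` may contain ``ETMRCA``, ``ETLBT``, ``E(T_k)`` (uses
    ``k_values``) and ``f_nb`` (max relative error over the spectrum).
    """
    if model.kind != "exponential":
        raise ValueError("approximations are defined for exponential histories")
    N0, r, rho = model.N0, model.r, model.rho
    e_j = first_coalescence_means(model, n)
    reports = []
    for q in quantities:
        if q == "ETMRCA":
            reports.append(
                ErrorReport(q, n, rho, etmrca_stable(model, n, e_j), approx_etmrca(n, N0, r))
            )
        elif q == "ETLBT":
            reports.append(
                ErrorReport(q, n, rho, etlbt_stable(model, n, e_j), approx_etlbt(n, N0, r))
            )
        elif q == "E(T_k)":
            if not k_values:
                raise ValueError("E(T_k) report needs k_values")
            from .exact_expectations import expected_times_smalln

            exact = expected_times_smalln(model, n)
            for k in k_values:
                reports.append(
                    ErrorReport(
                        f"E(T_{k})",
                        n,
                        rho,
                        float(exact.et_k[k - 2]),
                        float(approx_expected_time(n, k, N0, r)),
                    )
                )
        elif q == "f_nb":
            ex = expected_spectrum(model, n)
            apx = approx_spectrum(n, N0, r)
            worst = int(np.argmax(np.abs(apx.f - ex.f) / ex.f))
            reports.append(
                ErrorReport(
                    f"f_nb (worst b={worst + 1})",
                    n,
                    rho,
                    float(ex.f[worst]),
                    float(apx.f[worst]),
                )
            )
        else:
            raise ValueError(f"unknown quantity {q!r}")
    return reports


def roundoff_error_bound(
    n: int,
    model: PopulationHistory,
    sigma: float,
    replicates: int = 1,
    seed: int = 0,
) -> float:
    """Conservative upper bound on the maximum relative round-off error of
    the spectrum recursion.

    Each first-coalescence mean e_j is corrupted by multiplicative Gaussian
    noise of relative standard deviation ``sigma`` (one or two orders above
    the true round-off level of the e_j evaluation); the whole spectrum is
    recomputed and the maximum over b of |f^(sigma) - f| / f, maximized
    over replicates, is returned.  Streamed over the recursion index so no
    O(n^2) matrix is stored; usable for n into the hundreds of thousands.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ej = first_coalescence_means(model, n)
    ejp = ej * (1.0 + sigma * rng.standard_normal((replicates, n - 1)))
    b = np.arange(1.0, n)
    nb2 = n - 2.0 * b
    f = np.zeros(n - 1)
    fp = np.zeros((replicates, n - 1))
    w_prev2 = np.full(n - 1, 6.0 / (n + 1.0))
    f += w_prev2 * ej[0]
    fp += w_prev2[None, :] * ejp[:, 0][:, None]
    w_prev1 = 30.0 * nb2 / ((n + 1.0) * (n + 2.0))
    f += w_prev1 * ej[1]
    fp += w_prev1[None, :] * ejp[:, 1][:, None]
    for j in range(2, n - 1):
        a1 = -(1.0 + j) * (3.0 + 2 * j) * (n - j) / (j * (2 * j - 1.0) * (n + j + 1.0))
        a2 = (3.0 + 2 * j) / (j * (n + j + 1.0))
        w = a1 * w_prev2 + (a2 * nb2) * w_prev1
        f += w * ej[j]
        fp += w[None, :] * ejp[:, j][:, None]
        w_prev2, w_prev1 = w_prev1, w
    return float(np.max(np.abs(fp - f[None, :]) / np.abs(f[None, :])))
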