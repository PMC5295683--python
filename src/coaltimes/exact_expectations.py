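"""Numerically stable exact coalescent expectations for large samples.

The classical route to E(T_k) — partial-fraction expansion of the product of
Lorentzian factors — produces coefficients with huge alternating magnitudes
and is unusable beyond n of about 50.  The hypergeometric-summation route
gives alternative expansions of ETMRCA, ETLBT and the expected allele
frequency spectrum f_nb directly in the first-coalescence means e_j:

    ETMRCA = sum_{j=2}^n  c_jn * (-1)^j * e_j,
    ETLBT  = sum_{j=2}^n  c_jn * (1 + (-1)^j) * e_j,
    f_nb   = mu * sum_{j=2}^n W_bjn * e_j,

with c_jn = (2j-1) n! (n-1)! / ((n+j-1)! (n-j)!) and the W coefficients
generated by a three-term recursion.  Evaluated with term-ratio updates
(never raw factorials) these sums stay stable into the hundreds of
thousands of lineages.

The classical small-n path (`expected_times_smalln`) is retained, guarded
at n <= 50, because it yields per-k expectations E(T_k), E(S_k) and serves
as an independent oracle for the stable formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .popmodels import PopulationHistory, binom2, first_coalescence_means

__all__ = [
    "CoalescentExpectations",
    "ExpectedSpectrum",
    "etmrca_stable",
    "etlbt_stable",
    "w_coefficients",
    "expected_spectrum",
    "expected_times_smalln",
    "partial_fraction_coefficients",
    "stable_sum_coefficients",
]

SMALL_N_LIMIT = 50


@dataclass
class CoalescentExpectations:
    """Expected times for one scenario: per-j first-coalescence means e_j
    (j = 2..n), ETMRCA and ETLBT; the small-n path also fills per-k
    E(T_k) and E(S_k) (k = 2..n)."""

    n: int
    scenario: PopulationHistory
    e_j: np.ndarray
    etmrca: float
    etlbt: float
    et_k: Optional[np.ndarray] = None
    es_k: Optional[np.ndarray] = None


@dataclass
class ExpectedSpectrum:
    """Expected allele-frequency spectrum: f[b-1] = f_nb is the expected
    number of segregating sites with b mutant copies among n sequences,
    p[b-1] = p_nb the probability that a random segregating site is of
    class b (f_nb normalized by mu*ETLBT)."""

    n: int
    mu: float
    f: np.ndarray
    p: np.ndarray


def stable_sum_coefficients(n: int) -> np.ndarray:
    """Coefficients c_jn = (2j-1) n!(n-1)!/((n+j-1)!(n-j)!) for j = 2..n,
    accumulated multiplicatively so no factorial is ever formed."""
    if n < 2:
        raise ValueError("n must be >= 2")
    c = np.empty(n - 1)
    c[0] = 3.0 * (n - 1) / (n + 1)
    if n > 2:
        j = np.arange(2, n, dtype=float)
        ratio = (2 * j + 1) / (2 * j - 1) * (n - j) / (n + j)
        c[1:] = c[0] * np.cumprod(ratio)
    return c


def etmrca_stable(model: PopulationHistory, n: int, e_j: np.ndarray = None) -> float:
    """Expected time to the most recent common ancestor, stable for large n.

    ``e_j`` may be supplied to avoid recomputing the first-coalescence means.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if e_j is None:
        e_j = first_coalescence_means(model, n)
    j = np.arange(2, n + 1)
    signs = np.where(j % 2 == 0, 1.0, -1.0)
    val = float(np.sum(stable_sum_coefficients(n) * signs * e_j))
    if not np.isfinite(val) or val <= 0:
        raise ArithmeticError(f"ETMRCA sum lost stability at n={n}: {val}")
    return val


def etlbt_stable(model: PopulationHistory, n: int, e_j: np.ndarray = None) -> float:
    """Expected total length of branches in the tree, stable for large n.
    Odd-j terms vanish through the (1 + (-1)^j) factor."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if e_j is None:
        e_j = first_coalescence_means(model, n)
    j = np.arange(2, n + 1)
    even = np.where(j % 2 == 0, 2.0, 0.0)
    val = float(np.sum(stable_sum_coefficients(n) * even * e_j))
    if not np.isfinite(val) or val <= 0:
        raise ArithmeticError(f"ETLBT sum lost stability at n={n}: {val}")
    return val


def w_matrix(n: int, b_values: np.ndarray) -> np.ndarray:
    """W coefficients for the spectrum expansion, shape (n-1, len(b_values));
    row i holds W_{b, j=i+2, n} for every requested allele class b.

    Seeds: W_b2n = 6/(n+1) and W_b3n = 30(n-2b)/((n+1)(n+2)); the three-term
    recursion then advances j = 2..n-2.  (The 6/(n+1) reading of the first
    seed is the one consistent with dimensional analysis and with the exact
    constant-size 1/b spectrum; it is pinned by tests.)
    """
    if n < 3:
        raise ValueError("spectrum recursion needs n >= 3")
    b = np.asarray(b_values, dtype=float)
    if np.any((b < 1) | (b > n - 1)):
        raise ValueError("allele class b must satisfy 1 <= b <= n-1")
    W = np.empty((n - 1, b.size))
    W[0] = 6.0 / (n + 1)
    W[1] = 30.0 * (n - 2 * b) / ((n + 1.0) * (n + 2.0))
    for j in range(2, n - 1):
        a1 = -(1.0 + j) * (3.0 + 2 * j) * (n - j) / (j * (2 * j - 1.0) * (n + j + 1.0))
        a2 = (3.0 + 2 * j) * (n - 2 * b) / (j * (n + j + 1.0))
        W[j] = a1 * W[j - 2] + a2 * W[j - 1]
    return W


def w_coefficients(n: int, b: int) -> np.ndarray:
    """W_bjn for j = 2..n for a single allele class b (1 <= b <= n-1)."""
    return w_matrix(n, np.array([b]))[:, 0]


def expected_spectrum(
    model: PopulationHistory, n: int, mu: float = 1.0
) -> ExpectedSpectrum:
    """Expected allele-frequency spectrum f_nb (b = 1..n-1) and the
    normalized site-class probabilities p_nb, O(n^2) overall."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if mu <= 0:
        raise ValueError("mutation intensity mu must be positive")
    e_j = first_coalescence_means(model, n)
    if n == 2:
        f = np.array([2.0 * mu * e_j[0]])
        return ExpectedSpectrum(n=n, mu=mu, f=f, p=np.array([1.0]))
    W = w_matrix(n, np.arange(1, n))
    f = mu * (W.T @ e_j)
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f))[0]) + 1
        raise ArithmeticError(
            f"numerical-stability failure in spectrum at (n={n}, b={bad})"
        )
    total = f.sum()
    return ExpectedSpectrum(n=n, mu=mu, f=f, p=f / total)


def partial_fraction_coefficients(n: int, k: int) -> np.ndarray:
    """Coefficients A_jkn (j = k..n) of the expansion of the T_k density as
    a signed mixture of first-coalescence densities:

        A_jkn = prod_{l=k..n, l!=j} lambda_l / (lambda_l - lambda_j),

    with lambda_m = C(m,2).  Magnitudes diverge rapidly with n (alternating
    signs), hence the small-n guard in callers.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    lam = binom2(np.arange(k, n + 1, dtype=float))
    A = np.empty(lam.size)
    for i in range(lam.size):
        others = np.delete(lam, i)
        A[i] = np.prod(others / (others - lam[i]))
    return A


def expected_times_smalln(model: PopulationHistory, n: int) -> CoalescentExpectations:
    """Per-k expected coalescence times via the classical partial-fraction
    route: E(T_k) = sum_j A_jkn e_j, E(S_k) = E(T_k) - E(T_{k+1}).

    Guarded at n <= 50 because the A coefficients blow up beyond that; use
    the stable sums or transform inversion for larger samples.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n > SMALL_N_LIMIT:
        raise ValueError(
            f"partial-fraction coefficients are unstable for n > {SMALL_N_LIMIT}; "
            "use etmrca_stable/etlbt_stable or the transform-inversion densities"
        )
    e_j = first_coalescence_means(model, n)
    et_k = np.empty(n - 1)  # index k-2, k = 2..n
    for k in range(2, n + 1):
        A = partial_fraction_coefficients(n, k)
        et_k[k - 2] = np.sum(A * e_j[k - 2 :])
    es_k = et_k.copy()
    es_k[:-1] -= et_k[1:]  # E(S_n) = E(T_n)
    etmrca = float(et_k[0])
    etlbt = float(et_k[0] + np.sum(et_k))
    return CoalescentExpectations(
        n=n, scenario=model, e_j=e_j, etmrca=etmrca, etlbt=etlbt, et_k=et_k, es_k=es_k
    )
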