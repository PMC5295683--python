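"""Maximum-likelihood fitting of the exponential-growth product parameter
rho = r*N0 to an observed site-frequency spectrum.

Under the infinite-sites model with per-site mutation intensity mu -> 0,
the probability that a randomly chosen segregating site carries b mutant
copies among n sequences is p_nb = f_nb / (mu * ETLBT), a quantity that
depends on the demography only through rho (mu and N0 cancel in the
ratio).  Treating each segregating site as an independent SNP, the
log-likelihood of a spectrum {c_b} is the multinomial kernel

    l(rho) = sum_b c_b * ln p(b | n, rho),

maximized here over a log-spaced rho grid followed by bounded local
refinement.  Two backends supply the expected spectrum: ``exact`` (the
stable W-coefficient recursion with exact first-coalescence means) and
``approx`` (closed-form large-sample expected times differenced into
interval means).

The packaged fixture ``mtdb_table2.tsv`` carries the mtDB human
mitochondrial spectrum (n = 2704 sequences, 3213 diallelic segregating
sites, rare-allele counts, treated as folded).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from . import exact_expectations as ee
from . import approximations as ap
from .popmodels import PopulationHistory, first_coalescence_means

__all__ = [
    "SiteFrequencySpectrum",
    "read_sfs",
    "write_sfs",
    "load_mtdb_spectrum",
    "SpectrumModel",
    "site_class_probability",
    "log_likelihood",
    "FitResult",
    "fit_exponential_growth",
    "bootstrap_ci",
]

# internal reference size used when only rho is specified; p_nb is
# invariant to this choice (checked by tests)
_REFERENCE_N0 = 1e4


@dataclass
class SiteFrequencySpectrum:
    """An observed spectrum: allele classes b with site counts c_b >= 0.

    ``folded`` means counts are by minor ("rare") allele copy number, so
    all b <= floor(n/2).
    """

    n: int
    b: np.ndarray
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.b.size != self.counts.size:
            raise ValueError("b and counts must have equal length")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("site counts must be non-negative integers")
        hi = self.n // 2 if self.folded else self.n - 1
        if np.any((self.b < 1) | (self.b > hi)):
            raise ValueError(
                f"allele classes must lie in 1..{hi} for "
                f"{'folded' if self.folded else 'unfolded'} spectra with n={self.n}"
            )
        if np.unique(self.b).size != self.b.size:
            raise ValueError("duplicate allele classes")

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum())


def read_sfs(path) -> SiteFrequencySpectrum:
    """Read a spectrum from TSV: '#'-prefixed metadata lines carrying
    ``n=`` and ``folded=``, then rows ``b<TAB>count``."""
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].replace(",", " ").split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'b<TAB>count'")
            try:
                b = int(parts[0])
                c = int(parts[1])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer field") from err
            rows.append((b, c))
    if "n" not in meta:
        raise ValueError(f"{path}: missing '# n=<int>' metadata line")
    n = int(meta["n"])
    folded = str(meta.get("folded", "false")).lower() in ("true", "1", "yes")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    b, c = zip(*rows)
    try:
        return SiteFrequencySpectrum(n=n, b=np.array(b), counts=np.array(c), folded=folded)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_sfs(sfs: SiteFrequencySpectrum, path) -> None:
    """Write a spectrum in the TSV format read by :func:`read_sfs`."""
    frame = pd.DataFrame({"b": sfs.b, "count": sfs.counts.astype(int)})
    with open(path, "w") as fh:
        fh.write(f"# n={sfs.n} folded={str(sfs.folded).lower()}\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def load_mtdb_spectrum() -> SiteFrequencySpectrum:
    """The packaged human mtDNA spectrum (n = 2704, 3213 segregating
    sites, rare-allele counts; folded)."""
    ref = importlib.resources.files("coaltimes").joinpath("data/mtdb_table2.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_sfs(path)


class SpectrumModel:
    """Cached expected-spectrum machinery for one (n, backend) pair.

    Precomputes the rho-independent coefficient matrix once (the W
    recursion for the exact backend, log coefficients linking E(S_k) to
    f_nb for the approximate one) and caches the full class-probability
    vector per rho, so repeated likelihood evaluations — grid scans,
    refinements, bootstrap refits — cost one O(n) means evaluation and one
    matrix-vector product each.
    """

    def __init__(self, n: int, backend: str = "exact"):
        if backend not in ("exact", "approx"):
            raise ValueError("backend must be 'exact' or 'approx'")
        if n < 3:
            raise ValueError("n must be >= 3")
        self.n = n
        self.backend = backend
        self._cache: dict = {}
        if backend == "exact":
            self._W = ee.w_matrix(n, np.arange(1, n)).T  # (b, j)
        else:
            self._C = np.exp(ap.spectrum_coefficient_log(n, np.arange(1, n)))  # (b, k)

    def probabilities(self, rho: float) -> np.ndarray:
        """p_nb for b = 1..n-1 at the given rho (unfolded)."""
        key = float(rho)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = self.n
        if self.backend == "exact":
            if rho == 0.0:
                model = PopulationHistory.constant(_REFERENCE_N0)
            else:
                model = PopulationHistory.exponential(_REFERENCE_N0, rho=rho)
            e_j = first_coalescence_means(model, n)
            f = self._W @ e_j
            total = ee.etlbt_stable(model, n, e_j)
        else:
            if rho == 0.0:
                et = ap.approx_expected_time(n, np.arange(2, n + 1), _REFERENCE_N0, 0.0)
                es = et.copy()
                es[:-1] -= et[1:]
            else:
                es = ap.approx_interval_means(n, _REFERENCE_N0, rho / _REFERENCE_N0)
            f = self._C @ es
            total = float(np.sum(np.arange(2.0, n + 1) * es))
        p = f / total
        self._cache[key] = p
        return p

    def class_probabilities(self, sfs: SiteFrequencySpectrum, rho: float) -> np.ndarray:
        """Probabilities of the observed classes; folded classes combine
        p_nb + p_{n,n-b} (b < n/2) or keep p_{n,n/2} alone."""
        p = self.probabilities(rho)
        n = self.n
        if not sfs.folded:
            return p[sfs.b - 1]
        out = p[sfs.b - 1].copy()
        partner = n - sfs.b
        out[partner != sfs.b] += p[partner[partner != sfs.b] - 1]
        return out


def site_class_probability(
    n: int, b: int, rho: float, folded: bool = False, backend: str = "exact"
) -> float:
    """Probability that a random segregating site falls in class b."""
    model = SpectrumModel(n, backend)
    p = model.probabilities(rho)
    if not folded:
        return float(p[b - 1])
    if b > n // 2:
        raise ValueError("folded class must satisfy b <= n/2")
    if 2 * b == n:
        return float(p[b - 1])
    return float(p[b - 1] + p[n - b - 1])


def log_likelihood(
    sfs: SiteFrequencySpectrum,
    rho: float,
    backend: str = "exact",
    model: Optional[SpectrumModel] = None,
) -> float:
    """Multinomial log-likelihood kernel sum_b c_b ln p(b | n, rho)."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if model is None:
        model = SpectrumModel(sfs.n, backend)
    p = model.class_probabilities(sfs, rho)
    if np.any((p <= 0) & (sfs.counts > 0)):
        warnings.warn(f"zero class probability at rho={rho}; log-likelihood is -inf")
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(np.sum(sfs.counts * np.log(p)))


@dataclass
class FitResult:
    """Grid log-likelihood curve and the refined ML estimate."""

    rho_grid: np.ndarray
    loglik: np.ndarray
    rho_hat: float
    backend: str
    loglik_hat: float = field(default=np.nan)
    ci: Optional[Tuple[float, float]] = None


def fit_exponential_growth(
    sfs: SiteFrequencySpectrum,
    rho_min: float = 50.0,
    rho_max: float = 1000.0,
    grid_points: int = 60,
    backend: str = "exact",
    *,
    model: Optional[SpectrumModel] = None,
    refine_tol: float = 0.05,
) -> FitResult:
    """ML fit of rho: log-spaced coarse grid scan, then bounded scalar
    refinement around the grid argmax to a tolerance of ``refine_tol``."""
    if not 0 <= rho_min < rho_max:
        raise ValueError("need 0 <= rho_min < rho_max")
    if grid_points < 10:
        raise ValueError("grid_points must be >= 10")
    if model is None:
        model = SpectrumModel(sfs.n, backend)
    lo = max(rho_min, 1e-6)
    grid = np.geomspace(lo, rho_max, grid_points)
    if rho_min == 0.0:
        grid = np.concatenate([[0.0], grid])
    ll = np.array([log_likelihood(sfs, r, backend, model) for r in grid])
    i = int(np.argmax(ll))
    if i in (0, len(grid) - 1):
        warnings.warn(
            f"log-likelihood argmax at the grid boundary (rho={grid[i]:.3g}); "
            "consider widening [rho_min, rho_max]"
        )
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, len(grid) - 1)]
    else:
        lo_b, hi_b = grid[i - 1], grid[i + 1]
    if hi_b > lo_b:
        res = optimize.minimize_scalar(
            lambda r: -log_likelihood(sfs, r, backend, model),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": refine_tol},
        )
        rho_hat, ll_hat = float(res.x), float(-res.fun)
        if ll[i] > ll_hat:  # refinement should never lose to the grid
            rho_hat, ll_hat = float(grid[i]), float(ll[i])
    else:
        rho_hat, ll_hat = float(grid[i]), float(ll[i])
    return FitResult(grid, ll, rho_hat, backend, ll_hat)


def bootstrap_ci(
    sfs: SiteFrequencySpectrum,
    rho_hat: float,
    replicates: int = 200,
    seed: int = 0,
    level: float = 0.95,
    backend: str = "exact",
    *,
    rho_min: float = 50.0,
    rho_max: float = 1000.0,
    grid_points: int = 40,
) -> Tuple[float, float]:
    """Parametric-bootstrap confidence interval for rho.

    Simulates ``replicates`` spectra of ``sfs.total_sites`` sites at
    rho_hat with the package's own coalescent simulator, refits each with
    a shared spectrum cache, and returns the empirical quantiles of the
    refitted estimates.  Aborts if more than 5% of refits fail.
    """
    from .simulate import simulate_sfs

    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    model = PopulationHistory.exponential(_REFERENCE_N0, rho=rho_hat)
    cache = SpectrumModel(sfs.n, backend)
    estimates = []
    failures = 0
    for _ in range(replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        rep = simulate_sfs(
            sfs.n, model, sfs.total_sites, folded=sfs.folded, seed=rep_seed
        )
        try:
            fit = fit_exponential_growth(
                rep, rho_min, rho_max, grid_points, backend,
                model=cache, refine_tol=0.5,
            )
            estimates.append(fit.rho_hat)
        except (ValueError, ArithmeticError):
            failures += 1
    if failures > 0.05 * replicates:
        raise RuntimeError(
            f"{failures}/{replicates} bootstrap refits failed; aborting"
        )
    if failures:
        warnings.warn(f"{failures}/{replicates} bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lower), float(upper)
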