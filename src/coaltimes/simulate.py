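"""Coalescent simulation of genealogy times and site-frequency spectra
under an arbitrary deterministic size history.

Times are drawn by the time-scale construction: on the tau scale the
inter-coalescence intervals are independent exponentials with rates
C(k,2), so cumulated tau-scale coalescence times mapped through the
inverse time-scale change g^{-1} have exactly the joint law of the
coalescence times under N(t).

Site classes are drawn without building tree topologies.  A mutation
falling uniformly on the branches of an exchangeable coalescent tree
while k ancestral lineages exist subtends b of the n leaves with
probability C(n-b-1, k-2) / C(n-1, k-1) — the first-part law of a uniform
composition of n into k parts.  Sampling therefore proceeds in two steps:
pick the level k with probability proportional to its total branch length
k*S_k (pooled across genealogies, which length-biases trees exactly as a
Poisson mutation process does), then draw b from the composition law by
inverse-CDF lookup.  Aggregated class frequencies converge to the
expected site-class probabilities p_nb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .popmodels import PopulationHistory, binom2, inverse_time_scale
from .sfs_inference import SiteFrequencySpectrum

__all__ = [
    "SimulatedGenealogy",
    "simulate_times",
    "sample_coalescence_times",
    "simulate_sfs",
]


@dataclass
class SimulatedGenealogy:
    """One realized genealogy: coalescence times t_k and intervals s_k
    for k = n..2 (arrays ordered by descending k, i.e. increasing time
    toward the past); tmrca = t_2 and tlbt = sum_k k*s_k."""

    n: int
    scenario: PopulationHistory
    t_k: np.ndarray
    s_k: np.ndarray
    seed: int

    @property
    def tmrca(self) -> float:
        return float(self.t_k[-1])

    @property
    def tlbt(self) -> float:
        k = np.arange(self.n, 1, -1)
        return float(np.sum(k * self.s_k))


def sample_coalescence_times(
    n: int, model: PopulationHistory, reps: int, seed: int = 0
) -> np.ndarray:
    """Vectorized draws of coalescence times: array (reps, n-1) whose
    column i holds t_{n-i} (k descending n..2, times increasing)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n, 1, -1, dtype=float)
    rates = binom2(k)
    s_tau = rng.exponential(1.0, size=(reps, n - 1)) / rates
    tau = np.cumsum(s_tau, axis=1)
    if model.kind in ("constant", "exponential"):
        return inverse_time_scale(model, tau)
    out = np.empty_like(tau)
    for i in range(reps):
        out[i] = inverse_time_scale(model, tau[i])
    return out


def simulate_times(n: int, model: PopulationHistory, seed: int = 0) -> SimulatedGenealogy:
    """Draw one genealogy; reproducible under a fixed seed."""
    t = sample_coalescence_times(n, model, 1, seed)[0]
    s = np.diff(np.concatenate([[0.0], t]))
    return SimulatedGenealogy(n=n, scenario=model, t_k=t, s_k=s, seed=seed)


def _composition_first_part_cdf(n: int, k: int) -> np.ndarray:
    """CDF of the subtree size b subtended by a mutation at level k:
    P(B <= b) = 1 - C(n-1-b, k-1)/C(n-1, k-1), b = 1..n-k+1."""
    b = np.arange(1.0, n - k + 2)
    gl = special.gammaln
    with np.errstate(invalid="ignore"):
        log_s = gl(n - b) - gl(n - b - k + 1.0) - gl(float(n)) + gl(float(n - k + 1))
    surv = np.exp(log_s)
    surv[-1] = 0.0  # exact: no subtree can exceed n-k+1 leaves
    return 1.0 - surv


def simulate_sfs(
    n: int,
    model: PopulationHistory,
    n_sites: int,
    folded: bool = False,
    seed: int = 0,
) -> SiteFrequencySpectrum:
    """Simulate a site-frequency spectrum of ``n_sites`` segregating sites
    under the infinite-sites model.

    One genealogy is drawn per site; each site picks its level k with
    probability proportional to branch length k*s_k pooled over all
    genealogies (the length-biasing of a Poisson mutation process), then
    its class b from the exchangeable subtree-size law.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    # genealogy intervals, chunked so memory stays bounded for huge draws
    chunk = max(1, min(n_sites, int(2e7) // max(n - 1, 1)))
    levels = np.empty(n_sites, dtype=int)
    filled = 0
    k_desc = np.arange(n, 1, -1, dtype=float)
    rates = binom2(k_desc)
    while filled < n_sites:
        m = min(chunk, n_sites - filled)
        s_tau = rng.exponential(1.0, size=(m, n - 1)) / rates
        tau = np.cumsum(s_tau, axis=1)
        t = inverse_time_scale(model, tau) if model.kind != "general" else np.vstack(
            [inverse_time_scale(model, row) for row in tau]
        )
        s = np.diff(np.concatenate([np.zeros((m, 1)), t], axis=1), axis=1)
        w = k_desc * s  # branch length at each level
        # pooled length-biased choice of (genealogy, level); one site is
        # assigned per pooled genealogy batch of equal size
        flat = (w / w.sum()).ravel()
        idx = rng.choice(flat.size, size=m, p=flat)
        levels[filled : filled + m] = n - (idx % (n - 1))
        filled += m
    # draw subtree sizes per distinct level via inverse CDF
    b_out = np.empty(n_sites, dtype=int)
    for k in np.unique(levels):
        mask = levels == k
        cdf = _composition_first_part_cdf(n, int(k))
        u = rng.random(int(mask.sum()))
        b_out[mask] = np.searchsorted(cdf, u, side="right") + 1
    if folded:
        b_out = np.minimum(b_out, n - b_out)
    classes, counts = np.unique(b_out, return_counts=True)
    return SiteFrequencySpectrum(
        n=n, b=classes, counts=counts.astype(float), folded=folded
    )
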