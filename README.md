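# coaltimes

Coalescence-time densities, expectations and allele-frequency spectra
for large samples drawn from populations of time-varying size — and
maximum-likelihood inference of exponential growth from an observed
site-frequency spectrum.

## Who this is for

Population geneticists and methods developers who need *exact*
coalescent quantities at modern sample sizes (thousands to hundreds of
thousands of sequences), where the classical partial-fraction formulas
explode numerically, and simulation-based estimates are too noisy to
measure the accuracy of closed-form approximations.

## What it computes

For a sample of `n` sequences from a population with deterministic size
history `N(t)` (constant, exponential `N0·e^{-rt}`, or arbitrary):

* **Marginal densities of coalescence times `T_k`**, for any `n`, by
  inverting the time-scaled transform.  On the coalescent time scale
  `τ = g(t) = ∫₀ᵗ dσ/N(σ)` the transform of `T_k` is the Lorentzian
  product `P(s) = ∏_{j=k}^{n} C(j,2)/(s + C(j,2))`, and

  `π_{T_k}(t) = 1/N(t) · (1/π) ∫₀^∞ Re[P(iω) e^{iωg(t)}] dω`,

  evaluated by adaptive Gauss–Kronrod quadrature or an inverse FFT.
* **The limit density of TMRCA** as `n → ∞`, from the closed-form limit
  transform `2πiω / cos(π√(¼ − 2iω))`.
* **Numerically stable expectations** — ETMRCA, expected total branch
  length, and the expected spectrum `f_nb = μ Σ_j W_bjn e_j` — valid for
  `n` into the hundreds of thousands (term-ratio accumulation, scaled
  exponential integrals, three-term `W` recursion).
* **Closed-form large-sample approximations** of expected times and
  spectra, with exact relative-error reports.
* **Maximum-likelihood fitting of `ρ = r·N0`** to a site-frequency
  spectrum via the multinomial kernel `Σ_b c_b ln p(b | n, ρ)`, with
  parametric-bootstrap confidence intervals driven by the built-in
  coalescent simulator.  The human mtDNA spectrum (n = 2704, 3213
  segregating sites) ships as a packaged dataset.

## Worked example

```python
from coaltimes import (PopulationHistory, invert_density_quadrature,
                       density_moments, fit_exponential_growth,
                       load_mtdb_spectrum)

# density of T_6 for n = 800 under growth (N0 = 2e6, r = 0.001)
model = PopulationHistory.exponential(2e6, r=0.001)
grid = invert_density_quadrature(800, 6, model)
mean, sd, skew = density_moments(grid)
print(f"{mean:.3f} {sd:.3f} {skew:.4f}")

# growth fit to the packaged mtDNA spectrum
fit = fit_exponential_growth(load_mtdb_spectrum(), 50, 1000, 60, "exact")
print(f"{fit.rho_hat:.1f}")
```

prints

```
6647.881 250.590 0.1239
339.2
```

The first line says the sixth coalescence time of an 800-sequence
genealogy under this growth scenario averages ~6648 generations with a
standard deviation of ~251 and mild right skew (already nearly normal).
The second line is the maximum-likelihood growth product parameter for
the human mtDNA data: `ρ̂ ≈ 339` means the expansion signal in the
spectrum is strong — the corresponding closed-form-approximation backend
gives `ρ̂ ≈ 342`, and a 200-replicate parametric bootstrap (seed 1) puts
`297 < ρ < 405` around it.

The `examples/` directory holds one short narrative script per
capability (expected times, density inversion, the TMRCA limit, the
mtDNA fit, simulation + re-estimation); each prints the numbers it
computes and one line on what they mean.  A thin CLI mirrors the same
operations, e.g.

```bash
coaltimes expectations --n 800 --model exponential --N0 2e6 --r 0.001
coaltimes sfs-fit --sfs src/coaltimes/data/mtdb_table2.tsv --backend exact
```

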