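# Methods

## Model

`coaltimes` works with the retrospective coalescent of a sample of `n`
DNA sequences drawn from a panmictic population whose effective size `t`
generations before the present is a deterministic function `N(t)`.  Time
runs from the present into the past and is continuous (diffusion
approximation).  `T_k` denotes the time at which the genealogy first has
`k - 1` ancestral lineages, `S_k` the interval during which exactly `k`
lineages exist; `TMRCA = T_2` and the total branch length is
`TLBT = sum_k k*S_k = T_2 + sum_k T_k`.  Mutations follow a Poisson point
process on the branches under the infinite-sites model, so a segregating
site's allele class `b` (mutant copies among `n`) has expected count
`f_nb` and, in the small-mutation-rate limit, class probability
`p_nb = f_nb / (mu * E[TLBT])`.

Everything rests on the time-scale change
`tau = g(t) = int_0^t dsigma / N(sigma)`, which maps the variable-size
coalescent onto the standard constant-size one: on the `tau` scale the
intervals are independent exponentials with rates `C(k,2) = k(k-1)/2`.

Supported histories: constant `N0`; exponential growth
`N(t) = N0*exp(-r*t)` with product parameter `rho = r*N0` (`r = 0`
degenerates exactly to constant); and a general positive `size_fn` with
optional breakpoints.  `N0` is on the coalescent scale on which a pair of
lineages coalesces after `N0` generations on average; no diploid `2N`
convention is applied anywhere.  Whether `N0` should be read as haploid
or diploid census size is left to the user's organism and ploidy.

## Transform inversion

The Laplace-type transform of the `T_k` marginal with respect to `tau`
is a finite product of Lorentzian factors
`P(s) = prod_{j=k}^n C(j,2)/(s + C(j,2))` — `T_k` is hypoexponential on
the `tau` scale.  Densities follow by Fourier inversion along `s = i*w`
and the change of variables back to natural time with Jacobian `1/N(t)`.
Numerical choices:

* **Quadrature path** (`invert_density_quadrature`): adaptive
  Gauss–Kronrod integration (`scipy.integrate.quad_vec`) of
  `Re[P(iw) e^{iw tau}]` over `[0, Omega]`, using conjugate symmetry.
  `Omega` is found by doubling until `|P(i*Omega)| < 1e-13`; the product
  is evaluated as a sum of complex logs so it never under- or overflows.
  Target relative accuracy ~1e-5 or better.  For `k = n` the transform
  has a single factor whose slow `1/w` decay makes quadrature wasteful,
  so the analytic first-coalescence density is returned.
* **FFT path** (`invert_density_fft`): inverse FFT of `P(iw)` on a
  uniform `tau` grid of default 1024 points spanning
  `[0, mean + 12*sd]`, the moments being the exact hypoexponential
  closed forms; the 12-sd margin absorbs right-tail skewness.  If mass
  at the grid boundary exceeds 1e-6 the range and grid are doubled with
  a warning (aliasing guard).  Moment accuracy is ~1e-4 (constant) to
  ~1e-3 (strong growth) at the default grid, per the package's own
  cross-checks.
* **Classical path** (`marginal_density_partial_fraction`): the signed
  mixture `sum_j A_jkn q_j(t)` with partial-fraction coefficients
  `A_jkn = prod_{l != j} lambda_l/(lambda_l - lambda_j)`,
  `lambda_m = C(m,2)`.  The coefficients grow combinatorially with
  alternating signs, so this path is guarded at `n <= 50` and serves as
  the small-`n` oracle.  Near `n = 50` its own floating-point noise
  reaches percents of the density mid-tree; tests that use it as an
  oracle bound that noise explicitly by `eps * sum_j |A_jkn| q_j(t)`.
* **Default time grids**: uniform in `tau` over
  `[mean - 12*sd, mean + 30*sd]` (clipped at 0, 3000 points), mapped
  through `g^{-1}`.  The right margin is generous because the `tau`-scale
  tail decays at rate `C(k,2)`, which can be as slow as one `sd` per
  unit of tail for `k` near `n`; 30 sd leaves <1e-13 of mass outside the
  grid in the worst (single-exponential) case.  Moments use Simpson
  integration on the (generally non-uniform) natural-time grid.
* **Negative ringing**: inversion output may dip slightly below zero;
  values are clipped to zero after the normalization check, never
  before.  The warning threshold is 1e-9 of the peak for quadrature and
  1e-4 for FFT/classical output, matching each path's intrinsic noise.

The limit transform of TMRCA as `n -> infinity` is the closed form
`2*pi*i*w / cos(pi*sqrt(1/4 - 2*i*w))` (an infinite product summed by a
gamma-quotient identity), inverted by quadrature with principal branches
of the complex square root and cosine; the removable `w = 0` singularity
is set to its analytic value 1.  The branch convention was verified by
convergence of finite partial products.  An FFT route is deliberately
not offered for the limit kernel: its slow algebraic onset at small `w`
combined with the `exp(-pi*sqrt(w))` tail makes aliasing control
unreliable.

## Stable exact expectations

Per-`k` expectations via partial fractions share the classical path's
instability, so large-`n` expectations use the alternating
hypergeometric-summation forms in the first-coalescence means `e_j`:
`ETMRCA` and `ETLBT` with coefficients
`c_jn = (2j-1) n!(n-1)!/((n+j-1)!(n-j)!)` accumulated by term ratios
(`c_2 = 3(n-1)/(n+1)`, `c_{j+1}/c_j = (2j+1)(n-j)/((2j-1)(n+j))`), so no
factorial is ever formed; and the expected spectrum
`f_nb = mu * sum_j W_bjn e_j` with the `W` three-term recursion seeded by
`W_b2n = 6/(n+1)` and `W_b3n = 30(n-2b)/((n+1)(n+2))`.  The first seed
sometimes circulates in a typographically flattened form that can be
misread as `6*(n+1)`; the `6/(n+1)` reading is fixed here because it
alone is dimensionally consistent with the second seed and reproduces
the constant-size `f_nb = 2*mu*N0/b` spectrum to machine precision (the
alternative is off by a factor of order `n^2`).  A perturbation study (`roundoff_error_bound`)
corrupts the `e_j` with multiplicative Gaussian noise (sd `sigma`,
deliberately one to two orders above the true evaluation error of the
`e_j`) and recomputes the spectrum, giving a conservative bound on
round-off amplification; at `sigma = 1e-13` the bound stays below 1e-6
for `n` to 1e5, so the recursion is safe into the hundreds of thousands.

For exponential growth the means have the closed form
`e_j = exp(beta) * E1(beta) / r` with `beta = C(j,2)/rho`.  `exp(beta)`
overflows for `beta` beyond ~700 while `E1` underflows, so the product is
computed as a single scaled exponential integral: directly via
`scipy.special.exp1` for `beta <= 30`, and by the classical continued
fraction (modified Lentz) beyond.  The crossover keeps both branches at
full double precision; tests pin agreement with an arbitrary-precision
evaluation to 1e-12 relative over `beta` in `[1e-6, 1e8]`.

`E(S_k)` is recovered from `E(T_k)` by differencing (`E(T_{n+1}) = 0`),
which is exact by definition rather than a separate formula.

## Large-sample approximations

The closed forms `E(T_k) ~ (1/r) ln[2 r N0 (1/(k-1) - 1/n) + 1]` and
`ETLBT ~ [2 n N0/(2 r N0 - n)] ln(2 r N0 / n)` come from the
deterministic limit of the lineage-count process.  The ETLBT expression
also circulates in a flattened, ambiguous typography; the reading used
here follows from integrating `m(tau) ~ n/(1 + n tau/2)` against
`N(t(tau))`, has the removable limit `2*N0` at `n = 2*rho`, and tracks
the exact path at 5e-4..5e-3 relative over `rho` in `[50, 1e4]`, `n` in
`[100, 1000]` — the naive flat parse is off by orders of magnitude.  Approximate spectra
substitute differenced approximate `E(T_k)` into the standard spectrum
formula, whose non-negative coefficients are evaluated through `gammaln`
(log-space, no cancellation); normalization uses the exact identity
`sum_b f_nb = mu * sum_k k E(S_k)`.

## Likelihood fitting

Treating each segregating site as an independent SNP, the log-likelihood
of a spectrum `{c_b}` is the multinomial kernel
`sum_b c_b ln p(b | n, rho)`.  The class probabilities depend on the
demography only through `rho` (both `mu` and `N0` cancel in
`f_nb / (mu*ETLBT)`), so the fit is one-dimensional: a log-spaced grid
scan (default 60 points) followed by bounded scalar refinement to
`delta rho = 0.05`, small enough that reported estimates are
grid-independent at the 0.1 level.  A `SpectrumModel` cache holds the
rho-independent coefficient matrix and the per-rho probability vectors,
which is what makes grid scans and bootstrap refits affordable
(one O(n) means evaluation plus one matrix–vector product per new rho).

The packaged mtDNA spectrum carries rare-allele (minor-allele) counts —
its largest class, 944, is below `n/2 = 1352` — and is therefore treated
as folded: class probabilities combine `p_nb + p_{n,n-b}`.  Fits of this
dataset are insensitive to the convention (folded and unfolded estimates
differ by ~0.1 in `rho_hat`); an unfolded override exists in the CLI.
Confidence intervals use a parametric bootstrap: spectra of the observed
size simulated at `rho_hat`, each refit with a shared cache (refinement
relaxed to 0.5, far below bootstrap noise); more than 5% refit failures
aborts.

## Simulator

Genealogy times are drawn exactly: independent exponentials on the `tau`
scale, cumulated and mapped through `g^{-1}` — this is the joint law of
the coalescence times under `N(t)`, not an approximation.  Site classes
are drawn without building topologies: a mutation landing while `k`
lineages exist subtends `b` leaves with probability
`C(n-b-1, k-2)/C(n-1, k-1)`, the first-part law of a uniform composition
of `n` into `k` parts, which is the same exchangeability fact the
spectrum formula rests on.  Each site gets its own genealogy; the level
`k` is chosen proportionally to branch length `k*S_k` pooled across the
per-site genealogies, reproducing the length-biasing of a Poisson
mutation process, and `b | k` is sampled by inverse CDF (log-binomial
survival function, `O(n)` per distinct level).  A single seeded
`numpy.random.Generator` drives all draws.

What the simulator emulates — and does not.  It produces exact
coalescence times and exchangeable site classes under the infinite-sites
model for any deterministic `N(t)`.  It does not model recombination,
population structure, selection, sequencing error or ascertainment, and
it returns class counts rather than sequences or tree topologies.
Passing recovery tests therefore validate the statistical machinery
under the model's own assumptions; they say nothing about robustness to
the ways real data violate them (linkage between mtDNA sites being the
obvious one for the packaged dataset — the multinomial likelihood treats
linked sites as independent, which narrows nominal intervals).

## Problem sizes used in the test suite

Golden checks invert densities at `n = 800` (18 scenario/`k` cells); the
mtDNA fit runs the full `n = 2704` likelihood; density-path
cross-validation uses `n` in {10, 50} over constant and `rho` in
{1, 10, 100}; simulator/inversion agreement uses 1e5 replicates at
`n = 50`; the round-off study runs one replicate at `n = 1e5`; bootstrap
checks use 100 replicates at `n` in {400, 500}.  These sizes were chosen
to exercise every large-`n` code path while keeping the default suite
runnable on a laptop in a few minutes.

## Known limitations

* General `N(t)` histories evaluate `e_j` and the time-scale change by
  per-point quadrature/bisection; expectations at `n` in the tens of
  thousands are fast only for constant/exponential histories.
* The FFT path's uniform-`tau` grid loses resolution in natural time
  under strong growth (the mapping is logarithmic); the quadrature path
  with freely placed points is the accurate fallback.
* Variances and covariances of coalescence times are available only
  numerically, through inverted densities; no closed-form second
  moments are provided.
* The likelihood fits a single exponential epoch; multi-epoch or
  non-parametric histories are out of scope.
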