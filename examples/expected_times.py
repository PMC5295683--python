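"""Expected coalescence times for a large sample under exponential growth.

Builds the growth scenario N(t) = N0*exp(-r*t) with N0 = 2e6 and
r = 0.001 per generation (product parameter rho = 2000), then computes
the expected time to the most recent common ancestor (ETMRCA) and the
expected total branch length (ETLBT) for n = 800 sequences with the
numerically stable large-n sums, alongside the closed-form large-sample
approximations.  The relative gaps illustrate the percent-level accuracy
of the approximations at this rho.
"""

from coaltimes import (
    PopulationHistory,
    approx_etlbt,
    approx_etmrca,
    etlbt_stable,
    etmrca_stable,
)

n, N0, r = 800, 2e6, 0.001
model = PopulationHistory.exponential(N0, r=r)

etmrca = etmrca_stable(model, n)
etlbt = etlbt_stable(model, n)
a_tmrca = approx_etmrca(n, N0, r)
a_tlbt = approx_etlbt(n, N0, r)

print(f"scenario: exponential growth, N0 = {N0:g}, r = {r}, rho = {model.rho:g}")
print(f"n = {n} sequences")
print(f"ETMRCA  exact = {etmrca:12.3f}  approx = {a_tmrca:12.3f}  "
      f"rel err = {abs(a_tmrca / etmrca - 1):.3%}")
print(f"ETLBT   exact = {etlbt:12.3f}  approx = {a_tlbt:12.3f}  "
      f"rel err = {abs(a_tlbt / etlbt - 1):.3%}")
print("times are in generations; ETMRCA is the expected depth of the "
      "genealogy, ETLBT the expected total branch length feeding mutations")
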