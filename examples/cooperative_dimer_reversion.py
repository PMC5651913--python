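"""Cooperative thermal reversion of the phytochrome homodimer.

Solves the sequential chain PfrPfr -> PfrPr -> PrPr, in which reversion
of the first subunit changes the rate of the second (dimer
cooperativity), and shows the exact biexponential decomposition of the
bulk Pfr signal the chain predicts.
"""

import numpy as np

from phykin import DimerChain, dimer_reversion_trace

times = np.linspace(0.0, 120.0, 7)

# published 1-908 biexponential pair
chain = DimerChain(k_fast=0.320, k_slow=0.034)
res = dimer_reversion_trace(chain, times)
print("bulk Pfr fraction, chain 0.320/0.034 min^-1 from pure PfrPfr:")
for t, f in zip(times, res.pfr_fraction):
    print(f"  t = {t:5.1f} min   Pfr = {f:.4f}")
print(
    f"exact decomposition: f(t) = {res.amp_fast:.3f}*exp(-{res.k_fast}*t)"
    f" + {res.amp_slow:.3f}*exp(-{res.k_slow}*t)"
)
print(
    "note: the pure chain pins the fast amplitude at "
    f"{res.amp_fast:.2f} for this rate ratio; the observed 0.90 share "
    "requires amplitude heterogeneity beyond the chain alone."
)

# degenerate limit: equal rates give (1 + k*t/2) * exp(-k*t), not a
# plain biexponential
eq = dimer_reversion_trace(DimerChain(k_fast=0.1, k_slow=0.1), times)
print(f"\nequal-rate limit is degenerate: {eq.degenerate}")
print("Pfr(20 min) =", round(float(eq.pfr_fraction[times == 20.0][0]), 4),
      "vs closed form", round((1 + 0.1 * 20 / 2) * np.exp(-0.1 * 20), 4))
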