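"""Stability of the uniform cortex vs flow strength and recruitment.

Counts unstable Fourier modes (j = 1..10) of the uniform steady state over
the (V_hat, K_ME) plane.  The fitted operating point sits in the stable
region but near the boundary — strong enough coupling to amplify AIR-1
asymmetries without spontaneous patterning.
"""

import numpy as np

from cortexflow import paramfit
from cortexflow.stability import count_unstable, stability_diagram

params = paramfit.fitted_params(k=2, polarization=True, seed=0)
Vs = np.linspace(0.0, 0.1, 6)
Ks = np.linspace(0.0, 6.0, 7)
diag = stability_diagram(Vs, Ks, params)

print("unstable-mode counts (rows: K_ME, cols: V_hat)")
print("        " + "  ".join(f"{v:5.2f}" for v in Vs))
for kme, row in zip(Ks, diag.counts):
    print(f"K_ME {kme:4.1f} " + "  ".join(f"{c:5d}" for c in row))

boundary = paramfit.choose_KME(params)
print(f"\nat the fitted V_hat = {params.V_hat:.3f}: defaults K_ME = "
      f"{params.K_ME} -> {count_unstable(params)} unstable modes; "
      f"instability boundary at K_ME = {boundary:.2f}")
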