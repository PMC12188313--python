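"""The parameter-estimation pipeline, step by step.

Derives the dimensionless defaults from direct measurements and the
synthetic target profiles: nondimensional rates, the cortical bound
fractions, the flow strength, the AIR-1 inhibition coupling, and the
recruitment strength at the stability edge.
"""

import numpy as np

from cortexflow import fixtures, paramfit, scenarios

dim = paramfit.DimensionalParams()
nd = paramfit.nondimensionalize(dim, polarization=True)
print(f"D_hat = {nd['D_E']:.3g}  l_hat = {nd['l_hat']:.3f}  "
      f"Koff_E (polarization) = {nd['Koff_E']:.1f} per myosin lifetime")

shell, bound = paramfit.cortical_fraction()
print(f"cortex = {100 * shell:.1f}% of the ellipsoid volume; x1.5 "
      f"enrichment -> {100 * bound:.0f}% of ECT-2 bound")

M_target = fixtures.myosin_target(seed=0)
V_hat = paramfit.fit_velocity_strength(M_target)
print(f"V_hat = {V_hat:.4f} (imposed myosin profile -> 10 um/min peak flow)")

E = fixtures.ect2_target(0, 256)
M = fixtures.myosin_target(0, 256)
k1 = paramfit.fit_myosin_params(E, M, k=1)
print(f"k=1 fit feasible? {k1.feasible} — linear feedback cannot push the "
      "myosin asymmetry (1.5) below the ECT-2 asymmetry (1.9)")

params = paramfit.fitted_params(k=2, polarization=True, seed=0)
A = scenarios.polarization_air1(1.9, target_edge_length=1.0, n_grid=256)
kae = paramfit.fit_KAE(A, params)
print(f"K_AE = {kae:.3f} (bisected so the myosin-free ECT-2 asymmetry "
      "is 1.2)")

kme = paramfit.choose_KME(params)
print(f"K_ME stability boundary = {kme:.2f}; shipped default 2.5 is stable")
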