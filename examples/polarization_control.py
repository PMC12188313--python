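"""Control polarization: persistent AIR-1 cue 1.9 µm from the posterior pole.

Runs the coupled pipeline (FEM AIR-1 solve -> 1D cortex model) from the
uniform state and prints the summary metrics: how strongly ECT-2 and
myosin polarise, how fast symmetry breaks, how wide the posterior
clearance domain is, and the peak cortical flow speed.
"""

from cortexflow import paramfit, scenarios

params = paramfit.fitted_params(k=2, polarization=True, seed=0)
print(f"fitted flow strength V_hat = {params.V_hat:.4g} "
      "(imposed myosin target drives 10 um/min peak flow)")

res = scenarios.run_polarization(1.9, params=params, n=500,
                                 target_edge_length=1.0, duration_min=15)
m = res.metrics
print(f"ECT-2 max/min asymmetry      : {m.ect2_asymmetry:.2f}")
print(f"myosin max/min asymmetry     : {m.myosin_asymmetry:.2f}")
print(f"symmetry-breaking time       : {m.t_sb_min:.2f} min "
      "(5% posterior myosin clearance)")
print(f"clearance domain             : {m.clearance_pct_half_perimeter:.0f}% "
      "of the half-perimeter per side")
print(f"peak flow                    : {m.peak_flow_um_min:.1f} um/min "
      f"at {m.peak_flow_time_min:.1f} min")
print("Flows and recruitment amplify the ~20% AIR-1-driven ECT-2 dip into "
      "a strong, localized posterior clearance.")
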