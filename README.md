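# cortexflow

A mechanochemical model of cortical polarization and
centralspindlin-independent cytokinesis in the *C. elegans* zygote, for
quantitative cell biologists and modellers studying how centrosomal cues
pattern the actomyosin cortex.

Aurora A kinase (AIR-1) is activated on the centrosomes, diffuses through
the cytoplasm and inhibits the RhoGEF ECT-2 at the nearby cortex,
attenuating RHO-1/myosin contractility there.  `cortexflow` couples:

* a **2D steady diffusion solve** for cytoplasmic AIR-1 on the elliptical
  embryo cross-section (P1 finite elements, Gaussian centrosome sources,
  no-flux boundary): −∇²a + κ̂a = f, whose boundary trace A(x̂) is the
  cortical cue; and
* a **1D periodic active-cortex model** for bound ECT-2 (E), bound myosin
  (M) and cortical flow (v), in myosin-lifetime/perimeter units:

      ∂ₜE = D̂_E ∂ₓ²E − ∂ₓ(vE) + K̂on(1 + K_ME M)E_c − K̂off(1 + K_AE min(A, A_sat))E
      ∂ₜM = D̂_M ∂ₓ²M − ∂ₓ(vM) + K_EM E M_c − M − K_fb M^k
      (1 − ℓ̂²∂ₓ²)v = V̂ ∂ₓM,   mean(v) = 0

  with well-mixed cytoplasmic pools E_c = 1 − mean(E), M_c = 1 − mean(M).

ECT-2 exchanges in seconds — far too fast for direct advection — but is
preferentially recruited by long-lived, flow-advected cortical components
(folded into the K_ME·M term; an explicit three-species variant is
included).  The package also provides the per-mode linear stability
analysis, the full parameter-estimation pipeline, seeded synthetic target
profiles standing in for the image-derived fitting curves, and the
in-silico experiment suite (centrosome-distance sweeps, recruitment and
residence-time perturbations, transient cues, acute cortical clearing,
and cytokinesis centrosome configurations).

See `docs/methods.md` for the model, numerics and fitting conventions.

## Worked example

```bash
python examples/polarization_control.py
```

prints (control polarization, centrosomes 1.9 µm from the posterior pole):

```
fitted flow strength V_hat = 0.0601 (imposed myosin target drives 10 um/min peak flow)
ECT-2 max/min asymmetry      : 1.48
myosin max/min asymmetry     : 1.50
symmetry-breaking time       : 0.08 min (5% posterior myosin clearance)
clearance domain             : 24% of the half-perimeter per side
peak flow                    : 8.0 um/min at 1.6 min
```

A weak AIR-1 signal (a ~20% posterior ECT-2 dip on its own) is amplified
by flow-coupled recruitment into a strong, localized posterior clearance
with wild-type-like flow speeds.  Other examples cover the AIR-1
distance dependence (`air1_profile.py`), the stability diagram
(`stability_diagram.py`), the fitting pipeline (`parameter_fitting.py`),
cytokinesis (`cytokinesis.py`) and the explicit-intermediary variant
(`extended_intermediary.py`).

A thin CLI wraps the same functions:

```bash
cortexflow run polarization --out out/
cortexflow fit --k 2 --out params.json
cortexflow make-fixtures --seed 0 --out fixtures/
```

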