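# Methods

`cortexflow` models how the *C. elegans* zygote patterns its actomyosin
cortex in response to centrosomal Aurora A (AIR-1), during both polarity
establishment and centralspindlin-independent cytokinesis.  The model has
two coupled layers: a 2D steady diffusion problem that turns centrosome
positions into a cortical AIR-1 profile, and a 1D active-cortex model of
ECT-2 (the RhoGEF upstream of RHO-1/myosin) and myosin with advection by
cortical flow.

## AIR-1 layer (2D, elliptical cross-section)

The embryo cross-section is an ellipse with semi-axes 27 × 15 µm
(perimeter L ≈ 134.7 µm).  AIR-1 is activated at the centrosome(s),
modelled as isotropic Gaussian sources of width σ_c (0.175 µm for the
small polarization centrosomes, 0.7 µm for mature cytokinesis
centrosomes), diffuses with cytoplasmic diffusivity D, and is inactivated
at a basal phosphatase rate.  Normalising by D, the steady concentration
a(x) solves

    −∇²a + κ̂ a = f(x) in Ω,   ∂a/∂n = 0 on ∂Ω,

with ∫f = C0/D (1/32 for polarization, 1 for cytokinesis — only the 32×
ratio is physically meaningful) split equally between centrosomes.

Numerics: linear (P1) triangular finite elements.  The mesh combines an
arclength-uniform boundary ring with a graded hexagonal interior lattice
(default edge 0.5 µm, 4× refined within 3σ_c of each source, with a 2×
grading annulus), Delaunay-triangulated; convexity of the ellipse
guarantees the triangulation tiles the inscribed polygon.  Mass/stiffness
matrices are assembled exactly; the Gaussian load uses a degree-5
(7-point) quadrature.  The discrete solve conserves the source exactly
(κ̂ ∫a = ∫f to the linear-solver tolerance), and halving the edge length
changes the boundary profile by <1%.  Boundary values are mapped to a
uniform periodic arclength grid (1000 points, origin at the posterior
pole, counter-clockwise) by linear interpolation.

Two quantities are not printed in the source material and are fixed by
reproducible rules:

* **Phosphatase rate κ̂** — the smallest value on a logarithmic scan
  (10⁻⁴–1 µm⁻², 25 points/decade) for which a polarization cue 1.9 µm from
  the posterior pole leaves anterior cortical AIR-1 below 1% of the
  posterior value.  At default resolution this gives κ̂ ≈ 9 × 10⁻³ µm⁻²
  (decay length ~10 µm).
* **AIR-1 unit** — absolute AIR-1 levels are arbitrary, so the package
  fixes the unit by the myosin-depleted calibration: with inhibition
  coupling K_AE = 1.3 the steady myosin-free ECT-2 asymmetry under the
  reference polarization profile is 1.2.  Because the myosin-free steady
  state is E ∝ 1/(1 + K_AE·min(A, A_sat)), this is a closed-form scalar
  root-find on the profile scale.  The same factor rescales cytokinesis
  profiles, whose posterior values then land near the saturation level
  A_sat = 0.25 — consistent with how that threshold was originally set.

## Cortex layer (1D, periodic)

Dimensionless variables: length in perimeters, time in bound-myosin
lifetimes (τ_M = 15 s), concentrations as fractions of the
all-bound-to-cortex level, with well-mixed cytoplasmic pools
E_c = 1 − mean(E), M_c = 1 − mean(M) (total mass of each species is
conserved identically).  The equations are

    ∂t E = D̂_E ∂x²E − ∂x(vE) + K̂on_E (1 + K_ME M) E_c
           − K̂off_E (1 + K_AE min(A, A_sat)) E
    ∂t M = D̂_M ∂x²M − ∂x(vM) + K_EM E M_c − M − K_fb M^k
    (1 − ℓ̂² ∂x²) v = V̂ ∂x M,   mean(v) = 0.

ECT-2 exchanges rapidly (τ_E = 3 s in cytokinesis, 20% faster in
polarization, so K̂off_E = 5 or 6); its binding is boosted by
myosin-associated recruitment (the factor 1 + K_ME·M — at the uniform
state ~40% of binding is recruitment-mediated and the maximal boost is
~twofold) and its unbinding by AIR-1-dependent phosphorylation, clamped
at A_sat.  Myosin is activated by cortical ECT-2 and inactivated at a
basal rate plus a RhoGAP-like nonlinear term K_fb·M^k (k = 2 in the main
parameterisation; k = 3 supported).  The velocity balances
myosin-proportional active stress against viscosity and friction;
ℓ̂ = 0.1 is the hydrodynamic length as a fraction of the perimeter
(ℓ ≈ 13 µm, quoted as 10% of the perimeter — the model uses the quoted
rounded value).

The saturation is implemented as a hard clamp min(A, A_sat).  A smooth
(e.g. Michaelis–Menten) alternative would change the ECT-2 off-rate only
in the narrow band where A crosses A_sat; in polarization A stays below
A_sat everywhere, so the choice matters only for cytokinesis posterior
values, where it shifts profiles by a few per cent at most.

K̂on_E is not free: whenever other ECT-2 parameters change it is re-solved
so the uniform AIR-1-free steady state binds 10% of ECT-2 (the measured
cortical fraction: a 400 nm cortex on a 27×15×15 µm ellipsoid is 6.7% of
the volume, ×1.5 cortical enrichment = 10%).  The myosin pair (K_EM = 9,
K_fb = 3.6 for k = 2) puts ~30% of myosin bound at the same state.

Numerics: N = 1000 periodic finite-volume cells; first-order upwind
advection (conservative to machine precision); explicit reactions;
backward-Euler diffusion with the three-point Laplacian; velocity from the
centered-difference/Laplacian system.  On the uniform periodic grid the
velocity and diffusion systems are diagonalised exactly by the FFT.  The
step is first-order in time; Δt = 0.25·min(Δx/max|v|, 0.01), re-evaluated
every step (CFL-safe by construction).  Doubling N or halving Δt moves
the reported metrics by <1%.

## Parameter estimation

1. Geometry, lifetimes, diffusivities (D = 0.1 µm²/s for both species,
   D̂ ≈ 8.3 × 10⁻⁵) and ℓ̂ from direct measurements.
2. Flow strength V̂: fixed so that the velocity driven by the imposed
   quasi-steady myosin profile peaks at 10 µm/min (the wild-type maximum).
   With the canonical synthetic targets this gives V̂ ≈ 0.060.
3. (K_EM, K_fb): unweighted least squares of the steady myosin field
   (ECT-2 imposed, transport active) against the myosin target, in
   log-space with bounds.  With linear feedback (k = 1) the non-advective
   steady myosin is proportional to ECT-2, so the measured myosin
   asymmetry (1.5) below the ECT-2 asymmetry (1.9) is unreachable —
   nonlinear inhibition is required.  Note the pair is only softly
   identified by profile shape (a ridge K_EM/K_fb ≈ const fits nearly as
   well); the package's identification test recovers parameters from
   forward-model-generated targets to <2%.
4. K_AE: bisection on full nonlinear myosin-free simulations until the
   steady ECT-2 asymmetry is 1.2; returns ≈1.3 in the package's AIR-1
   units (the calibration above makes this self-consistent).
5. K_ME: raised in steps of 0.05 until a Fourier mode of the uniform state
   goes linearly unstable; the default 2.5 (k = 2) is stable, with the
   computed boundary at ≈3.3 for the canonical targets.  How tightly the
   boundary hugs 2.5 depends on the stand-in profiles through V̂.

## Linear stability

Perturbing the uniform state with mode e^{2πijx} gives a real 2×2 growth
matrix per mode: diagonal decay (−K̂off_E, −1 − kK_fb M₀^{k−1}) plus
diffusive damping, recruitment/activation cross-couplings, and the
advective terms E₀·V̂q²/(1+ℓ̂²q²), M₀·V̂q²/(1+ℓ̂²q²) from the velocity
transfer factor (modes j ≥ 1 leave the cytoplasmic pools untouched).
Instability is declared on a positive real part of either eigenvalue; the
negative-determinant shortcut is computed alongside and any disagreement
(a positive-trace oscillatory instability) is logged.  Eigenvalues are
cross-checked against decay rates measured from the nonlinear integrator
to within 5%.

## Synthetic target profiles

The image-derived quasi-steady ECT-2/myosin curves used for fitting are
not available as data, so the fixtures module generates seeded synthetic
stand-ins: mirrored Gaussian bumps truncated to 6 Fourier modes (echoing
the Fourier-interpolant smoothing of punctate microscopy data), affinely
rescaled to exact means (0.1 / 0.3) and max/min asymmetries (1.9 / 1.5),
with both maxima in the same anterior region (ECT-2 broad at x̂ = 0.35,
width 0.25; myosin sharper at x̂ = 0.30, width 0.12) since both describe
one quasi-steady embryo.  Seeds jitter the bump width and harmonic
weights by a few per cent.  What the stand-ins do not capture: the true
measured profile shapes (so values fitted *to* them — V̂, the free
(K_EM, K_fb) pair, and the precise stability margin of K_ME = 2.5 —
reproduce the printed values only approximately), embryo-to-embryo
variability beyond the seed jitter, and measurement noise.

## Scenario suite and metrics

All scenarios start from the uniform steady state and are fully
deterministic.  Metrics: max/min asymmetries and anterior/posterior pole
ratios of each species; symmetry-breaking time t_sb (first time posterior
myosin drops 5% below its pre-cue value, interpolated between output
frames); clearance-domain width (contiguous below-mean ECT-2 region
around the posterior pole, one-sided extent as % of the half-perimeter —
the "x µm on either side of the pole" convention); peak flow speed in
µm/min (v̂·L/τ_M) and its time; maximal posterior ECT-2 clearing relative
to baseline; a local-maxima count (2% prominence) for detecting secondary
peaks; and a stability flag (any field exceeding 10× its total aborts the
run as unstable).

Scenario problem sizes used throughout the shipped analyses: 0.5 µm FEM
meshes, 1000-cell cortex grids, 10–25 min simulated time; the test suite
uses 1 µm meshes and 256-cell grids where the checked property is
resolution-insensitive.

The acute-removal scenario zeroes ECT-2 and myosin on 10% of the
*perimeter* around the posterior pole (the 1D model has no area measure).
Because the initial condition has a sharp concentration step, the flow
maximum occurs essentially immediately rather than after ~1 min; the
relaxation (steadily decaying flows, return to the uniform state) matches
the qualitative behaviour.

The extended three-species variant replaces myosin in the recruitment
term by an explicit intermediary P with PAR-like residence times
(presets 100 s and 200 s), advected by the same flow; its on-rate keeps
30% bound.  A consistency switch gives P exactly myosin's kinetics, in
which limit the model collapses onto the minimal one bit-for-bit.  With
realistic long-lived kinetics, even modest recruitment couplings produce
much stronger amplification than the minimal model and sustained
oscillatory patterning at couplings well below the minimal model's
instability threshold.

## Known limitations

* The AIR-1 attenuation with centrosome distance under the
  minimal-passing κ̂ rule is ~43% per 1.9→5 µm step (vs the reported
  ~50%), and consequently the symmetry-breaking-time ratio between 10 µm
  and 1 µm cues comes out ≈5 rather than ≈10: both are controlled by the
  unpublished phosphatase level, for which only the <1% anterior-impact
  criterion is reproducible.
* The myosin-free calibration (ECT-2 asymmetry 1.2) mathematically
  implies ~15–19% posterior ECT-2 depletion, so the package reports
  ~18% maximal clearing in the recruitment-free scenario; a 10% figure is
  consistent only with myosin clearing (ECT-2 drop × the ~0.66 relative
  myosin gain).
* PAR proteins, RHO-1 pulsing, the actin network, and
  centralspindlin-directed ECT-2 accumulation are outside the model.
* Cytokinesis centrosome presets are editable placeholders (the measured
  coordinates are figure-derived); quantitative cytokinesis claims are
  restricted to symmetry, amplification and monotonicity properties.
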