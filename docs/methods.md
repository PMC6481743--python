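# Methods

This note documents the models, numerical choices and limitations behind
`aortaflow`, in the order the pipeline runs.

## Scope and design premise

The package implements the *analysis* of an inlet-BC comparison study —
profile construction, outlet model, descriptor computation, and the
comparison statistics — not a Navier–Stokes solver. Velocity fields come
from closed-form laminar solutions and from a kinematic valve-jet
surrogate. This keeps every descriptor exercisable and verifiable against
analytic oracles; it also means the absolute descriptor values describe the
synthetic scenario, never a patient.

## Geometry

The vessel is a straight circular tube meshed on a structured polar grid
(`n_radial` rings × `n_circ` sectors × `n_axial` slices; axis wedges stored
as degenerate hexahedra). Defaults: R = 15 mm (ascending-aorta calibre),
L = 180 mm, 10 × 24 × 24 cells. The AAo/AA/DAo regional labels used for
summary statistics are assigned by arc-length fractions (thirds by default,
configurable), standing in for the anatomical partition of a real aorta.
Cross-section integrals use the trapezoidal rule in radius on the polar
grid, which integrates the disc area exactly (`Σw = πR²`) and smooth
integrands at second order; flux normalizations are always done against
this same quadrature, so generated fields and inlet BCs satisfy their
target `Q(t)` to machine precision at every slice and phase.

## Synthetic flow fields

*Analytic oracles.* Poiseuille (`w = 2Q/(πR²)(1 − r²/R²)`), swirling
Poiseuille (`v = (−Ωy, Ωx, w(r))`, for which the helicity density is
exactly `2ΩW0`), and Womersley flow, evaluated from the complex Bessel
profile with the amplitude chosen so the oscillatory flux is exactly
`Q_a sin(ωt)`.

*Valve-jet surrogate.* The inlet axial profile is an off-centre Gaussian
(centre `e·R`, width `σ·R`; defaults e = 0.4, σ = 0.35) normalized to unit
flux, with small seeded azimuthal harmonics (≤5%) emulating valve-to-valve
variability; the in-plane field is a solid-body swirl of edge speed `S`
modulated by `Q(t)/Q_peak`. Downstream evolution is frozen kinematics: at
arc length `s` the axial profile is blended `α(s)·jet + (1−α(s))·parabola`
with `α = exp(−s/λ_jet)` and the swirl decays as `exp(−s/λ_swirl)`
(defaults `λ = L/3`). Blending toward the *parabolic* (not flat) profile
keeps a no-slip-consistent wall gradient downstream so TAWSS stays finite
everywhere; because both blend terms carry flux `Q(t)`, conservation is
exact by construction. The swirl edge speed is calibrated by root finding
so the cycle-averaged inlet in-plane/total velocity ratio hits a target
(default 0.51, the severe-stenosis condition; the generator reports the
achieved ratio).

*Flow waveform.* Systole is a squared-sine pulse (peak 400 ml/s, duration
0.35 T) on a 5% diastolic baseline — strictly positive so per-time flux
rescaling is always well posed — giving ≈5 l/min at 60 bpm. The four
particle-release markers T1–T4 are equally spaced across systole at
`i·T_sys/5`.

## PC-MRI emulation

A plane acquisition records three velocity components per pixel per phase:
slab-averaged along the plane normal (5-point Gauss–Legendre across the
10 mm slab; samples outside the vessel contribute zero, as static tissue
would), plus independent zero-mean Gaussian noise per component (default
5% of VENC; the noise model is a placeholder — real PC-MRI noise is
velocity-encoded Rician — and is surfaced in the config), with each
component wrapped into `[−VENC, VENC)` to emulate aliasing. VENC follows
the clinical protocol rule: 10% above the expected per-component peak,
floored at 5 cm/s. Pixel values are evaluated from the generator's closed
form where one exists, since a scanner measures the physical flow rather
than a mesh interpolant; fields without a closed form are sampled
trilinearly. The lumen mask marks pixels whose centre lies inside the
cross-section.

## Inlet-BC construction

Plane-to-inlet registration is a least-squares rigid (Kabsch) fit to ≥4
non-collinear reference-point correspondences, with an optional Umeyama
uniform scale for anisotropic-voxel corrections; the RMS fit error is
reported. Inlet nodes are back-projected onto the plane and sampled
bilinearly inside the lumen mask. Near the wall, where the bilinear support
is clipped by the mask, a one-sided weighted plane fit over the masked 4×4
pixel window is used instead of mask-renormalized averaging: renormalized
averaging cannot extrapolate, and systematically pulled wall-node
velocities toward interior values (a ~9% local bias on the solid-body
swirl, enough to dominate the round-trip error budget). Nodes with no
masked pixel nearby get zero velocity before rescaling. Temporal
interpolation between the 100 phases is periodic linear (cubic schemes
overshoot at the systolic jet). Finally every variant is rescaled by one
scalar per time point so its quadrature flux equals `Q(t)` exactly —
without this normalization, inter-variant differences would confound
profile shape with stroke volume. The waveform itself defaults to the one
extracted from the map (through-plane flux over the mask), as a clinician
would do.

The reported in-plane fraction is the ratio of spatial mean magnitudes
(`100·mean|v_in|/mean|v_tot|`); the pixelwise-averaged alternative is also
computed and stored, since either convention is defensible.

## Windkessel outlet

`P + R_dC dP/dt = (R_p+R_d)Q + R_pR_dC dQ/dt`, integrated with an implicit
trapezoidal step (A-stable, second order; verified by the dt-halving
ratio), `dQ/dt` from periodic central differences of the sampled waveform.
Cycles repeat until the max-norm pressure change between consecutive cycles
falls below 1 Pa (cap 50 cycles); non-convergence is returned with its
residual and a warning, never silently. Default parameters (R_p = 8 MPa·s/m³,
C = 10 nl/Pa, R_d = 140 MPa·s/m³) give ≈95 mmHg mean at 5 l/min with a
1.4 s decay time — a healthy systemic bed; patient-specific tuning is out
of scope.

## Wall shear stress

Velocity gradients at wall-face centroids come from a weighted (1/d²)
least-squares linear fit over the owner hexahedron's 8 nodes, with the
constant term free. The stencil is deliberately compact: widening it
azimuthally folds wall curvature into the linear fit and *degrades* the
gradient (a 3-sector-wide stencil showed ~40% bias on the Poiseuille
oracle; the compact stencil is first-order convergent, ~4% at the default
mesh). `τ_w` is the tangential part of `μ(∇v + ∇vᵀ)n̂`. Time integrals use
the periodic trapezoid rule over the stored phases. Surface statistics are
area-weighted: means (whole and per region, exactly consistent by
construction), and an interpolated weighted quantile for the 99th
percentile (Hazen positions under uniform weights) — a robust maximum that
excludes isolated spurious faces. OSI is clipped to [0, ½] and defined as 0
where `∫|τ|dt` vanishes. Spatiotemporal maps take the single axial face
ring nearest the analysis plane, order it by angle about the contour
centroid, and normalize cumulative arc length to [0, 1).

## Helicity and HFI

Vorticity uses the same least-squares gradient reconstruction, on
per-node stencils (index-space neighbours; symmetric in the interior,
one-sided at boundaries). `Hk = v·ω`; `LNH = Hk/(|v||ω|)` with the
convention LNH = 0 where either factor vanishes. Threshold volumes count
node-volume-weighted fractions with `Hk ≥ θ` and `Hk ≤ −θ` separately
(θ = 200 m/s² by default, the conventional display threshold).

Particles advect by classic RK4 (observed order 4.0 on solid-body
rotation) through trilinear-in-space / periodic-linear-in-time sampling, or
a closed form when available; default 500 seeds on a uniform inlet-disc
grid (the study driver uses 200 to keep runs interactive), dt = T/200,
horizon 3 cycles. Traces keep their partial history on domain exit but need
≥10 accepted steps to count. HFI is the along-trace mean of |LNH|, averaged
over particles, then over the four release times with equal weight; a
signed variant is available behind a flag.

## Comparison study

`run_study` executes all stages with the 3D variant as reference; percent
differences follow `100·(variant − 3D)/3D`. Degenerate cells are handled
explicitly: a vanishing reference with an equal value compares as exactly
0%, with a differing value as NaN (flagged, never dropped) — this makes the
reference's self-comparison identically zero and keeps the purely-axial
null scenario's report clean. Reports are deterministic: one seed drives
jet harmonics and acquisition noise, and identical configs produce
byte-identical JSON.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the descriptor pipeline is correct (against
closed forms) and that the *structure* of the published comparison emerges:
inter-variant differences are largest proximally and decay along the
vessel, and dropping in-plane components underestimates mean inlet velocity
by ≈40% under the calibrated 51% secondary-flow condition. They do not
reproduce patient-specific magnitudes, which require real anatomy and a
Navier–Stokes solve. One structural difference is expected: in the
surrogate, helicity exists only where the inlet supplies it, so FLAT and TP
variants yield HFI ≈ 0 and their HFI difference vs 3D is ≈ −100%, whereas
in real aortas arch curvature generates helicity from any inflow and a flat
profile can *over*-predict HFI. The surrogate likewise omits flow
reversal (no diastolic backflow, hence OSI ≈ 0), turbulence/transition,
wall motion, and branch flows.

## Default problem sizes

Tests and the acceptance script run the study at 10 × 24 × 24 cells,
24–100 phases and 30–200 particles, and the convergence studies at
n_radial ∈ {6, 12, 24}; these sizes sit on the flat part of the
accuracy-vs-cost curve for the straight-tube fixture (the WSS and Hk
oracles are within 5% at the default mesh and first-order convergent).
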