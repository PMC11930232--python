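# Methods

## Overview

`escapeswim` quantifies the energetics of the larval zebrafish C-start
escape swim by an experiment-driven simulation chain: silhouette movies →
rigid-motion isolation → midline kinematics → body reconstruction →
penalized Navier–Stokes simulation → power, work, cost of transport, and
viscosity-sweep experiments. Because the experimental recordings and the
histology database behind the original study are not redistributable, the
package ships a first-class synthetic-data generator whose outputs carry
exact ground truth; every downstream stage is validated against that ground
truth.

## Synthetic C-start generator (`synthgen`)

The generator emulates a stereotyped three-stage escape: a high-amplitude
C-bend, a counterbend, and a bout of fast swimming, rendered at the
acquisition geometry of a high-speed dark-field setup (10,000 frames/s,
512 × 420 px over ≈13.0 × 10.7 mm²; pixel scale 13.0/512 mm/px).

The midline is parameterized by its tangent angle φ(s, t):

* **Bend stages.** φ(s,t) = Θ(t)·W(s) with W(s) = (s/L)^1.5 (bending grows
  toward the tail; the head is comparatively stiff) and Θ(t) following a
  sin² pulse per stage: +A_C over the first stage (default 120°, 11 ms),
  −A_CB over the second (default 80°, 10 ms). Θ is by construction the
  head–tail angle.
* **Fast swimming.** A traveling wave
  φ(s,t) = A_F·r(τ)·B(s)·sin(ωτ − 2πs/L), B(s) = (s/L)^1.5, one wavelength
  per body length. Because B(0) = 0 and B(L) = 1 with a full 2π phase lag,
  the head–tail angle is exactly A_F·r(τ)·sin(ωτ): amplitude (default 40°)
  and frequency (default 60 Hz full cycles; four beats = two cycles,
  ≈33 ms) are exact ground truth. r(τ) is a 3 ms smoothstep ramp keeping
  the body velocity continuous across the counterbend transition.

Defaults give six |head–tail angle| maxima (C-bend, counterbend, four
beats) over ≈54 ms, total path of the center of mass ≈3 mm in water, and
tail speeds ≤0.4 m/s — all in the physiological range for 5 dpf escapes.
The functional form is a stand-in chosen for testability, not a measured
kinematic; see Limitations.

Per-frame midlines are normalized so the width-weighted silhouette centroid
sits at the origin and the silhouette's principal second-moment axis is at
0° (tracked continuously). This is the same convention the Procrustes
isolation converges to, so the superposed rigid motion (default 40, 15 mm/s
translation, 800°/s rotation) is exactly the rigid ground truth of the
rendered movie.

Rendering is crisp (no edge blur) with seeded additive Gaussian intensity
noise (default 2% of range, clipped). The swept half-width is floored at
0.8 px away from the tips — the thin caudal margin still covers about one
pixel on a real sensor — which keeps the tail silhouette connected.

Cross-section stacks are superellipse sections of the tabulated width/height
profile plus a thin dorsoventral fin-fold blade over the posterior body,
bilaterally symmetric by construction, with a seeded random subset of
interior slices removable to emulate missing histology sections.

## Rigid-motion isolation (`imaging`)

Segmentation thresholds strictly below the lower percentile of pixel
intensity (default 5), keeps the largest connected component and fills
holes. The body angle is the principal second-moment axis, π-periodic; the
branch closest to the previous frame's angle is taken (differential
scheme), with an isotropy guard that returns the previous angle flagged.
Center-of-mass and angle traces are smoothed with a Savitzky–Golay filter
(window 11 frames, order 3 — both configurable; the underlying study names
no specific filter).

Rigid transforms are applied to sub-pixel boundary contours
(marching-squares at the 0.5 level), not resampled images, so recomposition
costs a single rasterization; round-trip IoU on synthetic sequences is
≥0.98 (measured ≈0.99).

## Midline extraction (`midline`)

The morphological skeleton's longest geodesic path seeds the midline. Two
systematic artifacts of pixel skeletons are corrected:

* the skeleton forks inside the wide head and its longest branch hooks
  toward a head corner — the path is cut at the head's width maximum
  (distance-transform argmax) and later extended straight through the
  nearly rigid head to the snout tip via ray–contour intersection;
* the staircase of the 8-connected path corrupts tangents — the path is
  resampled at ≈2 px, refined to the midpoint of its two sub-pixel contour
  crossings along the local normal (3 iterations), and smoothed along
  arclength (order-2 Savitzky–Golay over ≈18 px, preserving genuine bends).

The final polyline is resampled to 301 equal-arclength points (300
segments). Equal-arclength resampling is done directly on the smoothed
polyline; a final spline fit was tried and rejected because its free end
tangents corrupt the head–tail angle (the telescoped sum of joint angles).

On default synthetic sequences the recovered midline is within ≈0.3 px of
ground truth, the tail-beat frequency within ≈2% and the fast-swim beat
amplitude within ≈4%; the C-bend peak angle is underestimated by ≈10%
(arclength smoothing flattens the highest-curvature tail region), which is
why descriptor recovery is specified for the fast-swim quantities.

Descriptors locate the six movement stages from the ordered maxima of the
|head–tail angle| trace (prominence 10°, minimum separation 2 ms): first
maximum = C-bend, second = counterbend, third–sixth = fast-swim beats. The
analysis window ends half a beat period after the sixth maximum (the
endpoint convention is not fixed by the source study). The tail-beat
frequency is 1/(2·mean inter-peak interval) since |angle| peaks twice per
undulation cycle. "Rotation amplitude" is implemented as the mean of |α|
local maxima — an interpretation, since per-cycle extrema are equally
defensible.

## Body reconstruction (`body3d`)

Missing cross-sections are filled by entropic optimal-transport
interpolation: the barycenter of the two bracketing key slices with linear
axial weight. The barycenter uses the convolutional formulation (Gibbs
kernel = Gaussian blur of σ = √(ε/2) px; iterative Bregman projections,
≤2000 iterations, marginal L1 tolerance 10⁻⁶), with ε defaulting to
10⁻³ × (slice diagonal)². The kernel truncation is widened to span the
whole slice so that transport between distant supports (point-mass tests)
is possible in float64. Output densities are thresholded at 0.5 of their
maximum.

The voxel volume's signed-distance field is sampled per transverse slice;
each of the n_axial stations (default 300) takes the zero contour of the
nearest slice resampled to n_circ (default 180) equal-arclength markers.
Volume comes from the voxel count; on a cylinder benchmark, volume and
lateral area are within 5% of the closed forms.

Bending follows the Euler–Bernoulli assumption: each cross-section is rigid
in-plane and stays orthogonal to the midline at matched arclength (the
vertical axis stays vertical for planar swims). In-plane rigidity is the
simplest choice consistent with the orthogonality statement; volume change
under an 80° bend is ≤3% (monitored in tests). The net translation and
rotation that bending re-introduces are removed by a momentum Procrustes
pass: the mass-weighted centroid is subtracted, and the angular-momentum
rate of the centered marker motion is integrated and derotated
(differential form — derotate by the accumulated angle first, then measure
the residual). Marker positions are mean-filtered over 0.5 ms
(window = round(0.5 ms/dt) ≥ 1) and finite-differenced for the deformation
velocity ũ.

For the 2D solver the body is reduced to its dorsal silhouette: a volume
lattice of midline stations × lateral fractions carrying ũ, with the
boundary polygon as its rim. The same momentum Procrustes and mean filter
apply. The full 3D marker path remains available at reduced resolution.

## Flow solver (`flowsolver`)

The penalized incompressible Navier–Stokes equations are advanced on a 2D
MAC staggered grid: explicit second-order centered advection and diffusion,
implicit penalization u ← (u* + λΔtχu_s)/(1 + λΔtχ) (unconditionally stable
in λ; default λ = 10⁸ s⁻¹, a value the source study does not fix), and an
incremental pressure projection whose Poisson problem is solved exactly by
DCT (no-slip box, Neumann pressure) or FFT (periodic benchmarks) — the
discrete divergence after projection is at machine precision. Hard
stability checks raise, proposing a maximum Δt, when the advective CFL or
the diffusive limit is violated; the escape driver subdivides each
acquisition interval accordingly (CFL number 0.35, Δt also capped at
50 μs and at 0.2Δx²/ν).

The fully explicit advection–diffusion step (rather than semi-implicit
diffusion) is a deliberate simplification: at the grid sizes and time steps
used the diffusive limit never binds, and it keeps the projection exactly
solvable by fast transforms. On the 128² Taylor–Green benchmark the decay
rate matches exp(−2νk²t) to 0.03% over a convective period.

The body enters as a mollified characteristic function (smoothed Heaviside
of the signed distance over one cell) with the solid velocity field
u_s = ū + ω∧r + ũ extended to the grid by nearest-marker lookup. The rigid
state is *not* prescribed: ρ_s A dū/dt = F and d(Jω)/dt = M per unit span,
with the inertia recomputed from the current polygon each step
(ρ_s approximated by ρ: the larva is near neutrally buoyant). Domain:
12 × 12 mm no-slip box centered on the initial center of mass (the source
study states the domain size but not its outer boundary conditions; a
periodic option exists for benchmarks).

Loads and power use the stress tensor T = −pI + μ(∇u + ∇ᵀu) integrated
over the boundary markers: F = Σ (T·n)Δs, M = Σ r×(T·n)Δs, and the
traction-power P = −Σ (T·n)·u_s Δs (positive = work done by the body on
the fluid; the printed double-integral form of the power in the source is
typographically garbled, and this is the standard reading consistent with
its derivation). Pressure is sampled 1.5 cells outside the surface (the
mollified interface is not physical); the viscous traction uses a one-sided
wall gradient — the sampled velocity differenced against the known surface
velocity — which resolves near-wall shear better than an interior centered
gradient at these grid sizes. The exact momentum/energy exchanged through
the penalty term each step is also recorded (`penalty_force`, etc.) but is
not used for coupling: its χ-rasterization impulses rectify into the power
integral at coarse resolution.

2D loads and power are per unit span and converted to watts with a body
span of 0.622 mm (the measured body height at the swim-bladder level).

### Problem sizes

The desk-scale acceptance setting is 128² cells over the 12 × 12 mm domain
(Δx = 94 μm; the production-resolution counterpart, Δx = 2.857×10⁻² mm at
Nx = 420, is reported as configuration arithmetic only). A full six-movement
escape (≈54 ms, ≈1100 substeps) runs in ≈5 s on one CPU; the six-viscosity
virtual sweep in ≈40 s.

## Energetics (`energetics`)

E = ∫P dt (Riemann sum matching the discrete formulation; trapezoid
optional), CoT = E/d_total with d_total the cumulative center-of-mass path,
Re = ρV̄L/μ with V̄ the mean speed over the six-movement window and L the
body length. Power is averaged over a 1 ms moving window before
integration; other traces use Savitzky–Golay (window 11, order 3) plus
spline resampling. Vorticity and the Q-criterion use centered differences
of the cell-centered velocity; in 2D the Q-criterion uses Frobenius norms
of the 2×2 gradient parts and is reported per unit depth.

## Experiments (`experiments`)

* **Virtual sweep**: one fixed body movement simulated at each viscosity of
  {0.83, 1.1, 2.3, 5, 10, 15} mPa·s.
* **Realistic sweep**: per-viscosity body movements, each simulated at its
  own viscosity. The synthetic stand-in for the behavioral adaptation
  scales the beat frequency as f = f₀(μ₀/μ)^0.2 (μ₀ = 0.83 mPa·s) with
  amplitudes fixed — the observed direction of adaptation; no quantitative
  law is available.
* **Frequency rescaling**: time-axis dilation by 1/factor (default
  factor 0.7 = 30% slowdown) resampled to the original dt; per-frame shapes
  unchanged, ũ scaled by the factor (consistent with pure time dilation;
  whether to rescale or recompute ũ is not fixed by the source and both
  coincide for linear resampling).

Sweep tables are fitted by ordinary least squares with Pearson correlation
(n ≥ 3, non-constant abscissa); heavier inferential machinery (ANOVA,
post-hoc tests) is out of scope.

## Known limitations

* **2D reduction.** The solver resolves the horizontal plane only. The
  dominant consequences: the thin-fin and dorsoventral surfaces that carry
  much of the real viscous load are absent, and the 2 mm water column's
  confinement is not modeled. At 128²–256², the viscous share of the
  traction power is only ≈2–6% across the 0.83–15 mPa·s range (though that
  share is itself linear in μ with R² ≈ 0.999), while the dominant
  pressure/recoil share varies non-monotonically by ±4%. Total mean power
  and CoT therefore do not reproduce the near-perfect linearity in μ that
  the full-resolution 3D setting exhibits; the sweep's monotonic trends
  (distance, Reynolds number, wake enstrophy decreasing with μ; CoT
  increasing) are robust.
* **Stand-in kinematics.** With the generator's ramped 40° beats, the
  deformation power in late fast swim is weak relative to the rigid-recoil
  power, which peaks near the bend apex: the canonical "power spike in the
  middle of each curvature phase" pattern is clean in the bend stages (with
  power minima at the curvature maxima) but one of the two late fast-swim
  phases peaks at its boundary instead of inside it.
* **No elastic or sensorimotor feedback**: the deformation is prescribed;
  force transmission through passive elasticity is not modeled.
* The C-bend peak head–tail angle is systematically underestimated by ≈10%
  by the midline extractor (smoothing at the highest-curvature instant).
* Passing tests certify recovery of *synthetic* structure (crisp
  silhouettes, planar motion, exact stage grammar); real recordings add
  defocus, glare, pigmentation and out-of-plane motion that this suite does
  not exercise.
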