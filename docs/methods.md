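# Methods

`gastroflow` models the fluid mechanics of the fed human stomach in three
layers: a parametric average-stomach geometry, a prescribed wall-motility
law, and a moving-boundary incompressible flow solver for the stomach's
symmetry plane, with metrics for the retropulsive jet, antral eddies and
pressure differences. This note records the models, the parameter choices,
the numerical methods, and the limits of what the package's tests show.

## Geometry

The stomach is reconstructed the way CAD stomach models are classically
built from a planar silhouette: the midplane outline is traced as two
spline branches (lesser and greater curvature), both branches are resampled
to `n_sections` points, corresponding points are joined by chords, and each
chord's midpoint and half-length define an auxiliary circle. The circles
are lofted into a watertight, mirror-symmetric triangulated surface
(`trimesh` is the mesh container; the loft itself is built here). The
fundus is closed by a spherical dome seated on the last auxiliary circle —
the dome scales with that circle's radius, so wall deformations carry it
along — and the pylorus by a flat cap over the 1.2-cm pyloric ring.

**Default shape.** The outline is generated from three monotone-cubic
profiles over normalized centerline arclength — tangent angle θ(σ), circle
radius ρ(σ), and chord tilt λ(σ) (the rotation of the pairing chord from
the local normal toward the proximal tangent) — plus the centerline length.
The knots were calibrated once by least squares on quantities computed
through the actual construction pipeline, targeting: greater curvature
34 cm, widest section 10 cm, pyloric ring 1.2 cm, capacity 0.9 L, and the
wave kinematics below. Default measurements: 34.0 cm / 10.0 cm / 1.2 cm /
0.898 L.

**Pairing schedule.** Chord pairing is by index after resampling each
branch at prescribed normalized-arclength fractions. The default schedule
is non-uniform: chords tilt progressively toward the cardia (up to ~57°),
exactly as the section circles of image-derived stomach models fan through
the corpus and fundus. This matters kinematically: under *uniform*
(equal-arclength) pairing the ratio of wave speeds along the two curvatures
is identically the ratio of branch lengths, independent of the outline
shape, and the published speed pair is then unattainable by any
non-degenerate outline (adjacent circles would have to interpenetrate, as
the chord field must churn faster than the no-crossing bound
ρ·(κ + dλ/ds) < cos λ allows). With tilted chords the greater-curvature
foot of each chord slides distally faster than the lesser-curvature foot,
which is the real geometric origin of the curvature-wise speed asymmetry.
Uniform pairing remains the default for user-supplied outlines and for the
straight-tube fixtures.

**Feasibility bound on the speed pair.** Even with tilt, an embedded loft
(no circle interpenetration) jointly bounds the two branch traverse rates;
the printed means (4.6 and 2.1 mm/s) sit slightly outside the bound for any
smooth outline compatible with the other targets. The default geometry is
calibrated at the feasible boundary: mean 4.33 mm/s (greater), 2.07 mm/s
(lesser), maximum 7.4 mm/s — 2–8 % below the printed values and well inside
the ±10 % band those measurements carry.

**Measurements.** Branch lengths are polyline arclengths of the resampled
outline; the widest width is the maximum circle diameter; the enclosed
volume is the divergence theorem over the watertight surface (checked in
the tests against a Cavalieri slice-stacking oracle at 1-mm slabs). The
midplane polygon (sections' chord endpoints plus the dome trace) feeds the
2-D solver; its area equals the closed outline's area by construction.

## Motility

Antral contraction waves (ACWs) are born every 20 s at the mid-corpus
(15 cm from the pylorus along the centerline), translate at a constant
2.3 mm/s along the horizontal axis of the symmetry plane, and live 58 s.
Each wave scales the radii of the circles it covers by
`1 − occ(age) · B((s − s_w)/w)`, with `B` a compactly supported cos² bump
of total centerline width 2 cm and `occ` the piecewise-linear occlusion
profile measured for liquid meals: 0 → 40 % over the first 17.5 s, a 16-s
plateau, then a terminal ramp to 80 % at end of life. Relative occlusion
means the fractional narrowing of the midplane lumen width at the wave
peak.

**Wave death.** A wave whose 80 %-deep indentation vanished instantaneously
at age 58 would be a wall-position discontinuity (it injects tens of m/s of
spurious wall velocity into any flow solve). Here the wave peak's
centerline coordinate is extrapolated past the pylorus, so the terminal
contraction slides off the sphincter and its indentation fades to exactly
zero as the wave expires: the geometry is calibrated so the trailing edge
of the bump leaves the domain at age ≈ 57.8 s. Consequences: the maximum
occlusion realized on the wall is ~76 % (as the peak crosses the pyloric
ring) while the occlusion *profile* still evaluates to 80 % at age 58, and
the wall pattern repeats with a 20-s period from t = 38 s onward exactly.

**Tonic contraction.** The stomach is closed and liquid-filled, so the
capacity displaced by the travelling indentations must be returned by the
proximal wall. Radii above the mid-corpus apex (placed at the wave birth
station) are scaled by `1 + f(t) · w(s)` with `w` rising linearly from 0 at
the apex to 1 at the fundus top; `f(t)` is solved by bracketed
root-finding (`brentq`) so the lofted volume equals the rest volume to
1 × 10⁻⁶ relative. Over a motility period |f| peaks at 6.5 %, inside the
8 % physiological cap, which the model treats as a hard feasibility bound.
The dome cap is what makes the cap attainable: it contributes volume ∝
(1+f)³ and thus most of the restoring capacity.

**Wall velocities** are central finite differences of wall positions with
Δt = 1 ms (checked against Δt = 0.1 ms).

## Flow solver

The gastric content is a Newtonian liquid (ρ = 1 kg/L; μ = 10⁻³ Pa·s for
the glucose-solution meal, 1 Pa·s for the honey-like comparison). The
solver integrates the incompressible Navier–Stokes equations in the
deforming midplane on a uniform staggered (MAC) grid with an
incremental-pressure (Van Kan) projection scheme:

1. predictor with the previous pressure gradient, 2nd-order upwind
   advection, and diffusion — explicit when `ν Δt/h² ≤ 0.2`, backward
   Euler (matrix-free CG) otherwise;
2. direct-forcing immersed boundary: cells are re-classified each step
   against the wall polygon (`shapely`), and every face not flanked by two
   fluid cells is set to the nearest wall vertex's velocity — no remeshing
   for arbitrarily large boundary motion;
3. a pressure-increment Poisson solve per connected fluid component
   (5-point stencil, homogeneous Neumann at walls, sparse LU), with the
   compatibility mean removed per component; that mean is the logged
   *area-drift rate*, the honest price of reducing a 3-D-volume-conserving
   wall law to its midplane (it stays ~10⁻³ s⁻¹);
4. velocity correction on interior faces and pressure anchoring at a
   reference point, since a closed domain fixes pressure only up to a
   constant.

The incremental form is essential for the *pressure*: non-incremental
Chorin smears the reported field by (I − νΔtL)⁻¹, which at 10 Pa·s
flattens it over √(νΔt) ≈ 1.4 cm and destroys the viscosity scaling of
cross-wave pressure drops (measured ratio 2.5 instead of ~10).

**Time stepping.** Advective CFL (0.5) clamped to [0.01, 0.1] s for the
low-viscosity regime and [0.005, 0.05] s for the high-viscosity one. The
explicit viscous limit ρh²/4μ participates only when diffusion is explicit;
with implicit diffusion a quiescent fluid runs at the upper bound in either
regime. Discrete continuity after projection holds to ~10⁻⁹ s⁻¹ (tolerance
10⁻³); no-slip at forced faces is exact by construction (tolerance 10⁻⁴).

**Verification.** A body-force-driven periodic channel reproduces the
parabolic profile to <0.1 % L2 at h = H/32 (the `periodic_x` mode exists
for this benchmark); a rigid box stays exactly at rest; runs are
bit-deterministic. On the bench-chamber scenario the cycle-peak
retropulsive velocity converges with observed order ≈ 1.2 across h = 8, 4,
2 mm, consistent with the first-order sharpness of the staircase boundary.

## Metrics

The jet axis is the local centerline direction pointing away from the
pylorus; the throat is the auxiliary-circle chord of the most-occluded
wave. `throat_profile` samples the retropulsive component across that
chord; `jet_report` walks from the chord's velocity maximum along the axis
until the speed has decayed 40 % (censored if the ray exits the fluid
first). Mean |vorticity| is averaged over the antropyloric region, defined
(configurably) as the distal third of the centerline arclength. Pressure
drops are probe differences, invariant under anchoring. The jet-onset
criterion (throat retropulsive speed exceeding k× the wave speed, k = 2) is
a package definition, exposed as configuration.

## Study conditions and problem sizes

The stomach cycle is simulated over the periodic regime t ∈ [38, 58] s at
h = 2.5 mm (≈ 3 × 10³ fluid cells) for the viscosity-direction suite, with
a matched fixed-step window (h = 1.5 mm, Δt = 10 ms, t ∈ [44, 54] s) for
throat-profile comparisons and h = 1.5 mm for the pressure-scaling check —
the coarsest grids at which those two measurements are converged. The
chamber runs use its 20.3 × 20.3 cm midplane at h = 4 mm (8 mm and 2 mm
for the convergence triplet); the 2.3-cm depth is metadata. The hump
profile is the stated single cycloid arch (50 % occlusion, 5.5 mm/s,
4-cm base) smoothed over a 6-mm bending length, since an elastic sheet
cannot form the arch's base cusps (unsmoothed cusps inject ~0.15 m/s
spurious wall velocities).

## What the 2-D reduction does and does not show

The full problem is three-dimensional; this package deliberately solves
the symmetry-plane reduction, whose velocity and vorticity magnitudes are
known to sit about an order of magnitude below the 3-D ones. Accordingly the flow checks are directional, not quantitative:

* **Reproduced:** the antral eddy strength (mean vorticity) is lower and
  the cross-wave pressure drop is far larger (~40×) at 1 Pa·s than at
  10⁻³ Pa·s; the chamber benchmark shows the higher retropulsive core
  velocity, more concentrated at the contracted section, for 20 mPa·s oil
  vs water.
* **Not reproduced — the jet pair.** Both jet directions (higher peak
  retropulsive velocity and shorter 40%-decay length at 1 Pa·s) require
  velocity scales the planar reduction does not reach. The throat flux is
  kinematically forced and identical across viscosities (verified to
  0.2 %), so a higher peak requires a flatter low-viscosity profile (plug
  vs parabolic); at the 2-D velocity scale the watery fluid's throat
  Reynolds number is only ~30, both profiles are near-parabolic (peak/mean
  1.43 vs 1.47), and water's residual inertia leaves its measured peak
  ~9 % higher instead (the margin grows under grid refinement, so it is
  not a discretization artifact). Likewise, a creeping-flow velocity field
  is viscosity-independent under prescribed wall motion, so both jets
  decay at the same geometry-set rate and the 40%-decay lengths are
  statistically indistinguishable (median 0.75 cm for both fluids). The
  two corresponding acceptance tests assert the original directions and
  are expected to fail; the bench chamber, whose Reynolds number is two
  orders higher, does reproduce the peak/localization contrast.

The quantitative 3-D numbers (7.6 cm/s maximum retropulsion, 7.5/11.9 cm/s
jet initial velocities, 2.3/0.2 cm jet lengths, 56 % jet-onset occlusion)
are out of reach of the midplane model by design and are not asserted.

## Known limitations

* The outline calibration trades ~2–8 % of the curvature-wise wave speeds
  for an embeddable (non-self-intersecting) surface; the exact printed
  speed pair is geometrically infeasible under any planar chord pairing.
* The immersed boundary is a first-order staircase; lumens narrower than
  ~2 cells (the near-pyloric throat at high occlusion) are under-resolved.
* Midplane area is not exactly conserved by the 3-D-volume-conserving
  tonic law; the solver absorbs the drift uniformly per fluid component
  and logs it.
* No gastric emptying (closed pylorus), isothermal contents, Newtonian
  rheology only, no wall slip or mucous layer.
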