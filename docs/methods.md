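# Methods

## Problem and model

A stereotactic frame fixes a 3D coordinate system (x, y, z) to the
patient's head; image-guided planning requires mapping target points
measured in a CT slice's 2D (u, v) coordinates into that frame system.
Fiducial localizers mounted on the frame make this possible: each rod of
a localizer produces a fiducial spot in the slice, and the geometry of
the spots encodes where the slice cuts the frame.

`spframe` models two localizer families:

* **Sturm-Pastyr (SP)**: a vertical rod B flanked by two diagonal rods
  A and C forming a V, all three axes coplanar.  At local height h above
  the apex the fiducial spacings of an untilted slice are
  d_AB = d_BC = h·tan α and d_AC = 2h·tan α, so spacing encodes height.
* **N-localizer**: two vertical rods joined by a diagonal; the position
  of the diagonal fiducial between the vertical fiducials encodes the
  crossing fraction along the diagonal.

Frame coordinates are millimetres, origin at the frame-base centre,
+y anterior, +z superior, +x completing a right-handed system.  The scan
plane satisfies z = z0 + y·tan θ, where θ is the anteroposterior tilt
(positive = anterior higher); its in-plane chart is an isometry, so image
distances are 3D distances.

## Solvers

**Classic one-point SP solve.**  Noise-free fiducial centres are
collinear, so the scan line in the localizer plane has two degrees of
freedom: the rod-B height h_B and the local slope m.  From
d_AB = h_A·t·√(1+m²), d_BC = h_C·t·√(1+m²) with h_A = h_B/(1+tm),
h_C = h_B/(1−tm) (t = tan α):

    m   = (d_BC − d_AB) / (t·(d_AB + d_BC))
    h_B = (d_AB + d_BC)·(1 − t²m²) / (2t·√(1+m²))

This is exact for noise-free input at any tilt.  Under noise the slope
estimate divides by the fiducial spacing, so classic accuracy degrades
sharply toward the apex (spacing → 0) and with tilt (the slice cuts the
V asymmetrically).  The solved rod-B point pairs with fiducial B.

**Three-point SP solve.**  Noise breaks collinearity and makes the three
distances linearly independent; matching all three exactly yields one
point per rod.  With s = h_A + h_C, p = h_A − h_C and squared distances
normalized by d_AC², the system reduces to a quadratic in S = s²
(coefficients in the `spframe.sp` module docstring); each real root
determines p and h_B in closed form.  Numerically:

* Collinear input sits exactly at the quadratic's tangency (double
  root), which is simultaneously the point where the three constraints
  become linearly dependent.  Generic root-finding is ill-conditioned
  there (solution sensitivity scales as the square root of the
  collinearity perturbation), but the tangency midpoint −B/2A is
  well-conditioned; algebraically simplified, cancellation-free forms
  recover noise-free heights to ~1e−13 mm.
* All quadratic algebra runs in extended precision (`np.longdouble`),
  and squared distances are accumulated in extended precision directly
  from the (u, v) floats.  The measured noise-free band of the relative
  discriminant is ≤ 3e−19, while genuinely noisy input essentially never
  falls below ~1e−15; the tangency classification threshold of 1e−17
  separates the two regimes.
* Admissible solutions need all heights in [0, extent] and distance
  residuals within tolerance; among them the solver returns the branch
  nearest (summed squared height difference) to the classic collinear
  estimate (h_A, h_B, h_C), with a deterministic larger-h_B tie-break.
  The scalar API polishes candidates with damped Newton iterations in
  extended precision (residual ≤ 1e−9·d_AC); the vectorized Monte Carlo
  path skips polishing, since raw closed-form residuals (≲1e−7 mm) are
  negligible against millimetre-scale noise.
* Degenerate input (d_AC < 1 mm, slice at the apex) and infeasible
  distance triples (negative discriminant: no real placement on the
  rods) raise typed errors; the Monte Carlo counts and excludes such
  iterations per cell (`n_failed`).

**N-localizer solve.**  The three fiducials are collinear at any tilt
(two planes meet in a line), and the fraction f = d_AB/d_AC equals the
crossing fraction along the diagonal rod, so
p_B = top_end + f·(bottom_end − top_end) is exact at any tilt — the
N-localizer is structurally tilt-insensitive.  Vertical rods contribute
(x, y)-only constraints (their frame-horizontal position is constant).

**Registration.**  [x, y, z] = [u, v, 1]·M with M fitted column-wise by
ordinary (unweighted) least squares; (x, y)-only records enter the x and
y columns but never the z column.  At least three non-collinear full
records are required.  The Monte Carlo engine evaluates the same fit via
batched normal equations (one 3×3 solve per iteration), verified in the
tests to reproduce the module-level fit.

## Monte Carlo protocol

Per scenario and slice height: forward-model all localizers, fit the
unperturbed matrix M (through the same batched code path, so zero noise
gives exactly zero error), then per iteration displace every fiducial
centre independently by a bounded random vector, re-solve, refit, and
map the six target points (0,0), (±50,0), (0,±50), (+50,+50) with both
matrices.  RMSe per target is the root mean squared 3D distance between
the two mappings.  Standard errors come from the empirical variance of
the per-iteration squared errors (delta method for the square root).

Noise is uniform over the closed disk of radius 1.0 mm by default (the
natural reading of a "maximum magnitude" bound); per-component uniform
and truncated-Gaussian variants are available, all norm-bounded.

Randomness: one counter-based Philox stream per (seed, scenario id,
height index), so results are bit-reproducible and independent of
execution order; all iterations at a height are drawn vectorized from
that height's stream.

Scenario presets `fig3`–`fig7` encode the published experiment arms
(localizer counts, tilt angles, height ranges, 2 mm height step, six
targets, 1 mm noise).  The published iteration count is 2^21 per height;
the test suite and the acceptance script run 2^14, which resolves the
relational comparisons at ~1% relative standard error per cell.  The
height unit of parallelism makes the full-scale run a matter of minutes
with the vectorized engine (`sweep(..., n_iterations=2**21)`).

Statistical testing: per-cell comparisons across a family of m cells use
a Sidak-style simultaneous threshold calibrated so the family-wise
false-alarm rate matches a single 3-standard-error test (z(1) = 3,
z(456) ≈ 4.3); strict orderings are asserted as "no cell violates beyond
the band" plus the aggregate effect, because a per-cell +3 SE demand
would reject a correct implementation wherever the true gap is below MC
resolution.

## Default geometry

The frame and localizer dimensions are package choices, configurable in
every entry point; they are NOT the manufacturer's dimensions of any
physical frame, which are not published in the sources available to us:

| parameter | default | rationale |
|---|---|---|
| placement radius | 100 mm | head-sized frame ring |
| SP half-angle | tan α = 0.4 | V slope giving d_AC ≈ 0.8·z |
| SP vertical extent | 180 mm | covers z ≤ 155 mm at 10° tilt, where the anterior localizer is cut at local height z + 100·tan 10° ≈ z + 17.6 mm |
| N rod spacing | 120 mm | comparable transverse footprint |
| N rod height | 150 mm | covers z ≤ 130 mm at 10° tilt |

A tilted plane is rejected when it would cut the frame base inside the
placement radius (z0 < radius·tan θ), reproducing the larger minimum
heights of the tilted runs.

## What the simulation does and does not capture

The forward model treats rods as mathematical lines and fiducial centres
as exact plane-line intersections perturbed by bounded 2D noise.  Real
CT data adds partial-volume effects, ellipse-elongation of diagonal-rod
fiducials under tilt, centre-detection bias, scanner distortion and
through-plane averaging — none of which are modelled.  Passing tests
therefore demonstrate the geometric and statistical properties of the
solvers under the stated noise model, not end-to-end clinical accuracy.

## Known limitations and observed deviations

* The three-point solve implemented here matches the three measured
  distances exactly (verified against an independent constrained
  root-finder).  The exact-matching estimator uses the collinearity
  residual — a noise-amplified quantity near the collinear manifold — so
  its per-point height errors (1.2–2.2 mm RMS at 1 mm noise) exceed the
  classic collinear fit's (~1.1 mm); the accuracy gain of 9/12 sets over
  3/4 sets comes from the registration averaging over more
  correspondences.  With this construction the simulated posterior-target
  RMSe of the three-localizer frame at 10° tilt is very slightly LOWER
  for 3 sets than for 9 sets (by ~0.04 mm, reproducible across seeds)
  over a band of mid-range heights — a reversal invisible at the 1.2 mm
  scale of the published curves but resolvable at n = 2^14.  The
  corresponding ordering test documents this as an open discrepancy.
* The SP-versus-N comparison (difference of mean RMSe over the
  overlapping height window) is geometry-dependent; with the default
  dimensions above it measures ≈ 0.18 mm, larger than the published
  0.1 mm.  The deviation is consistent with the invented dimensions
  (e.g. a wider V or a different N footprint changes both arms) and is
  reported as computed rather than calibrated away.
* Tilt does not degrade accuracy uniformly: at the anterior target and
  the lowest heights of the tilted three-localizer range (z = 21–27 mm),
  a 10° tilt IMPROVES the RMSe by 0.01–0.05 mm, because the tilted plane
  cuts the anterior localizer ~17.6 mm higher — away from the apex —
  and near the bottom of the range that conditioning gain outweighs the
  degradation of the other localizers.  The effect follows directly from
  the near-apex blow-up and is below the resolution of the published
  curves; the corresponding cell-wise monotonicity test documents it.
* The N-localizer tilt-equality comparison is restricted to heights
  where the slice crosses every rod at least 6 mm from its ends under
  both tilts; nearer the ends, out-of-rod fraction estimates are
  excluded as failures and the clipping biases the surviving RMSe.
* Near the apex (z = 5 mm) a few percent of noisy iterations are
  infeasible for the exact three-point system and are excluded from the
  RMSe; the published protocol's handling of such draws is not described
  in the available text.
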