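# Methods

## Contact model

Both bones are rigid triangulated surfaces; all compliance lives in a bed
of independent normal springs (an elastic-foundation / Winkler model — no
shear coupling between neighbouring springs). One spring per talar
triangle is cast from the triangle centroid along the triangle normal to
the first intersection with the tibial surface; the ray length is the
local cartilage gap `h_i`. The casting is a vectorised Moller-Trumbore
intersector that accepts front- and back-face hits (the articular sheets
are open), treats rays within 1e-12 of parallel to a triangle plane as
misses, and takes the nearest hit with ray parameter above 1e-12.
Barycentric coordinates are accepted with a 1e-9 slack so rays passing
exactly through shared edges still register.

Springs longer than the threshold `h_T` are removed from the computational
domain for that time point ("nominal contact region"). A length exactly
equal to `h_T` is kept: the removal rule is read strictly as "longer
than". `h_T` defaults to 3.5 mm, twice the thickness of a typical
undeformed tibiotalar cartilage layer.

Spring stiffness follows the confined-compression elastic-foundation
estimate

    k_i = s(nu) * E * A_i / h_i,   s(nu) = (1 - nu) / ((1 - 2 nu)(1 + nu))

evaluated at the *current* gap, so stiffness is strain-dependent: a spring
whose gap has closed is stiffer. Defaults: E = 10.35 MPa, nu = 0.4247,
homogeneous over the joint. Gaps below 1e-3 mm would make the stiffness
diverge; they are reported as an interpenetration error rather than
clamped, because they indicate broken geometry, not physics.

## Equilibrium and tension release

The talus has three translational degrees of freedom; rotations are pinned
to zero. Sign convention (pinned here once): the spring direction `n_i`
points from talus toward tibia; positive spring force means compression
pushing the talus back along `-n_i`; with `G(v)` the force the ligaments
exert on the talus at cumulative translation `v`, equilibrium on the
active set `S` reads

    F - sum_{i in S} [k_i (n_i . u) + f_i^{t-1}] n_i + G(u_cum + u) = 0.

The 3x3 tangent `K = sum k_i n_i n_i^T + K_lig` is assembled and the
system solved by Newton iteration (the ligaments are tension-only, hence
piecewise linear; convergence is typically 1-3 steps). Newton steps use a
minimum-norm least-squares solve so that rank-deficient but consistent
systems — e.g. parallel plate normals under a purely normal load — solve
cleanly; an under-constrained error is raised only when the residual
cannot be reduced below tolerance. After each converged solve, springs
with `f_i <= 0` are released (all of them per pass by default; a
one-per-pass variant exists for conservative active-set descent) and the
solve repeats on the reduced set. Springs are never re-admitted within a
time point. The default residual tolerance is `1e-8 * max(1, ||F||)` N;
the active-set iteration cap defaults to the initial nominal spring count
(each pass removes at least one spring).

Edge cases, decided once and tested:

- **Zero problem.** `||F|| = 0` with zero stored forces and slack
  ligaments returns the zero solution without running the loop.
- **Zero load with stored state.** This is the unloading limit — the
  stored push-back forces must drive the talus back, so the full solve
  runs. In the uniform-unload limit all spring forces pass through zero
  together, the release rule empties the active set, and the solution is
  accepted with an empty active set if the remaining (ligament-only)
  residual meets tolerance; otherwise a lift-off error is raised.
- **Stiffness update.** By default `k_i` is held at its start-of-step
  value during the active-set iteration ("lagged"): gaps are refreshed
  between time points, not inside a solve. A `within_step` mode that
  recomputes `k_i` from the deformed gap each pass is provided for
  comparison.

Contact pressure is `f_i / A_i` (the spring force is already normal to its
triangle); active contact area is the summed area of compressed triangles,
reported in cm².

## Classical vs extended time stepping

Per frame the tibia (and the ligaments' fixed endpoints, configurable) is
re-posed from the *reference* pose to the frame's absolute dorsiflexion
angle about the joint axis — absolute, not incremental, so no drift
accumulates. Springs are recast and re-thresholded every frame because the
relative pose changes. The joint contact force is applied as a point load;
with translation-only equilibrium only the force vector matters, so the
application point (talus centroid) is recorded but torque balance is not
enforced.

- **DEM**: stored forces are identically zero and the computed
  displacement is discarded after evaluating forces; the talus never
  leaves the reference pose. Frames are independent.
- **EDEM**: the talus is translated by the computed increment, the active
  springs' forces are stored as next-step push-back forces (released and
  over-threshold springs carry zero into the next step), and all springs
  are made available again for the next cast. Stored forces live per talar
  triangle, so they survive the recast.

With zero state the extended equations reduce exactly to the classical
ones, so the two methods coincide on the first frame — asserted to 1e-12.

## Joint axis

The dorsiflexion/plantarflexion axis is the axis of the least-squares
cylinder fitted to the talar triangle centroids (centroids, not vertices:
they are the quantities the contact model actually uses). The fit
optimises the axis direction over its two spherical angles with
Gauss-Newton (`scipy.optimize.least_squares`), recovering the circle
centre and radius in the orthogonal plane by a linear Kasa fit at each
step; initial directions are the three principal axes of the centroid
covariance and the best converged candidate wins. Coplanar or collinear
inputs and fits whose radius vastly exceeds the data extent are rejected
as degenerate. On exact cylinder samples the axis is recovered to
~1e-9 mm; with 0.01 mm isotropic noise the direction stays within 0.1
degrees over repeated draws.

## Ligaments

Four bundles (anterior/posterior tibiotalar, anterior/posterior
talofibular) of parallel fibres, each a linear tension-only spring
(`T = (E A / L0) max(dL, 0)`, E = 255 MPa, fibre area 1 mm², 5 fibres per
bundle by default — fibre area and count are not anatomically constrained
and are config-exposed). Rest lengths are captured at the reference pose
with zero pre-strain. Ligament forces enter the equilibrium balance
(disable-able); they are evaluated at the current cumulative pose and
carry no history of their own — the springs carry the memory. The tangent
contribution includes both the material term and the geometric
`(T/L)(I - d d^T)` term, which is what gives near-vertical fibres their
lateral stiffness.

## Anatomical frame and gait input

The anatomical frame is +x anterior, +y superior, +z lateral (right
side). Gait CSVs carry signed clinical components (medial/lateral,
posterior/anterior, superior/inferior); the sign mapping (default:
positive = medial -> -z, positive = posterior -> -x, positive = superior
-> +y) is a configurable `ColumnMap`, because the reporting convention of
a gait table is not an anatomical fact. Time may be seconds or percent
stance; internally frames are an ordered sequence and must be strictly
increasing. A packaged seven-row table of measured stance-phase angles and
forces (peak superior force 4078.26 N at 78 % stance) drives the
`table1_like` profile by piecewise-linear interpolation; the `half_sine`
profile is an idealised ramp with a linearly ramping angle.

## Synthetic joints

The generator produces four joint archetypes with known analytic
properties (see README). Default dimensions give articular areas of a few
cm² — the scale of an adult tibiotalar joint — and triangle areas of order
0.1 mm² at the highest test resolutions. The depression fixture raises
tibial vertices inside two circles; on the matched grids used, a talar
centroid ray meets the covering tibial face at its centroid, so the gap is
`gap + depth * k/3` with `k` the face's raised-vertex count and the
over-threshold set is exactly the faces with `k >= 2` — computed
geometrically and exposed as fixture metadata. The default extra depth
(2.7 mm on a 2.5 mm gap) keeps every face class a finite margin away from
the 3.5 mm threshold so the classification is not a knife-edge float
comparison, and keeps the depression faces above threshold under the
largest talus settlement the default loading produces (~0.6 mm).

What the fixtures do **not** emulate: real trochlear asymmetry, cartilage
thickness maps from imaging, fibula kinematics, and measurement noise in
the gait series. Passing tests therefore demonstrate the correctness of
the machinery (casting, thresholding, equilibrium, state transport,
sensitivity sweeps) and the directional physics (area recruitment,
push-back return, threshold-driven inactive regions), not agreement with
any subject's absolute pressures.

## Sensitivity analysis

Peak contact pressure is swept over a uniform rectilinear grid of the
length threshold `h_T` in [2.5, 4.5] mm and ligament modulus `E_lig` in
[200, 350] MPa (20x20 by default; the test suite uses 5x5 to stay fast).
The response at a grid point is the maximum over the stance of the
per-frame peak pressure, recomputed by a full stance run with the
overridden parameters; points are independent and order-invariant, and a
failing run is recorded with its reason rather than aborting the sweep.
Gradients are central differences in the interior and one-sided at the
edges; failed points and their stencil neighbours are masked. Cartilage
modulus and Poisson ratio are deliberately excluded from the sweep: a
single stateless solve is exactly homogeneous in `E` (pressures invariant,
displacement ~ 1/E — asserted as an invariant for the DEM step without
ligaments), and `nu` enters only through the analytic factor `s(nu)`. For
the state-carrying extended method with ligaments this homogeneity is not
an identity and is left as an experiment, not an invariant.

## Problem sizes and numerical choices

Test and acceptance runs use 200-800 triangles per surface and 5-21
stance frames; mesh convergence is demonstrated on 128/512/2048/8192
triangle levels, where peak pressure changes by ~0.2 % and active area by
~0.01 % between the two finest levels. All computations are deterministic
given inputs; two identical runs produce bit-identical results.

## Known limitations

Rigid bones, translation-only talus (no rotations, no torque balance),
elastic springs (no viscoelasticity or biphasic behaviour), a single
combined cartilage layer per spring, linear tension-only ligaments without
toe region or wrapping, and no fibula as a separate body. Lateral (axis-
direction) loads on a cylindrical joint are structurally unsupported by
the spring bed and are resisted only through ligament geometric
stiffening; such load cases fail loudly rather than silently.
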