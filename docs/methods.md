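# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `airwaykit`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and unit conventions

Voxel arrays are indexed `[i, j, k]` along `(x, y, z)` with 0-based indices
mapping to world coordinates at voxel centers, `world = origin + index ·
spacing`. All geometry is in millimeters; airflow quantities cross into SI
internally (m, m/s, Pa) and are reported in the field's customary mixed
units (mm², mm³, ml/s, m/s, Pa). Arclength `s` runs rostral → caudal,
starting at 0 at the rostral end of the centerline. Station labels around
the hard-palate anchor are signed offsets with positive = rostral, so label
`o` sits at arclength `s_anchor − o`. Inspiration is positive flow in
breathing traces.

## Synthetic phantoms

The phantoms stand in for animal micro-CT data that studies of this kind do
not deposit. They emulate the *geometry and measurement chain*, not CT
physics: no beam hardening, photon noise, partial-volume blur, motion, or
respiratory gating. Passing tests therefore demonstrate the correctness of
the algorithms on ideal data at known resolution; they do not certify
robustness to scanner artifacts.

* **Intensity model**: three levels — lumen −1000, soft tissue 0, bone
  +1000 (HU-like) — with a thin bone shell around the lumen, enough to
  exercise the inversion + threshold + seeded-component segmentation route.
* **Voxelization**: a voxel is lumen if its center lies within the analytic
  surface (inclusive). A discretization note: when the radius is an exact
  integer multiple of the spacing, lattice points fall exactly on the
  surface and the inclusive rule grows single-voxel spurs that measurably
  distort flow resistance (~10% on a 16-voxel-diameter tube). Benchmarks
  therefore use non-integer radius/spacing ratios; real anatomies never hit
  this degeneracy.
* **Default spacing** is 0.02 mm, the 20 µm reconstruction voxel typical of
  high-resolution in-vivo micro-CT. Tests and the acceptance script run
  most phantoms at 0.04–0.08 mm — the coarsest spacing at which each
  measured quantity stays inside its validation tolerance — and reserve the
  native 0.02 mm for the sub-voxel area checks.
* **Mouse airway**: parametric, not anatomical. A straight axis (curvature
  is an option, default 0°) carries circular cross-sections whose area
  follows pchip-interpolated control points: ~2.2 mm² in the nasal cavity,
  a nadir of 0.75 mm² at 1 mm caudal to the hard palate, recovering to
  ~1.1 mm² near the epiglottis. Landmark stations: meatus merge 4.0 mm,
  hard-palate caudal edge 9.0 mm, epiglottis 14.5 mm, arytenoid 14.8 mm,
  total length 16 mm. These defaults give airway-scale ground truth (nasal
  volume ≈ 18.6 mm³, pharyngeal volume ≈ 4.9 mm³, pharyngeal length
  5.8 mm) matching the magnitudes published for wild-type mice. The
  `scale_factor` knob scales cross-sectional radii uniformly (areas ×
  factor²) and serves as the "genotype" contrast. An optional left/right
  nasal split models the paired nasopharyngeal meatuses merging at the
  meatus-merge station; its ground-truth area uses the exact two-circle
  union formula.
* **Breathing traces**: half-sine inspiration of duration Ti = ti_fraction/f
  and amplitude πTV/(2Ti) (integrating exactly to TV), half-sine expiration
  returning volume to baseline; volume is the cumulative trapezoid of the
  (optionally noisy) flow. Defaults (TV 0.269 ml, 180/min, ti_fraction
  0.24) were chosen so Ti = 80 ms and PIF = 5.28 ml/s, the breathing scale
  reported for awake wild-type mice.
* **Cohorts**: independent per-measure normal draws with specified group
  moments — the exact sampling model behind a published (mean, SD, n)
  table, with no between-measure correlation.

## Segmentation

Inversion is exact negation. The automatic threshold is Otsu on the full
inverted histogram; a fixed threshold is exposed for parity experiments
(published workflows typically hand-tune it). Foreground is *strictly
above* threshold, making a rising fixed threshold monotone (never adds
voxels). The seed's 26-connected component is kept — 26-connectivity lets
thin nasal passages survive — and holes are filled per axial slice rather
than in 3-D so genuine side channels are not sealed.

## Centerline

Published airway workflows trace the central axis manually; reproducibility
needs an algorithmic default. The mask is thinned (3-D skeletonization),
skeleton voxels become a graph with 26-neighbor edges weighted by physical
distance, and the centerline is the Dijkstra shortest path between the
skeleton nodes nearest the user's endpoints. Because thinning erodes open
tube ends by roughly a lumen radius, the path is bridged straight to the
supplied endpoints. The polyline is resampled at half a voxel and smoothed
with a moving average; the window parameter defaults to 0.2 mm but is
floored at 10 voxel spacings, because the discrete skeleton zigzags at the
half-voxel scale and an under-resolved window inflates arclength by ~0.6%
— enough to violate the one-voxel length-recovery tolerance on coarse test
grids. At the native 20 µm voxel the floor coincides with the 0.2 mm
default. Endpoints stay pinned during smoothing. A user-supplied polyline
(`Centerline.from_points`) bypasses extraction entirely.

Measured on phantoms: straight-tube length within 0.5%, axis deviation
under one voxel, quarter-torus (R = 5 mm) arclength within 0.15%, mouse
pharyngeal length within ~0.3 voxel.

## Cross-sections and volumetry

A section at arclength `s` samples the mask with nearest-neighbor
interpolation on a plane through the centerline point, normal to the local
tangent, at a pitch of half the voxel spacing; the area is the in-plane
4-connected region containing the centerline point. The in-plane grid
extent is estimated from the mask voxels in a thin slab around the plane.
Sections clipped by the volume boundary are measured over the in-volume
part and flagged `truncated` (with a warning); stations outside the
centerline range are flagged `missing` rather than raised, so a station
battery near an end degrades gracefully. At 20 µm voxels the digital
r = 0.5 mm cylinder measures π r² within 0.5%, and a 30°-tilted cylinder
still measures π r² (not the πr²/cos 30° axial ellipse) — the essential
property of curved-plane reformation.

Voxel-to-segment assignment for volumes uses the arclength of the nearest
centerline vertex — well-defined for curved airways and exactly additive
across segments by construction. The nasal segment spans the nostrils to
the hard palate; the pharyngeal segment spans the hard palate to 5 mm
caudal of it (or the centerline end, whichever is rostral). Whether the
"nasal cavity" should instead end at the meatus merge is not standardized;
the hard-palate convention is used consistently for both volumes and the
1-D/3-D flow summaries.

## Airflow

Flow is modeled as steady, Newtonian, homogeneous and incompressible, with
air at 20 °C (ρ = 1.204 kg/m³, μ = 1.825 × 10⁻⁵ Pa·s; configurable — studies
rarely state their values). Boundary conditions: pressure 0 Pa at the
nostrils, constant volumetric flow Q at the outlet (default 5.28 ml/s).
Using one constant Q for all subjects makes the computed pressures a pure
function of airway geometry.

**Quasi-1-D model.** Mean velocity v(s) = Q/A(s); pressure from Bernoulli
exchange plus a Poiseuille loss for the circular-equivalent radius,
integrated by trapezoid over the supplied stations. For a constant-area
tube this reduces to Hagen–Poiseuille exactly (quadrature error < 0.1% at
1000 stations). Pressure is monotone non-increasing in non-expanding ducts;
the viscous component is exactly linear in Q.

**Voxel-grid solver.** A marker-and-cell staggered grid over the lumen
voxels: pressure at cell centers, velocities on faces. Pseudo-transient
projection: explicit predictor (first-order upwind convection, central
diffusion with no-slip ghosts at the staircase walls), a pressure Poisson
solve (7-point operator; Dirichlet p at the inlet faces, homogeneous
Neumann elsewhere; sparse LU below 120k cells, otherwise ILU-preconditioned
CG warm-started across steps), then a face-velocity correction that renders
the discrete divergence zero to machine precision — so the volumetric flux
through *every* transverse plane equals Q exactly. The outlet face carries
a uniform Dirichlet velocity delivering Q; the region within two hydraulic
diameters of it is excluded from Vmax extraction because the imposed plug
profile generates local transverse artifacts. Convergence is declared when
the dimensionless momentum residual `max|du|/dt · h²/(ν·u_ref)` falls below
`grid_tolerance` (default 10⁻³; benchmarks use 10⁻⁴). The time step is
0.15 h²/ν capped by a CFL bound, and the flow-axis velocity is initialized
with a wall-distance-squared profile scaled to Q per slice — close to the
developed laminar profile, so iterations mostly relax staircase detail (the
steady solution is independent of initialization). The solver estimates the
Reynolds number at the narrowest transverse section and warns above 2000;
there is no turbulence closure.

Benchmarks (Re < 1, 16.7 voxels/diameter): ΔP within 1.6% of
Hagen–Poiseuille, centerline peak speed 1.98× the mean (parabolic profile),
flux error at machine precision, error decreasing monotonically over
8 → 16 → 32 voxels/diameter, and ΔP linear in Q within 3%. On a venturi,
the speed peak coincides with the minimum-area station.

**Summaries.** Vmax regions: "nasal" = nostrils → meatus merge,
"pharyngeal" = hard palate → epiglottis. Pmax is the station-averaged
pressure at the epiglottis (robust to single-voxel outliers); the pointwise
minimum is also reported. Segment drops are differences of station
pressures and telescope exactly to Pmax − P_inlet.

Absolute pascal and m/s values for real airways are **not** reproducible
from published descriptions (mesh, discretization and turbulence settings
of commercial CFD packages go unreported); only the physics assumptions,
boundary conditions, and directional/relative statements are. Accordingly
the narrowing contrast is validated directionally: 0.8×-scaled sections at
fixed Q give strictly larger |Pmax|.

## Plethysmography

Quiet wakefulness = maximal movement-free intervals of ≥ 5 s (inclusive).
Breath detection uses hysteresis-guarded zero crossings: a breath starts
when flow rises through +band (band = 5% of the 95th-percentile |flow|,
configurable) and each onset is then refined back to the true upward zero
crossing so the band does not clip the inspiratory lobe. Ti/Te are
crossing-to-crossing durations; TV integrates the inspiratory lobe
including its zero-crossing boundary samples; PIF/PEF are lobe extrema.
Breaths crossing an epoch border are discarded whole. The plausibility
filter excludes TV < 0.05 or > 2.0 ml with *strict* inequalities (the
bounds themselves are retained) and is idempotent. RR = retained breaths /
extracted quiet time; MV = mean TV × RR by construction.

On noiseless traces across TV ∈ [0.05, 0.5] ml, RR ∈ [60, 300]/min,
ti_fraction ∈ {0.3, 0.5}, all seven parameters are recovered within 2%.
One boundary subtlety: a true TV of exactly 0.05 ml is measured a few
parts in 10⁵ low by any quadrature, so its survival of the strict filter
is a knife-edge; the recovery characterization therefore runs the
detection chain with the filter disabled, while the filter's boundary
semantics are asserted exactly on constructed breath tables.

## Statistics

Welch's t with Welch–Satterthwaite df, two-sided p from the t distribution
(no multiple-testing adjustment by default, matching how such tables are
published; Holm adjustment is available). The summary route and the
raw-sample route agree to machine precision by construction, and p matches
an independent quadrature of the t density to 10⁻⁶. Degenerate inputs
(both SDs zero) resolve by the means, with a warning when p = 0.

Recomputing published P values from printed summary rows reproduces them to
the printed precision within ±0.003: the residual (e.g. 0.0159 vs a printed
0.018) is fully explained by the printed means/SDs being rounded to two
decimals while the original analysis used raw data.

Calibration (by simulation): null rejection at α = 0.05 is 0.05 ± 0.01
over 2000 large-sample replicates; cohorts drawn from a large published
effect (frontal-bone length, n = 8/7) reject at p < 0.001 in > 90% of
replicates.

## Pipeline

One YAML config drives phantom-or-volume → segmentation → centerline/areas
→ cohort morphometry → airflow → plethysmography → statistics. Every stage
logs its full parameter set (unstated settings are the usual cause of
irreproducible imaging pipelines); the log carries no timestamps, so a
rerun with the same config and seed is byte-identical. A stage failure
raises an error naming the stage and leaves earlier outputs intact. The
default airflow solver in the pipeline is the quasi-1-D model; the 3-D
solver is selected per config.

## Known limitations

* Phantoms are geometric ideals; no CT physics, soft-tissue contrast
  ambiguity, or motion (rescans for motion artifacts are an acquisition
  remedy, outside computation).
* The mouse phantom's landmarks are functional, not anatomical — the
  26 craniofacial landmark *definitions* live in study supplements and are
  not modeled; morphometry validation is purely geometric.
* Laminar solver only; at the study's physiological Q (5.28 ml/s through
  ~1 mm² sections) airway Reynolds numbers reach a few hundred —
  transitional effects and secondary flows in real, non-circular anatomy
  are not captured by the 1-D model and only partially by the voxel grid
  at practical resolutions.
* No fluid–structure interaction: airway collapse and critical closing
  pressure (P_CRIT) are out of scope.
* Parity with commercial instrument software (breath segmentation) and
  commercial CFD packages is not claimable; their algorithms are
  proprietary/unreported.
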