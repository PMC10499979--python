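# Methods

This note documents the models, conventions and numerical choices behind
`stonemesh`, the assumptions they rest on, and what the synthetic validation
does and does not establish.

## The mesh model

The index treats stone fragmentation as crack-making on a rectangular grid.
A target stone unit is a cube of edge `target_size` (default 5 mm, the
fragment size an 18F percutaneous channel clears without further crushing).
A stone is described by graded levels: each sampled CT level's orthogonal
measurements (x = maximum in-plane diameter, y = maximum diameter
perpendicular to the x chord) are mapped to unit counts by

```
grade(m) = floor(m / target_size) + 1
```

a half-open binning in which (0, 5) mm → 1, [5, 10) → 2, [10, 15) → 3, and a
value exactly on a bin edge takes the higher grade. The amount of stone is

```
Q = sum_i [ x_i (y_i - 1) + y_i (x_i - 1) ]            (within-level cracks)
  + sum_i [ min(x_i, x_{i+1}) * min(y_i, y_{i+1}) ]    (between-level cracks)
```

in dimensionless units "u" (a count of 5 mm × 5 mm target cross-sections; we
deliberately do not attach a physical area to u). For a solid block of
a × b × c target units, Q equals the number of internal faces between unit
cubes, (a−1)bc + a(b−1)c + ab(c−1) — the test suite checks this equivalence
exhaustively for a, b, c ≤ 6 against a brute-force face count. Q is additive
over stones, monotone in every unit grade, and zero exactly for a
single-level (1, 1) stone, which already fits the channel.

The between-level rule — the product of the per-axis minima of the two
adjacent graded pairs — is the shared-cross-section reading of "the product
of x and y": the column of units both levels contain. It reproduces every
inter-level term of the worked eight-level example (4×4, 4×4, 4×3, 4×3,
7×4, 8×4, 6×4) and its 423 u total.

`target_size` and `level_step` are free parameters: a narrower channel needs
a smaller target and, to measure it, proportionally finer CT spacing
(`GridSpec` enforces `level_step <= target_size`).

## Mask measurement conventions

- **Axes.** Masks are indexed (z, y, x) with slice 0 the most superior
  level; bottom-up scanning reverses slice order. Spacing is (dz, dy, dx)
  in mm, default isotropic 0.7 mm (the CT-urography reference distance).
- **Connectivity.** 3-D stones are 26-connected; in-plane components are
  8-connected — the standard morphometry choice.
- **Boundary and diameters.** In-plane measurements are taken on the
  0.5-level marching-squares iso-contour of the (padded) binary section.
  Contour vertices interpolate midway between foreground and background
  pixel centres, making them a nearly unbiased sub-pixel boundary estimate
  for rasterized shapes; x is the exact maximum pairwise distance over the
  contour's convex hull, y the hull's extent perpendicular to the x chord
  (projection width, since chord-based y is not otherwise specified by the
  measurement protocol). Two residual artefacts are accepted and tested
  with matching tolerances: max-Feret over a zigzag contour overshoots a
  smooth boundary by a fraction of a pixel, and marching squares chamfers
  right-angle corners by half a pixel.
- **rectangle_mode.** For near-rectangular sections the axis-aligned length
  and width can be measured instead of the diagonal; this mode makes
  axis-aligned cuboids exact and is off by default.
- **Level sampling.** Every k-th slice with k = round(level_step / dz)
  (k = 7 at 0.7 mm), starting at the first slice containing stone in the
  scan direction. A stone spanning ≤ k slices yields one level holding its
  maximum-area cross-section. Sub-target stones (every measured x and y
  below `target_size`) are dropped entirely.
- **Branched sections.** If a 3-D stone shows several discontinuous
  surfaces at one level, each component is measured separately and their
  within-level cracks are added; between-level pairing uses the largest
  (principal) component's graded pair, as the protocol does not specify
  pairing for branched sections. Disjoint 3-D stones are always separate
  series whose Q values add.
- **Observer averaging.** Two observers' series are averaged in millimetres
  before grading; averaging after grading can differ by a whole unit when
  the observers straddle a bin edge, so the order is fixed.

## Phantoms

Phantoms are unions of analytic primitives rasterized at voxel centres:
ellipsoids (ordinary calculi), cuboids (exact closed-form checks), and
unions of 3–6 overlapping rotated ellipsoids standing in for branched
staghorn morphology — irregular enough to exercise the model, with no claim
of anatomical fidelity. Ground truth records the analytic volume (voxel
volume for overlapping unions, where no closed form exists) and the maximum
diameter from the 3-D convex hull of surface voxels.

The voxel grid's origin is jittered by a seeded sub-voxel offset: a scanner
grid has no privileged phase relative to a stone, and a pinned phase was
found to bias top-down vs bottom-up sampling systematically (the first cut
into the stone always landed at the same depth from one side). All
generation is deterministic given the spec, including the jitter;
`align_grid=True` pins voxel boundaries to the shape extent so that aligned
cuboids rasterize exactly.

The cohort battery draws the dominant semi-axis log-uniformly from 4.5 to
17 mm, giving volumes from roughly 10² to 1.6 × 10⁴ mm³ and Q from a few u
to ~540 u — matching the spread reported for PCNL cohorts (volumes
237–15,028 mm³, Q 4–525.5 u). Defaults: 25% staghorns, 15% with a second
disjoint stone, and (where enabled) 6% sub-target pebbles to exercise the
ignore rule.

## Volume calibration

Summing x·y·dz over every native slice gives a bounding-box-like volume
estimate; ordinary least squares of true volume on this sum yields the
shape coefficient k. For elliptical cross-sections the true area is
(π/4)·x·y, so k → π/4 ≈ 0.785 as spacing shrinks; on 30 single-ellipsoid
phantoms at 0.5 mm spacing the fitted slope lands near 0.77 (the residual
shortfall is the max-Feret overshoot described above) with R² > 0.999.
The intercept fit is the default for fidelity to conventional reporting;
the through-origin slope, which is the physically cleaner estimate, is
reported alongside. The noiseless phantom fit is necessarily tighter than
any clinical calibration, which carries observer and segmentation noise on
both axes.

## Cohort simulation and the regression study

Each synthetic patient couples a measured phantom to an outcome:

- predictors (Q, volume, maximum diameter) are resampled from a seeded,
  pre-measured phantom library (`phantom_predictor_pool`), so the three
  share the correlation structure of real geometry rather than being drawn
  independently; building the library once and reusing it across cohorts
  avoids re-rasterizing thousands of identical phantoms;
- the **volume predictor** carries a lognormal error of sd 0.18, emulating
  threshold-segmentation 3-D volumetry (partial-volume and threshold
  sensitivity put CT stone volumetry at roughly the 15–20% level). Without
  it, Q and exact analytic volume — two cross-section-area integrals of the
  same smooth shape — correlate at 0.995, far above what distinct clinical
  measurement chains show;
- lithotripsy time follows `time = time_per_u * Q + operator_offset *
  1[operator = "wyy"] + eps`, with `time_per_u` = 4.3 s/u (a ~120 u stone
  takes ~500 s) and `operator_offset` = 100 s. The noise is mildly
  heteroscedastic — per-record sd = `noise_sd` · clip(√(Q/Q̄), 0.35, 1),
  `noise_sd` = 390 s — because a homoscedastic sd of this magnitude drives
  small stones' times negative, and clipping them attenuates the recovered
  slope by ~7%. The sd was set so the Q-model adjusted R² sits near the
  0.72 operating point of the clinical study;
- Hounsfield values are drawn N(1162.51, 176.63²) truncated positive and
  classified soft (≤ 677.5), hard (≥ 970) or mid; hardness has **no**
  generative effect on time, encoding the clinical null finding;
- operator labels are Bernoulli with the 69/112 caseload split.

Time is linear in Q *by construction*: this encodes the working hypothesis
that crack count drives laser time. The regression study therefore tests
the machinery and the ordering logic, not the hypothesis itself. Under
these defaults, across independent 100-cohort batteries the adjusted-R²
ordering Q > volume > max diameter holds in 93–96% of cohorts (mean values
≈ 0.75 / 0.71 / 0.49) and the stone-type effect is null in 93–96%.

Model reports follow conventional OLS practice: standardized betas
b·sd(x)/sd(y), t and p per term, variance-inflation factors from the full
design matrix, adjusted R² and the model F. Dummy coding takes the hard
stone type and operator "gl" as references so rows align with the usual
Operator-wyy / Stone type-mid / Stone type-soft presentation. "Stone type
has no effect" is judged by the partial F-test on both hardness dummies
jointly — the correct test of a categorical effect (two independent 5%
per-dummy tests would fail jointly ~10% of the time under the null by
construction). The paired direction test is a two-sided paired t-test;
identical lists short-circuit to (t = 0, p = 1) rather than scipy's NaN.

## What the synthetic validation does not show

Phantoms are smooth, noise-free, perfectly segmented binary masks: no HU
texture, no partial-volume blur, no segmentation error on the mask itself,
no human measurement variability. Passing tests therefore establishes the
arithmetic, the measurement geometry and the statistical machinery — not
clinical accuracy. The clinical coefficients (k = 0.715, adjusted R²
0.716/0.661/0.471, t = 0.933) depend on patient scans and are not
reproducible here; the package asserts their structural counterparts
(k → π/4, the R² ordering, a null direction test) instead.

## Problem sizes and runtime choices

Default validation sizes — a 240-phantom predictor library, 50-phantom
direction suite, 30-ellipsoid calibration battery at 0.5 mm, 100 cohorts of
n = 112 — run in seconds to a couple of minutes on one core and give the
Monte-Carlo margins quoted above; they are the package's chosen operating
sizes, and all are parameters.

## Known limitations

- Q inherits the grading's +1 per axis, so very small retained stones grade
  coarsely; whether a floor should apply to tiny stones is left open and no
  extra rule is imposed.
- The between-level min-product is an inference from the worked example;
  other readings of "the product of x and y" (e.g. upper-level product)
  would change Q for strongly tapering stones.
- y is projection width, not the longest perpendicular chord; for concave
  sections the two differ.
- Staghorn phantoms are ellipsoid unions; real dendritic calculi are more
  complex, and the rotation-tolerance bound (≤ 15% change under a quarter
  turn) reflects grid anisotropy of the grading, not measurement error.
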