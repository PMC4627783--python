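# Methods

## Problem and model

`uterosnake` segments the uterus in 2-D grayscale laparoscopic-ultrasound
(B-mode) frames from a handful of clinician-drawn border points, then turns
the segmentation into morphometric measurements and agreement statistics.

The segmentation front is a closed parametric snake x(s) minimizing

    E = ∫ E1(x) ds + α ∫ E2(x) ds

with internal energy E1 combining membrane (tension) and thin-plate
(stiffness) terms, discretized with unit vertex spacing as

    E1 = ½ Σᵢ ( |xᵢ₊₁ − xᵢ|² + β |xᵢ₊₁ − 2xᵢ + xᵢ₋₁|² ),

and image energy coupling the front to bright, high-gradient pixels,

    E2(x) = −( (G(x)/G_max)² + (I(x)/I_max)² ),

where G is the Gaussian-derivative gradient magnitude at scale σ
(`gradient_sigma`) and I the intensity sampled at the same scale. Both
terms are normalized by their image-wide maxima so E2 ∈ [−2, 0] and the
two terms are commensurate. Negating the bracket makes minimization
attract the front to the border.

Two points deserve emphasis:

* **Normalization.** A literal per-pixel normalization G/|G| would be
  constant; the image-wide-maximum reading is the only one that yields a
  usable field. The intensity term is sampled at the analysis scale σ
  rather than per pixel because under fully developed speckle individual
  bright spikes would otherwise dominate I_max and pepper the interior
  with spurious attractors.
* **Intrinsic localization bias.** Because ĩ² increases monotonically into
  a bright organ while g̃² peaks on the border, the minimum of E2 along
  the border normal sits slightly *inside* the true edge — roughly σ/2 for
  a step edge. Smaller σ localizes better; larger σ captures from farther
  away and suppresses noise. This trade-off drives the protocol choices
  below.

## Initialization and evolution

The initial front is the convex hull of the seed points, resampled to
`n_vertices` equal arc-length vertices (counterclockwise). Evolution is
the classical semi-implicit scheme: the internal term is solved exactly
through the cyclic pentadiagonal system — diagonalized here by FFT, which
is exact for circulant operators — while the image force α·(−∇E2),
bilinearly interpolated, is applied explicitly with step `step_size`.

Three numerical safeguards:

* **Monotone descent.** The interpolated force is not the exact derivative
  of the monitored (interpolated) energy, so a raw step can raise E by
  O(1e−3) near equilibrium. Each step is therefore accepted only if the
  total energy does not increase, with up to four step halvings; a step
  that fails at every scale marks a numerical fixed point and stops the
  stage. The recorded `energy_trace` is non-increasing within each stage
  by construction.
* **Reparameterization.** Vertices are re-spaced to uniform arc length
  every `reparam_interval` (10) iterations to prevent clustering, but a
  re-spacing that would raise the energy is skipped and retried later.
* **Bounds.** Vertices leaving the image are clamped with a warning.

Evolution stops when the mean vertex displacement per iteration falls
below `tol`, or at `max_iters`.

### Contour resolution

With the unit-spacing discretization, the discrete tension force on a
circle of radius R sampled at n vertices is R(2π/n)² — it *grows* with
organ size at fixed n, and at n = 100 it exceeds the maximum image force
available from a normalized edge well for R ≳ 30 px, collapsing large
contours. The pipeline therefore resamples the front to roughly one vertex
per pixel of hull perimeter (`vertex_spacing = 1.0`, n clipped to
[100, 400]), which makes tension scale like h²/R — the continuum curvature
force — and restores a uniform balance across organ sizes. The bare
`SnakeParams` default stays at n = 100 for direct, small-scale use.

### Coarse-to-fine capture

The edge well of E2 reaches only ~±2σ. Seed hulls can sag several pixels
inside the border (chord sagitta plus seed jitter), and a deliberately far
init (e.g. a concentric circle 10 px inside a disk edge) is far outside a
σ = 2 well. `coarse_sigmas` prepends a schedule of larger scales — the
pipeline default is (8, 4) before the final σ = 2 — run in order, each for
an equal share of `max_iters`, so the wide coarse well pulls the front
near the border and the fine scales localize it.

### Operating points

* **Clean, sharp-edged images** (e.g. noise-free phantoms): final σ = 1,
  schedule (4, 2), `tol = 0.002`, `max_iters = 2000`. The front settles
  into the (shallow) well bottom; measured Dice against ground truth is
  ≥ 96% on disks and ellipses with radii 15–40 px at both tested
  contrasts, and a concentric init 10 px inside a disk edge converges to
  within ~0.5 px of the true circle.
* **Speckled images** (pipeline default): final σ = 2, schedule (8, 4),
  `tol = 0.01`, `max_iters = 1200`. On fully developed speckle the energy
  minimum is genuinely biased 1–2 px inward (intensity-term bias plus the
  fact that a shorter contour through rough terrain lowers E), so driving
  the descent to completion *under-segments*: on the default 20-phantom
  cohort, mean Dice falls from ≈94% to ≈88% as tol → 0. With the default
  tol the evolution stops as soon as the mean displacement stalls — for a
  seed hull already within a pixel or two of the border this happens
  within a few iterations — which doubles as regularization against
  speckle-driven contour creep. Users segmenting lightly degraded images
  should prefer the tight-tol protocol.

This is a limitation of the energy model itself, not of the solver:
passing the speckled-cohort tests shows that seeded-hull initialization
plus bounded energy descent tracks the true border well, not that the
energy's global minimum coincides with it.

After evolution the contour is smoothed by a cyclic moving average
(window 5) — a window-w average of points on a circle of radius R
contracts it by the factor mean(cos(2πk/n)), negligible at n ≥ 100.

## Preprocessing

Specular highlights (saturated blobs from the light source on the wet
organ surface) are detected at ≥ 250, the mask dilated by one pixel, and
the region filled by biharmonic inpainting; the output is clipped below
the cutoff, which also makes the operation idempotent. The ROI stage
smooths with a Gaussian (σ = 3, roughly the speckle correlation scale;
0 disables), splits the histogram by Otsu's between-class-variance
criterion, tidies the foreground (closing with a radius-3 disk whose
erosion treats the image border as foreground, then hole filling), and
keeps the connected component containing — or nearest to — the seed
centroid. Foreground polarity is configurable (`bright`/`dark`, default
bright, with the dark class including the threshold bin).

## Measurements

* **UA** — shoelace area of the contour polygon.
* **UMXD** — maximum Feret diameter: largest pairwise distance between
  convex-hull vertices.
* **UMID** — minimum Feret width of the convex hull, computed exactly as
  the minimum over hull edges of the farthest-vertex distance from the
  edge's supporting line (the minimum caliper width is always flush with
  an edge). "Minimum pairwise distance" would be meaningless (≈0 for
  adjacent vertices); the minimum caliper width is the standard
  morphometric reading.
* **AULA** — orientation of the major axis of the ellipse fitted to the
  boundary by direct ellipse-specific least squares (Halir–Flusser
  stabilized Fitzgibbon fit), measured counterclockwise from the column
  (horizontal) axis in the displayed image, in [0°, 180°). Contours with
  fewer than 64 vertices are densified by arc-length resampling before
  fitting. The fitted axis lengths are exposed alongside the Feret
  diameters.

Lengths are in pixels unless a mm/px scale is supplied (area scales with
its square). AULA is a circular quantity mod 180°; agreement statistics
unwrap differences into [−90°, 90°).

## Agreement and similarity statistics

For paired auto/manual series: ordinary least squares of auto on manual
with Pearson r; RMSE defined against the identity (an agreement error,
not the regression residual); Bland–Altman bias, limits of agreement
bias ± 1.96·SD (sample SD, n−1), the 95% CI of the bias
(bias ± 1.96·SD/√n, reported separately and labeled), and r95 — the
percentage of differences inside the closed limits. Dice and Jaccard
overlap are reported in percent, per case and as mean ± SD with the
maximum per-case deviation. The area error is the absolute mask-area
difference as a percentage of the image area; the α/β sweep varies one
parameter at a time with the other at its default and reports the mean
area error per grid point, continuing past per-cell failures.

## Synthetic phantoms

Each phantom is built from an analytic boundary (ellipse, optionally
perturbed by low-order radial harmonics 2–4 to emulate non-elliptical
shapes such as a septate fundus while keeping the truth analytic):
rasterized two-level template (organ 150, background 80 by default) →
Gaussian edge blur (σ = 2) of the *template* → multiplicative unit-mean
gamma speckle (shape 4, the fully-developed-speckle surrogate; CV =
1/√shape) → saturated specular spots (3 spots, radius 1–3 px, value 255)
→ clip and round to 8-bit levels. Blurring the template before the
speckle keeps the speckle statistics exact (blurring after would cut the
CV several-fold) while still softening the border. Simulated seed points
are 8 evenly spaced border samples with radial normal jitter (SD 2 px,
truncated at 3 px), mimicking clinician-drawn points.

What the phantoms do **not** emulate: beam-geometry point-spread,
attenuation/TGC depth effects, shadowing, neighboring organs and other
distractor structures, and operator variability beyond seed jitter.
Passing phantom tests therefore demonstrates correct mechanics and
calibrated statistics, not clinical-grade performance on in-vivo frames.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| α | 1.23 | image-energy weight (error-sweep optimum) |
| β | 0.91 | stiffness vs tension weight (error-sweep optimum) |
| n_vertices | 100 (pipeline: perimeter/1 px, ≤400) | contour resolution |
| step_size | 0.1 px | explicit image-force step (with backtracking) |
| tol | 0.01 px | mean-displacement convergence threshold |
| gradient_sigma | 2.0 px | analysis scale of G and I |
| coarse_sigmas | () (pipeline: (8, 4)) | coarse-to-fine schedule |
| max_iters | 500 (pipeline: 1200) | iteration budget across stages |
| saturation_cutoff | 250 | specular detection level |
| roi_presmooth_sigma | 3 px (pipeline) | despeckle before Otsu |
| smooth_window | 5 | cyclic moving-average window |

## Problem sizes used in the test suite and acceptance script

All results are recomputed at run time from seeded generators: a
20-phantom speckled cohort for the agreement analogue, a 10-cell
noise-free disk/ellipse grid for snake correctness, n = 10 000 Gaussian
differences for the Bland–Altman coverage check, 100 seeded repetitions
for regression recovery, and a 5-phantom, 3+3-point grid for the α/β
sweep. The full suite runs in well under a minute of compute per module
and the acceptance script in a few seconds.
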