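# Methods

This note documents the models behind `fruitgauge`: what the synthetic
generator emulates, the forward optics, the growth and stress statistics,
and the numerical and design choices a maintainer would want explained.

## Scene geometry

A fruit is modelled as an oblate spheroid with equatorial diameter `d`
(mm) and polar/equatorial ratio `k ∈ (0.6, 1.05]`; the 15 mm square
fiducial marker sits on the fruit top with its normal along the polar
axis. A pinhole camera at distance `D` (mm, measured to the marker plane)
and angle `θ` (between the optical axis and the marker normal) with focal
length `f` (px) sees

* marker area `A_m = s²·cos θ·(f/D)²`,
* fruit silhouette: an ellipse with semi-axes `a = d/2` and
  `b = a·√(cos²θ + k²·sin²θ)`, scaled by the *offset* projection
  `f/(D + k·d/2)`, so `A_f = π·a·b·(f/(D + k·d/2))²`.

The single perspective offset `k·d/2` — the fruit equator lying behind
the marker plane — is deliberately the whole story: no self-occlusion
ray tracing, no lens distortion. It reproduces both biases the analysis
cares about: at fixed `d`, a closer camera (larger `A_m`) yields a
*smaller* fruit/marker ratio, more steeply for larger fruit; and in the
far field (`k·d/2 ≪ D`) the ratio collapses to the closed form
`π(d/2)²/(s²·cos θ)`, which anchors the ratio-curve tests. The marker's
2 mm physical thickness is carried in the config but not in the optics;
at 80–100 mm working distance it would shift `D` by ~2 % uniformly and
cancels into the fitted coefficients.

Angle convention: `θ` is measured from the marker normal (= polar axis),
so `θ = 0` views the marker face-on; capture protocol draws
`D ~ U(80, 100)` mm and `θ ~ U(0, 20)°`. Focal lengths (3024 px at the
3024×4032 tier, 480 px at 480×640) make a 15 mm marker at 90 mm span one
sixth of the short image side, emulating the sighting-guide framing.

A sphere (`k = 1`) has an angle-independent silhouette; flatness is what
makes angle matter. The flatness index `F = 1 − k` is coupled to size as
`F = F₀ + β·(d − d̄) + ε`, `ε ~ N(0, σ_F²)`, with `F₀ = 0.15` at
`d̄ = 55` mm, `β = 0.0025`/mm, and `σ_F = 0.083` calibrated once so that
corr(d, F) ≈ 0.46 over a 30–90 mm reference population after clipping
`k` to its physical range (larger fruit more oblate; the sign of the
coupling is an assumption, as is the linear form). Per fruit the noise
`ε` is drawn once and kept for the whole trajectory, so flatness evolves
smoothly with growth.

## Rasterization and area extraction

Analytic areas are the reference; `render_mask` is a fidelity layer that
rasterizes the ellipse and the foreshortened marker rectangle into a
3-class label image (PNG, 0 = background, 1 = fruit, 2 = marker), with
marker pixels overriding fruit pixels. Class counts converge to the
analytic areas as resolution grows (relative error ~1e-4 at the high
tier, ~1e-3 at the low tier on the default check grid). An optional
droplet perturbation plants random blobs on the fruit contour until the
fruit area has been inflated by a configured fraction, emulating water
droplets misclassified as fruit on rainy-day photographs.

`extract_areas` labels each class by 4-connected components and reports
the largest component's pixel count — the conventional stand-in for a
top-scoring detection when the segmentation stage is replaced by label
masks. The fruit class is hole-filled first: the marker sits inside the
fruit outline and owns its pixels, but a segmentation fruit mask covers
the whole fruit, so the fruit area must be the full silhouette rather
than silhouette-minus-marker. Missing classes are hard errors (failed
detection), never silent zeros.

## Water potential, growth, and the season

Each tree's pre-dawn water potential follows a daily latent path: start
at the unstressed baseline `c = −0.4` MPa, decline at a per-tree drying
rate (drawn once per tree from U(0.002, 0.025) MPa/day) plus white noise
(0.02 MPa/day), clip to `[−2.0, −0.4]` MPa (mortality floor to
baseline), and reset instantaneously to `c` on rain-event dates (one
mid-August event by default; no post-rain growth surge is modelled). The
measured series subsamples this path every 7–10 days, always including
the season's last day. The default season runs July 21 – November 9.

Daily diameter growth is piecewise linear in Ψ: zero at the −2.0 MPa
floor, 0.25 mm/day at −0.8 MPa (slope α = 0.25/1.2 mm/day per MPa),
clipped below at zero. Only the anchor and the floor are empirically
motivated; the linear interpolation between them is the simplest monotone
choice. Trajectories integrate growth on the *measured* Ψ series,
linearly interpolated to days, using the day-interval midpoint — i.e. a
trapezoidal quadrature. This matters: the integrated stress statistic

    S_Ψ = | Σ ((Ψᵢ + Ψᵢ₊₁)/2 − c) · nᵢ |     [MPa·days]

uses the same trapezoid grid, so on noiseless data with Ψ ≤ c throughout,
period growth is exactly `α(c − floor)·T − α·S_Ψ`: the growth–stress
regression returns r² = 1 with slope −α to machine precision. This
identity is the strongest internal consistency check the pipeline has.
Accumulation starts from the last measurement at or before the period
start (the pair containing the boundary counts in full), ends with the
pair reaching the period end, and the absolute value is applied to the
total, not per interval — with Ψ ≤ c the readings coincide.

Initial diameters are N(40, 3²) mm in late July; with stress-dependent
growth this yields 16–34 mm of season growth and harvest diameters up to
~77 mm. Caliper readings add N(0, 0.15²) mm noise per replicate, two
replicates per fruit and day.

## Size models

The regression target is the caliper diameter (mean of the two
replicates) of the photographed fruit on the photo day, matching how
field ground truth is collected; the true geometric diameter is kept
separately for diagnostics.

* Ratio curve: least squares on `d = a·√ratio + b`. The square-root form
  is the exact inverse of the far-field area–diameter relation and keeps
  prediction single-valued; in that limit `a → 2s/√π ≈ 16.93` and
  `b → 0`.
* Regression suite: linear, ridge/lasso/elasticNet (α = 1), random
  forest and gradient-boosted trees (300 trees, seeded), RBF-kernel SVR
  (C = 100, ε = 0.1). Hyperparameters are fixed defaults, no search.
  Features are z-scored with statistics learned from the training season
  only and stored with the model; normalization is applied uniformly to
  all families, tree ensembles included (harmless there, required for
  the kernel and penalized families). Feature subsets compared: all
  three, the two areas, fruit + ratio, marker + ratio.
* Scoring: MAE and RMSE in mm, R² as the *squared Pearson correlation*
  between estimates and truths (not the identity-line R²; the two differ
  when predictions are biased), and the count of outliers ≥ 5 mm.

On the default benchmark the ensembles and SVR beat the global linear
fits, and the ensemble predictions on fixed-diameter pose sweeps are
nearly decorrelated from marker area (|corr| shrink factor ≈ 0.1–0.3
vs the raw ratio), which is the distance-bias correction the multi-
feature models exist for. Residual diameter trends are compared inside
the central 10th–90th percentile of the test diameters: at the support
edges every regression shrinks toward the training mean (and trees
cannot extrapolate), an artifact distinct from the perspective bias
under study.

## Experiment design and reproducibility

`run_all` mirrors a two-season field campaign at desk scale: 24 trees ×
5 fruits, ~5 photographs per fruit, tier and measurement day. Season 1
(training) uses a derived sub-seed and a season shifted back one year,
so cohorts differ in drying rates, growth and poses; season 2 is scored
held-out, and the stress analysis runs on season 2 (whole season plus
calendar-month sub-periods; period boundaries snap to the last
measurement at or before them). Caliper growth averages the two
replicates at each endpoint; image growth picks one seeded random
photograph per endpoint day; fruit growth is averaged per tree before
correlating with S_Ψ. All randomness flows from one config seed through
named substreams (per-purpose, per-tree), so reruns are byte-identical;
the manifest records config, versions and output digests. Fitted sklearn
estimators are deliberately not serialized — the evaluate stage refits
deterministically from the year-1 CSVs — keeping every artifact on disk
plain text.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the measurement problem: the
quadratic area–diameter relation, the distance and angle biases and
their dependence on size and flatness, the stress–growth coupling, rain
resets, caliper replicate noise, and two image-resolution tiers. It does
not emulate segmentation errors (masks are exact by construction unless
the droplet perturbation is enabled), occlusion, lighting, fruit-shape
irregularity beyond the spheroid, or the post-rain water-absorption
physiology that decorrelates growth from stress in wet spells. Passing
benchmarks therefore demonstrate that the *pipeline* is correct and that
the regression models remove geometric bias under the stated capture
protocol — not that field accuracy of any particular magnitude is
guaranteed. Growth–stress correlations near 1 over the whole season are
likewise a property of the simulator (growth depends on nothing but Ψ),
an upper bound a field study cannot reach.

## Numerical details

* Degenerate inputs are errors, not defaults: empty classes in masks,
  zero marker area, constant ratios in the ratio-curve design, zero
  variance in the correlation stage, periods not covered by the Ψ
  record, trees with no usable fruit.
* Constant features get unit scale in normalization (they carry no
  signal either way); constant estimate vectors score r² = 0.
* Areas are quantized to integer pixel counts by default (real masks are
  integer-valued); the closed-form tests disable rounding.
* Problem sizes used by the test suite and acceptance script — 24 × 5
  cohorts (~8 700 test images per tier), 250-pose sweeps, 5 000-fruit
  flatness populations — were chosen so the full suite runs in well
  under a minute per heavy check on one CPU.
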