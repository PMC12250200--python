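# fruitgauge

Monocular fruit sizing with a fiducial marker, and what the resulting
growth record says about tree water stress.

## The problem

Citrus growers impose controlled drought stress in summer and fall to
raise fruit sugar content, and steer irrigation by how stressed each tree
is. The reference stress measure — pre-dawn leaf water potential
(Ψ<sub>PLWP</sub>, MPa, ≤ 0) from a pressure chamber — is accurate but
impractical for routine use, while fruit growth rate is a convenient
proxy: stressed trees grow fruit slowly (about 0.25 mm/day at −0.8 MPa).
A cheap way to measure fruit diameter is to glue a 15 mm square marker
("plastic piece") to the fruit top, photograph it with a phone from
8–10 cm at 0–20°, segment fruit and marker, and infer diameter from the
fruit/marker area ratio.

The catch is geometry. The marker sets the image scale at *its* plane,
but the fruit's widest section sits half a polar diameter behind it, so
for a camera at distance `D` from the marker the fruit silhouette scales
as `f/(D + k·d/2)` while the marker scales as `f/D` (focal length `f`,
equatorial diameter `d`, polar/equatorial ratio `k`). Close cameras and
large fruit therefore lose relatively more fruit area, and fruit flatness
(correlated with size, r ≈ 0.46) adds an angle-dependent error. The area
ratio alone is a biased size measure; a regression model over (fruit
area, marker area, ratio) can learn to undo the bias.

`fruitgauge` implements this entire measurement chain as testable code,
with a synthetic-scene generator standing in for the field data:

* `scene_sim` — oblate-spheroid fruit with size-linked flatness, pinhole
  projection with the marker-plane perspective offset, seasonal
  water-potential paths with rain resets, stress-driven daily growth,
  label-mask rasterization (optional water-droplet perturbation);
* `mask_areas` — fruit/marker pixel areas from 3-class PNG label masks
  (largest 4-connected component, fruit class hole-filled);
* `size_models` — the ratio curve `d = a·√ratio + b` and seven regression
  families (linear, ridge, lasso, elasticNet, random forest, GBDT, SVR)
  over any subset of the three features, scored by MAE, RMSE and squared
  Pearson R²; outliers are errors ≥ 5 mm;
* `stress_pipeline` — per-period fruit growth by measurement method and
  the integrated water stress
  `SΨ = |Σ ((Ψᵢ+Ψᵢ₊₁)/2 − c)·nᵢ|` (MPa·days, baseline c = −0.4 MPa),
  and their per-tree correlation;
* `pipeline`/`cli` — a two-season experiment (train on season 1, test on
  season 2) with CSV interchange and a reproducibility manifest.

## Worked example

Simulate both seasons, fit and score all models, then run the
stress/growth analysis (drivers live under `analysis/`):

```bash
python analysis/01_simulate_cohorts.py      # writes results/simulated/
python analysis/03_fit_size_models.py       # writes results/models/
python analysis/04_stress_growth.py         # writes results/stress/
```

The first driver prints the study conditions it generated:

```
year1: 24 trees, psi range [-2.00, -0.40] MPa, season growth 17.8-31.4 mm, final diameter 75.7 mm max
year2: 24 trees, psi range [-2.00, -0.40] MPa, season growth 16.4-33.7 mm, final diameter 77.1 mm max
```

The model comparison (held-out season, high-resolution tier, all three
features) reproduces the expected ordering — the nonlinear models beat
the global linear fits because they can condition on the marker area,
i.e. on camera distance:

```
       family     r2  mae_mm  rmse_mm  n_outliers
          svr 0.9743  1.1127   1.4668          36
         gbdt 0.9732  1.1404   1.4936          41
random_forest 0.9696  1.2083   1.5875          58
        ridge 0.9673  1.2676   1.6419          56
       linear 0.9673  1.2676   1.6419          56
```

while the bare ratio curve reaches r2 0.9646, MAE 1.32 mm. The stress
analysis then relates per-tree growth to integrated stress per period;
over the whole season growth is almost a pure function of accumulated
stress, while short sub-periods around the mid-August rain reset
decorrelate:

```
    method     r2   slope
   caliper 0.9999 -0.2079
image_high 0.9816 -0.1757
 image_low 0.9759 -0.1788
```

The caliper slope is the growth-law constant −0.25/1.2 ≈ −0.208 mm per
MPa·day, recovered from the simulated record.

The same experiment runs end to end from one config file:

```bash
fruitgauge run-all --config configs/default.yaml --seed 11 --out results
```

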