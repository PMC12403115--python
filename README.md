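# phenometrics

Tools for quantifying spring phenology in the deciduous-tree /
leaf-feeding-caterpillar system, and for comparing the phenological metrics
that different field methods produce.

Monitoring a woodland in spring yields several parallel time series per tree:
ordinal bud scores, effective leaf-area index (LAI) from hemispherical
photography, mean crown NDVI from multispectral imagery, caterpillar counts
from water traps under the canopy, and frass (caterpillar droppings) mass
from frass traps.  Ecologists studying trophic synchrony — whether insect
timing tracks host-tree timing, and what that means for herbivory — need to
reduce each series to comparable dates.  This package implements the two
standard reductions and the downstream comparison analyses:

* **Half-dates.** Each per-tree series is normalized to [0, 1] (ordinal
  rescale for bud scores, within-tree min–max for LAI/NDVI, cumulative
  proportion of the season total for counts and frass) and fitted with a
  Beta-likelihood, logit-link penalized spline of day,
  `logit E[y(t)] = f(t)`.  The *half-date* is the day the fitted curve first
  crosses y = 0.5 (budburst, half-leaf, half-NDVI, and the frass / total
  caterpillar / final-instar winter-moth half-falls); the gradient at the
  crossing and a bootstrap 95% interval are extracted with it.
* **Peaks.** Raw trap counts (frass mass × 100, to centigrams) are fitted
  with a Poisson-likelihood, log-link penalized spline; the *peak date* and
  *peak height* (with interval) describe the caterpillar abundance maximum.

On top of the nine metrics the package provides absolute-agreement
repeatability (ICC(A,1) from two-way ANOVA mean squares), Spearman
correlation matrices, Gaussian cross-trophic regressions (caterpillar metric
~ tree metric + sampling area) with percentile-bootstrap intervals,
Beta-likelihood herbivory regressions (logit link, controlling for area and
canopy level), ELPD-based model comparison by cross-validation, and Moran's I
residual diagnostics with k-nearest-neighbour weights.

A synthetic-woodland generator (`phenometrics.synth`) simulates all five
observation streams from known latent phenology, so the entire chain is
testable end-to-end: every estimate can be checked against the ground truth
that generated its data.

## Worked example

```python
import phenometrics as pm
from phenometrics.pipeline import compute_half_dates, metrics_wide

cfg = pm.default_config(rng_seed=11,
                        species=[pm.SpeciesConfig("oak", 12, 112.0, 7, 30.0)])
trees, obs, truth = pm.generate_woodland(cfg)

hd = compute_half_dates(obs, trees, methods=("bud_score", "count_total"),
                        ensemble_size=200, seed=1)
row = hd[(hd.metric == "budburst") & (hd.tree_id == "oak_001")].iloc[0]
print(f"budburst day {row.half_day:.2f} "
      f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}), "
      f"gradient {row.gradient_at_half:.3f}/day, flag={row.flag}")

wide = metrics_wide(hd, None, trees)
res = pm.fit_cross_trophic_model(wide, "tc_half_fall", "budburst",
                                 area_reference="Great Wood",
                                 n_boot=500, random_state=1)
print(res.summary())
```

prints

```
budburst day 109.30 (95% CI 106.33-112.00), gradient 0.039/day, flag=ok
Gaussian model: tc_half_fall ~ budburst + area
n = 12; R2 (conditional) = 0.414; elpd = -40.70
  Intercept               118.972 (82.856, 173.791)*
  budburst                  0.277 (-0.244, 0.604)
  area[ForestGEO]           2.701 (-0.173, 7.434)
  area[Marley]              0.314 (-4.274, 3.448)
  Moran's I on residuals: -0.1111 (expected -0.0909, p = 0.672)
```

The first line is one tree's budburst date: the day its fitted bud-score
curve crosses 0.5, with the bootstrap interval and the curve's steepness at
the crossing (a logistic with rate k crosses at slope k/4).  The model block
regresses the day by which half of each tree's season caterpillar catch had
fallen on its budburst date: the slope estimate 0.277 (the generating value
was 0.20; at n = 12 trees the interval is wide and includes it) says each
day of later budburst delays caterpillar fall by ~0.28 days, and the area
terms point at the simulated between-area timing offsets (+2.3 days in
ForestGEO relative to Great Wood).  At realistic sample sizes (77 oaks, as
in the tests) the slope interval tightens to roughly ±0.08 and the area
effects become significant.

A CLI wraps the pipeline end to end (`phenometrics simulate | normalize |
fit | peaks | compare | report | all`, plus `phenometrics icc` for
two-column repeatability tables); every run writes a manifest with a content
hash per artifact.

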