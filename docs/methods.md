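# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
woodland does and does not emulate.

## Normalization

Each tree × method series is rescaled to the unit interval before curve
fitting, with one convention per class of stream:

* **Bud scores** (ordinal 1..5, or 1..7 for oaks; per-visit values are means
  of 12 crown sections, so fractional): `y = (score − 1)/(max_stage − 1)`.
* **State streams** (effective LAI, mean crown NDVI): within-tree min–max,
  `y = (v − min)/(max − min)`.  A winsorizing hook (clip to the (q, 1−q)
  empirical quantiles before taking min/max) is available and off by default
  at the operation level; the pipeline turns it on at q = 0.05 for LAI/NDVI
  because isolated sensor/exposure outliers otherwise corrupt the min/max
  anchors and propagate a level shift into every normalized value of the
  tree.  Flat series (max = min) have no defined trajectory and are flagged.
* **Event streams** (trap counts, frass mass): cumulative sum over visits
  divided by the season total.  The curve is nondecreasing and ends at
  exactly 1.  A zero season total (a tree that caught nothing) yields an
  `undefined` flag, never numbers; downstream tables carry the missing
  metric as NA.

Exact 0s and 1s are emitted here (the min/max visits, the last cumulative
visit).  Because the Beta likelihood lives on the open interval, the fitter
maps boundary values to the endpoints of the squeeze transform
`y' = (y(n−1) + 0.5)/n`, i.e. to `0.5/n` and `1 − 0.5/n` where n is the
series length.  Interior values are left untouched: they are already on the
Beta support, and transforming them would bend an exactly logistic trajectory
away from logit-linearity and bias the gradient at the midpoint, violating
the analytic identity (slope k/4 at the crossing) that anchors the test
suite.

## Trajectory model and half-dates

For each tree and stream the mean trajectory is a Beta regression with logit
link,

    y_t ~ Beta(mu_t * phi, (1 - mu_t) * phi),   logit(mu_t) = f(t),

where `f` is a cubic B-spline (8 basis functions over the observed day
range, second-difference penalty) and `phi` a free precision.  The roughness
weight is chosen on a log grid (10^−2 … 10^4, 7 points) by a Laplace
approximation to the marginal likelihood; because the penalty's null space
contains all linear functions of day, an exactly logistic trajectory is
recovered without bias at any penalty weight.  Series with fewer than 8
distinct visit days use the logistic fallback — midpoint, rate and precision,
three parameters — since the normalized scale fixes the asymptotes at 0
and 1.  Series with fewer than 5 distinct days are refused.

Bud-score series may carry an observer label per visit; the model then adds
ridge-penalized observer intercepts on the logit scale (a shrunken random
effect; ridge weight selected on a small grid jointly with the roughness
penalty).

Optimization is L-BFGS-B with analytic gradients, the log-precision bounded
in [−4, 12] (on noiseless data the likelihood increases without bound in
phi, and the fit should converge cleanly at the cap), followed by a few
Fisher-scoring polish steps; convergence is declared by Newton decrement,
which is invariant to the likelihood's scale.

The **half-date** is the first upward crossing of the central fitted curve
through y = 0.5, refined by bisection to 0.01 day on the continuous curve
(evaluation grid: 0.1 day).  The **gradient** at the crossing is a centred
finite difference (h = 0.05 day).  Curves that never reach 0.5 are flagged
`no_crossing`; curves already above 0.5 at the first observation, or crossing
in the first/last grid cell, are flagged `boundary`.  If a wiggly fit
recrosses, the first crossing is reported with a multiplicity note.

### Uncertainty

The 95% interval on the half-date is a bootstrap percentile interval over
the crossing days of B refitted curves (B = 500 by default; the penalty
weight is held at its selected value and refits are warm-started).  Two
resampling schemes are implemented:

* **case** (default): visits are resampled with replacement.  This is
  robust to misspecification of the Beta dispersion model.  In simulation
  with logit-scale observation noise — a realistic error structure for
  bud-score and greenness series — the parametric alternative undercovers
  badly (~70% actual coverage at nominal 95%) because the Beta's
  mean–variance relation forces too little dispersion near y = 0.5, exactly
  where the crossing is determined.  Case resampling restores honest
  coverage (~92% measured).
* **parametric**: draws from the fitted Beta model, refit per draw.

Percentile levels are expanded from 2.5/97.5 using the t-quantile at
df = n − edf (edf = trace of the smoother's effective-degrees-of-freedom
matrix), the standard small-sample correction for bootstrap percentile
intervals; at n ≈ 17 visits this widens the interval by roughly 10%.

## Count curves and peaks

Trap streams are modelled on their natural count scale: frass mass is
converted to integer centigrams (×100, round-half-up) so it fits the same
Poisson machinery as caterpillar counts.  The intensity is a log-link
penalized spline of day with the same basis and penalty-selection machinery
as the trajectory model.  Because interception traps accumulate between
visits, the log of the interval since the previous visit enters as an
exposure offset by default and the fitted intensity is a per-day rate;
setting `use_exposure_offset=False` reproduces plain per-visit modelling.
An optional quasi-likelihood scale factor inflates bootstrap dispersion for
overdispersed counts (default 1.0, plain Poisson).

The **peak day** is the grid argmax of the central intensity (ties resolve
to the earliest day; argmax at either end of the observed season raises a
`boundary` flag) and the **peak height** interval is the 2.5/97.5 percentile
of each bootstrap replicate's own maximum (parametric Poisson resampling —
counts are genuinely conditionally Poisson here, so the parametric scheme is
appropriate).

## Repeatability

Duplicate-instrument agreement is ICC(A,1) — two-way model, single
measures, absolute agreement — computed from the ANOVA mean squares
(McGraw & Wong):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + k/n (MSC − MSE)),  k = 2,

with the F-test p-value from MSR/MSE.  Absolute agreement (not consistency)
is the right variant for paired traps and paired cameras, because a constant
offset between instruments is a real disagreement; the consistency variant
is exposed but non-default.

## Comparison layer

* **Spearman matrices** on pairwise-complete rows, average ranks for ties;
  two-sided p by exhaustive permutation for n ≤ 9, t-approximation
  otherwise.  A Benjamini–Hochberg column is appended for reference but raw
  p-values drive the default significance marks.
* **Cross-trophic models**: Gaussian linear models of a caterpillar metric
  on a tree metric plus sampling area (treatment coding, configurable
  reference level).  Inference is maximum likelihood with pairs-bootstrap
  percentile 95% intervals (B = 1000); "significant" means the interval
  excludes zero.
* **Herbivory models**: Beta regression (logit link, free precision) of the
  herbivory fraction on a phenology metric, area, and relative canopy level.
  Canopy level enters as treatment-coded levels — a fixed-effect stand-in
  for a random intercept, with its contribution included in the conditional
  R² — because only three levels exist and shrinkage would be nominal.
  Boundary herbivory values (exact 0 or 1) get the standard squeeze.
* **Variance explained**: R² = var(fitted)/(var(fitted) + var(residual)),
  conditional on all model terms; `variance_explained_delta` reports the R²
  gain from adding a factor to a base model fitted on the same rows.
* **ELPD**: the expected log pointwise predictive density under
  cross-validation — exhaustive leave-one-out refitting for n ≤ 30, shuffled
  10-fold otherwise — with the Gaussian predictive density using the
  training-fold ML variance and the Beta predictive density refitted per
  fold.  `compare_models_elpd` pins the best model at Δelpd = 0; only models
  fitted on identical rows are comparable.
* **Moran's I** on model residuals with row-standardized k = 8
  nearest-neighbour weights, expectation −1/(n−1), and a two-sided
  permutation p (999 permutations).  Duplicate coordinates collapse to one
  site with the mean residual.

The Bayesian machinery that inspired this layer (posterior credible
intervals, PSIS-LOO) is deliberately replaced by ML + bootstrap + CV
equivalents: the package's contracts are coverage, sign recovery and model
ranking, which these deliver without an MCMC dependency.

## Synthetic woodland

The generator simulates the study conditions the analysis stack is built
for: six broadleaf species (hazel, sycamore, birch, beech, oak, ash; 30, 18,
17, 5, 77, 23 trees) whose mean budburst days span ~32 days; per-tree timing
deviations (SD 5 days); three sampling areas on a 100 m grid with caterpillar
timing offsets (+2.3 days ForestGEO, −1.2 Marley, 0 Great Wood).  Each tree
has a latent logistic leaf-out trajectory (rate ≈ 0.35 logit/day).  The five
streams derive from it:

* bud scores threshold the latent proportion into equal-width stages, with
  per-section noise (12 sections averaged) and observer intercepts;
* LAI and NDVI are scaled/shifted logistics lagged by 10 and 6 days with
  additive noise and ~2% outliers;
* water-trap counts are Poisson around a Gaussian-shaped daily intensity
  (SD 6 days) integrated between visits, centred at
  `a + b × half_date + area offset + noise` with b = 0.20 and residual SD 2
  days; the final-instar winter-moth substream is a binomial thinning whose
  retention rises through the season (≈0.011/day), shifting its peak ~1 day
  later than the total;
* frass mass is a noisy unimodal biomass curve leading the count peak by 4
  days, reported in grams;
* herbivory is one Beta draw per tree with
  `logit(mean) = 5.85 − 0.07 × half_date + canopy effect`, precision 25.

Visits run on a 3-day schedule with 5% random omissions; missed visits are
dropped rows, and trap values accumulate since the last kept visit
(interception-trap physics).  The truth table stores every latent quantity
(half-dates per stream, rates, peak days/intensities, trap-stream half-fall
days computed from the truncated intensity, herbivory means) so recovery is
directly checkable.

Within-tree observation-noise magnitudes for LAI/NDVI are assumptions chosen
to look like field data (SD 0.15 on an LAI amplitude of 3; SD 0.02 on an
NDVI amplitude of 0.45), not estimates from any dataset.  The generator
works at the extracted-measurement level only: no imagery, no weather, no
multi-year structure, no species-specific caterpillar communities.  Passing
tests therefore demonstrate that the estimators recover known structure
under realistic noise and sampling designs — not that any particular field
system satisfies the generator's assumptions.

## Problem sizes and numerical settings

The test suite and acceptance script scale simulations to what the analysis
needs: 100 trees for half-date calibration (B = 200), 100 simulations for
peak recovery, 20 replicate woodlands at the field sample sizes (77 and 72
oaks) for regression recovery, and a 68-tree six-species woodland (40% of
the full design) with B = 150 for the end-to-end reproduction script.
Bisection tolerance 0.01 day; evaluation grid 0.1 day; penalty grids as
above; all randomness flows from a single seed split per tree × metric.

## Known limitations

* Per-tree fitting with optional logit-scale shrinkage toward the species
  mean curve (`shrink_to_species_mean`) approximates, but is not, a
  hierarchical factor-smooth fit; trees with very sparse or very noisy
  series borrow no strength by default.
* Min–max normalization makes half-leaf and half-NDVI sensitive to the
  season window: if a series is still rising at the last visit, its maximum
  anchor is biased early.  The boundary flag catches the overt cases only.
* The exposure-offset treatment of unequal visit intervals assumes the
  intensity is roughly constant within an interval; very long gaps around
  the peak will blur it.
* ELPD under 10-fold CV is noisier than exhaustive LOO; Δelpd values within
  ~2 of zero should not be over-interpreted.
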