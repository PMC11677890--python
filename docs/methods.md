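# Methods

## Models

Three scaling models relate planar organ area to one-dimensional
measurements. Per petal, the Montgomery equation A = k·L·W, with L the
extent of the outline along its length axis, W the maximum perpendicular
extent and A the enclosed (shoelace) area. Because the petal fits inside
the L×W rectangle oriented along that axis, k ∈ (0, 1] always; π/4 for
an ellipse, 1 for a rectangle. Per flower, the Montgomery–Koyama–Smith
equation A_T = k_KS·L_KS·W_KS with A_T = Σ A_i, L_KS = Σ W_i, W_KS =
max L_i over the flower's petals; the same containment argument gives
A_T ≤ L_KS·W_KS, so k_KS ≤ 1 too. The power-law equation
A_T = β(L_KS·W_KS)^α frees the exponent; α = 1 recovers the isometric
structure, so the PLE nests the MKSE and never fits worse.

All fits are ordinary least squares after natural-log transformation
(areas are positive with multiplicative scatter, so the log stabilises
the variance). ME and MKSE are intercept-only regressions on an offset
(slope fixed at 1): â = mean(ln A − ln LW), k̂ = exp(â) with no
bias-correction of the back-transform. A `log_base` option reports the
intercept in another base; slope, correlation and k̂ are base-invariant,
and RMSE is always in natural-log units.

Fit quality is RMSE with divisor n (the ML variance, not n − p). AIC =
2p − 2·lnL with p = regression parameters + 1 for the error variance
(ME/MKSE p = 2, PLE p = 3) and the Gaussian maximum lnL =
−(n/2)(ln 2π + ln(rss/n) + 1). An exact fit (rmse ≤ 1e−12) has a
degenerate likelihood; AIC is reported as NaN and `compute_aic` raises
on rss = 0. Model choice between MKSE and PLE uses the percent error
PE = (RMSE_MKSE − RMSE_PLE)/RMSE_MKSE × 100 with a 5% default threshold;
a tie goes to the simpler model. The rule trace also records both AICs
and, when available, whether the PLE slope CI contains 1.

Confidence intervals are nonparametric case-resampling bootstrap:
observation pairs resampled with replacement, B = 3000 refits by
default, percentile 2.5/97.5 bounds, mandatory seed. Residual
resampling and BCa intervals were considered and rejected to keep the
scheme assumption-free; the cost is intervals that can be slightly wide
at small n, which the coverage simulations quantify (≥ 90% empirical
coverage of a 95% interval at n = 300).

## Measurement

Boundary tracing labels 8-connected foreground regions (diagonal
neighbours join, so thin petal tips stay attached), drops components
below 100 px (configurable; scanner dust), and contours each region at
the 0.5 level with marching squares on a padded grid, giving sub-pixel
vertex placement. Only outer rings are kept — petal silhouettes are
simply connected, so interior holes are treated as scan noise. A region
joined only at pixel corners yields one ring per lobe and each ring
becomes its own polygon. Pixel coordinates become cm via 2.54/dpi with
y increasing upward; all polygons are normalised counter-clockwise.
Regions touching the image border are flagged and warned about, not
dropped.

The length axis defaults to the major principal axis of the outline's
second moments of area (exact polygon moment integrals, not vertex
moments, so vertex density does not bias it); a base→apex landmark mode
exists for petals whose symmetry axis is known. Isotropic second
moments (square/circle-like outlines) trigger a fallback to the
longest-diameter axis with a warning. W is the maximum caliper extent
perpendicular to the axis, not the width at mid-length; for petals with
a concave (notched) apex, L is the axis extent of the outline as
traced — the notch is not bridged, which inflates the apparent k of
such petals relative to an un-notched shape of the same nominal length.
That convention is reproduced deliberately, not corrected.

## Synthetic data

The generator emulates a two-species petal study. Outlines come from a
half-width profile w(x) = (W/2)·f(x/L), f(t) = t^p1(1−t)^p2 normalised
to max 1, so axis extent and maximum width are exactly L and W and the
shape-determined k = ∫f dt is one dimensionless number per species. An
apex notch of depth d·L (d < 0.3) removes a wedge whose lobes still
reach x = L: length is preserved, area falls. Profile exponents in the
presets stay near 1 because real petals are blunt-tipped; exponents far
above 1 produce cusp-like tips thinner than a scan pixel that no tracer
(or scanner) could resolve.

Species presets (illustrative, not measurements): "mh_like" — 60
flowers, 11–12 petals each, length ~1.6 cm, W/L ≈ 0.55, obovate
(p1 = 1.2 > p2 = 0.8, k = 0.657); "pk_like" — 63 flowers, 5 petals,
length ~1.5 cm, W/L ≈ 0.95, rounded (p1 = p2 = 0.7, k = 0.732) with a
5% apex notch. Together they give ~690 + ~315 = ~1005 petals in 123
flowers, the scale of a realistic two-species campaign. Petal length is
lognormal with 80% of its log-variance between flowers and 20% within
(petals of one flower are similar in size); W/L is Gaussian truncated
at 0.05; observed areas are the exact outline areas times exp(ε),
ε ~ N(0, σ²) with σ = 0.03 by default, consistent with the log-scale
RMSEs such studies report (0.02–0.05). A `shape_drift` knob multiplies
p2 by exp(drift·(ln L_flower − μ)), making larger flowers differently
shaped; this breaks isometry and produces a power-law exponent α ≠ 1
that the PLE recovers, the regime where the extra parameter earns its
keep.

Every dataset carries its ground truth: the noise-free area of each
petal and the per-species shape k (mean of A/(LW), identical across
petals when shape is fixed). σ = 0 therefore allows exact-recovery
tests. What the generator does not emulate: petal-to-petal shape
variation within a species, measurement error on L and W themselves,
damaged or overlapping petals, and digitisation artefacts other than
rasterization. Passing tests show the estimators are correct under the
stated generative model, not that any particular species obeys it.

Rasterization marks pixels whose centres fall inside the polygon, the
natural counterpart of a thresholded scan. Round-trip
rasterize→trace→measure errors at 600 dpi are ≤ ~0.5% for preset-like
shapes (worst of A, L, W over 50 draws) and shrink with dpi; the
residual error is the half-pixel placement limit of any
contour-from-raster method.

## Group comparison

Tukey's HSD on the one-way species layout: pairwise studentized-range
statistics q = |m_i − m_j| / sqrt((MSW/2)(1/n_i + 1/n_j)) with the
pooled within-group mean square, p-values from the studentized-range
distribution with (k groups, N − k) df. With two groups this is exactly
the pooled t-test (q = √2|t|). Compact letters come from
insert-and-absorb on the significant pairs, lettered by descending
mean. Traits are compared on the raw scale. Petals are treated as
independent observations; petals within a flower are in fact
correlated, so petal-level p-values are anticonservative — a documented
caveat, deliberately not modelled (no mixed effects).

## Numerical choices and limitations

- Grouping keys are exact strings; flower ids need only be unique
  within species.
- Duplicate consecutive vertices are collapsed on polygon construction;
  self-intersecting or zero-area outlines are rejected outright.
- The bootstrap refits degenerate PLE resamples (all predictors equal)
  by redrawing; this is only reachable at tiny n.
- AIC has no small-sample correction (AICc) by design.
- Test-suite and acceptance-script problem sizes (200 simulations of 60
  flowers; 100 coverage replicates at B = 1000; 50 round-trip shapes)
  were chosen as the smallest sizes at which the Monte-Carlo error of
  each check is comfortably below its tolerance.
- Exact reproduction of any external study's fitted numbers requires
  that study's per-petal table; `read_petal_table` ingests such tables
  (species, flower_id, petal_id, A, L, W) and the pipeline then runs
  unchanged.
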