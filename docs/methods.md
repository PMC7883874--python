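# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical software vignette: what is computed,
under which assumptions, and where the genuinely open choices were made.

## 1. Crop surface height

The DSM is the per-cell aggregate of point z-values on a 5 cm grid. Cell
membership uses half-open intervals `[x0+i·c, x0+(i+1)·c)`; a point exactly
on the outer grid edge joins the last cell (histogram convention); the cell
value is located at the cell centre. The **aggregator is `max` by default**
(a surface model is conventionally top-of-canopy); `mean` and `p95` are
selectable, and the smoother `mean` surface is always the one used for
texture extraction. `CSH = DSM − DEM` cellwise; NaN propagates; negative
heights are clamped to 0 (ground-measurement noise) and counted.

Per-plot metrics pool all valid CSH cells whose centres fall inside the plot
polygon minus the 1.5 m destructive-sampling strip at the start of the
plot's long axis (the strip is trimmed in both years, matching how such
plots are managed). Pooled-cell computation is the default; computing
metrics per sub-area and averaging is a documented alternative the API
permits by calling `metrics_from_values` on subsets.

Numerical conventions, fixed because they shift results on small samples:
percentiles are type-7 (linear interpolation between order statistics);
skewness is Fisher–Pearson g1 and kurtosis excess g2 (population moment
ratios); variance/sd are sample statistics (ddof = 1); the mode is the
midpoint of the most populated 1 cm histogram bin over [0, max] (first bin
on ties) since continuous data have no exact mode; canopy height relief is
`(mean − min)/(max − min)`, defined as 0 for a flat canopy.

## 2. Spectral features

Band means are zonal means over valid cells inside the trimmed polygon; the
four bands must be co-registered. The 13 vegetation indices live in a
declarative registry (name → formula over {G, R, RE, N}) so the set can be
swapped without touching code. Indices are computed **from the plot-mean
reflectances**, not per pixel and then averaged; the per-pixel route can be
reproduced by running the registry formulas through `texture_image`-style
rasters, but is deliberately not the default because plot-mean VIs are what
zonal-statistics workflows produce. A vanishing denominator yields NaN with
a warning rather than an exception, so one degenerate plot cannot abort a
batch.

## 3. Texture

GLCMs are computed per pixel over a sliding window of radius 2 (5×5), a
single (0, 1) offset with symmetric counting, and 8 gray levels — the
"simple" default set of the common remote-sensing toolboxes; window radius,
offsets, level count and entropy base are all parameters. Edge pixels use
the truncated in-bounds window; nodata pixels never contribute pairs and
receive NaN features. Quantization is linear binning of a fixed value
range; per flight scene the range is [0, p99.9] of the scene's CSH values
(to stop a single outlier collapsing the bins) and min–max of each band, so
features are comparable across the plots of one scene.

Two conventions exist for *Haralick correlation* and they differ
numerically. The default follows the toolbox lineage: with marginal row
sums `r_i = Σ_j p(i,j)`, `HC = (Σ i·j·p − μ_t²)/σ_t²` where μ_t, σ_t are
the plain mean and population sd of the G values r_i. The textbook f3
variant (level-weighted marginal moments) is available via
`haralick_corr="f3"`. Degenerate marginals (constant window) return 0 with
a warning for both correlation features.

The sliding-window implementation accumulates pair counts via summed-area
tables per level pair and is verified in the tests against (a) a
per-window brute-force pair enumeration and double-sum feature oracle
(|Δ| < 1e-10) and (b) scikit-image's GLCM for the four features both
define (1e-8).

## 4. Agronomy

`t ha⁻¹ = g/quadrat_m² × 0.01`; `N (kg ha⁻¹) = DM(t ha⁻¹) · 10 · N%`.
Duplicate quadrats are averaged before scaling. The difference method pairs
each legume-containing plot with the pure-grass companion of its mixture
type **in the same block** (G_CG for CG/L_CG, G_LG for LG/L_LG); if that
plot is missing the treatment mean of the remaining grass replicates is the
fallback, and a sample with no reference at all is dropped with a log
entry. Negative fixation values are retained and flagged — under the
difference method they are meaningful (reference outgrowing the sward), not
errors. Pure-grass plots never receive a fixation value.

## 5. Variable selection

The three-step forward procedure operates on permutation importance
(increase in out-of-bag MSE): (1) *thresholding* — importance is averaged
over repeated forests (default 50 runs); a CART tree of importance-sd
versus rank gives, via its minimum prediction, the noise floor below which
variables are discarded (fallback: top ⌈√p⌉ with a warning if everything
would go); (2) *interpretation* — nested models over importance-ordered
prefixes, each prefix's OOB error averaged over repeated runs (default 25);
the smallest prefix within one sd (of the minimizing prefix's runs) of the
minimum is kept; (3) *prediction* — a greedy forward pass that keeps a
variable only if its OOB improvement exceeds the mean absolute OOB step
among the noisy post-interpretation prefixes; the first variable is always
kept. Ties in importance break by column name; all run seeds spawn from one
seed sequence, so the procedure is fully deterministic given (table,
response, seed). Selection runs on the full table before splitting; this
mirrors common practice but leaks information across splits — the
`run_selection=False` flag lets a user run selection inside each
calibration split instead (at ~100× the cost).

## 6. Random forest and validation

The forest is a bagged ensemble of scikit-learn regression trees with
explicit bootstrap bookkeeping, because per-tree OOB masks are needed for
the OOB error and for randomForest-style permutation importance, which the
stock sklearn ensemble does not expose. Defaults follow the classic
regression-forest settings: 500 trees, `mtry = ⌈p/3⌉`, node size 5.
Importance permutes one shared permutation per variable per forest (the
per-tree permutation of the classic implementation averages out over the
repeated runs the pipeline always performs); the permuted matrices are
stacked so every tree predicts once.

Splits are 75/25 with **marginal coverage**: every year, harvest date and
treatment level must appear in both parts (rejection sampling; a level with
fewer than two rows raises). `mtry` is tuned per split by 5-fold CV on the
calibration rows over the grid {⌈p/3⌉−2 … ⌈p/3⌉+2} ∩ [1, p]; the paper-style
alternative of scaling mtry with n rather than p is not meaningful once
selection has reduced p below n/3, so the conventional p/3 anchor is used
and any clamping is logged.

`R²_val` centres the total sum of squares on the **observed** validation
mean by default; centring on the mean prediction (`ybar="predicted"`) is
available but makes R² incomparable across models, which is why it is not
the default. `rRMSEP` is RMSE relative to the observed range in percent.
`norm.dev = (ŷ−y)/(ŷ+y)` is bounded in [−1, 1] for positive data; the
year effect on it is tested per mixture with Kruskal–Wallis plus Dunn's
pairwise z-tests (tie-corrected, Holm-adjusted — no adjustment was a
defensible alternative; Holm is uniformly safe) and a compact-letter
display.

## 7. The synthetic experiment

The generator emulates the study design the pipeline targets: 6 treatments
(CG, LG mixtures; L_CG, L_LG pure legumes; G_CG, G_LG pure grasses) × 4
blocks of 1.5 × 12 m plots with 0.5 m pathways, 2 years × 3 harvests, 5 cm
height grid, 4.5 cm spectral grid, and four plots excluded at the last
harvest of year 2 — exactly two of them legume-containing, so the biomass
table has 140 rows and the fixation response 94.

* **Canopy.** Point heights follow a scaled Beta(2, 5) (right-skewed, like
  real sward profiles) whose support is chosen so the sample mean equals
  the plot's target height, modulated by a mean-one lognormal patchiness
  field (Gaussian random field with per-treatment correlation length;
  variance larger in mixtures than pure stands). Ground returns lie on an
  analytic DEM (tilted plane + gentle undulation); cover determines the
  canopy/ground return ratio.
* **Biomass link.** `FM ∝ height · (1 + 0.5·cover)` with multiplicative
  noise (cv 5 %); DM via per-treatment dry-matter contents (0.15 legume /
  0.20 mixture / 0.28 grass); N concentration from the realized legume
  fraction (legume 2.9 %, grass 1.6 % of DM). Treatment baselines were
  calibrated on paper so the annual treatment-year means fall inside
  realistic envelopes: FM ≈ 11–96 t ha⁻¹ yr⁻¹, DM ≈ 3.2–14.2,
  N_Fix ≈ 70–330 kg ha⁻¹ yr⁻¹.
* **Climate.** Year 1 is a drought year: legume growth × 0.6, grass
  maturing tall (height × 1.3) at unchanged biomass; in year 2 the
  unfertilized grass declines (× 0.75). This creates the year × treatment
  decoupling of height and biomass that the year-effect statistics probe.
* **Reflectance.** Band levels are saturating functions of harvest DM (NIR
  up, red down, saturation scale ~1–1.2 t ha⁻¹) plus a small legume effect
  in green/red edge, spatially autocorrelated within-plot noise with
  treatment-specific correlation length (so texture carries signal),
  bare-soil pathways, and a truncated per-plot illumination/calibration
  bias (sd 0.015) — the component that, realistically, does not average
  out over a plot and limits spectral accuracy at high biomass.

Everything derives from one `SeedSequence`, so a fixed seed reproduces the
scene byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no radiative transfer (band levels are
phenomenological curves), no weather time series, no scan geometry (points
are uniform, not distance-dependent), no registration or georeferencing
error between sensors, no species dynamics within mixtures. The max-CSH
metric inherits a heavy upper tail from the lognormal patch field, so
plot maxima can exceed realistic sward heights; order statistics up to p95
are well behaved. Absolute accuracies obtained on synthetic scenes
therefore characterise the pipeline, not any field campaign; the
qualitative structure (fusion ≥ single sensor, spectral saturation,
year effects) is what is designed to transfer.

## 8. Problem sizes of the bundled studies

The test suite and the acceptance script run reduced but structurally
complete studies, chosen as the package's defaults for routine validation:
forests of 100–150 trees (instead of the 500-tree production default),
25 repeated splits for the variant comparison, 20 seeded repetitions of the
selection-recovery study, 1000 null simulations for the test calibration.
The production-scale settings (500 trees, 100 splits, mtry tuning) are the
defaults of the corresponding API functions and of `RunConfig`.

## 9. Known limitations

* Selection before splitting (see §5) is the documented default, with the
  leakage caveat.
* The rejection-sampling split can fail on pathological designs (a stratum
  level present but concentrated); it raises after 1000 attempts rather
  than silently relaxing coverage.
* The Dunn implementation covers pairwise two-sided comparisons with Holm
  adjustment; other step-down families are out of scope.
* GeoTIFF support covers single-band rasters with pixel-scale/tiepoint
  georeferencing (sufficient for QGIS/GDAL interchange), not tiled or
  multi-band files.
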