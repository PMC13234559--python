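# Methods

## Design

`geobaci` implements a pixel-based before-after-control-impact (BACI)
evaluation with statistical matching. The estimand is the average
effect of the intervention on the treated units, identified under the
usual matching assumptions: all confounders of placement and outcome
are observed among the matching covariates (conditional independence),
and matched controls exist for every impact unit (common support). The
difference-in-difference structure additionally removes any *level*
difference between impact and control units that is constant over time,
so only confounders that affect the outcome's *change* threaten the
estimate.

## Unit definition

Units are grid cells in a projected, metre-unit CRS with square pixels,
indexed row-major from the top-left corner with half-open cell extents.
A cell is an impact unit iff its **centre** is covered by an
intervention polygon (the centre rule is standard raster practice and
makes the labelling checkable by an exhaustive point-in-polygon oracle).
Candidate controls are cells whose centre lies in the control source
region — a Euclidean buffer of configurable width around the
intervention polygons and/or explicit control polygons — minus cells
inside intervention polygons, inside exclusion polygons, or within the
spillover-exclusion distance of any intervention polygon. The spillover
buffer restricts *control* eligibility only; impact polygons are not
eroded unless an optional inner buffer is requested. Buffers are
computed on the vector geometries (with 64 quadrant segments per circle
arc, so the polygonised arcs deviate from true circles by well under a
millimetre at kilometre radii), not by raster distance transforms.

Grid origin: the bounding box of the polygons plus the largest buffer,
optionally snapped to the nearest 10^(−k) metres (half away from zero),
then expanded outward one step if snapping would shrink coverage.
Subsampling of the impact/control pools retains round-half-even(f·n)
cells drawn without replacement by a single PCG64 generator seeded from
the spec; sampling happens after all exclusions, on the final pools.
When the input CRS is geographic the grid CRS defaults to the UTM zone
of the polygons' centroid (zone = ⌊(lon+180)/6⌋+1); an already-projected
input CRS is kept. The forward transverse-Mercator projection uses the
standard WGS84 series, sub-metre accurate within a zone.

## Covariates

Terrain slope and aspect use Horn's 3×3 finite-difference kernel
(nearest-edge padding at borders); aspect is the downslope facing
direction clockwise from north and is decomposed into
northness = cos(aspect) and eastness = sin(aspect), because circular
aspect is unusable in a distance metric. Flat cells get slope 0 and
northness = eastness = 0. Distances to roads/places are Euclidean
distances from cell centres to the nearest retained geometry; a
class filter like `track+` keeps the named class and everything above
it in a user-supplied ordered hierarchy. Land cover stays level-coded
in the unit table and is expanded to K−1 indicators at model time, with
the most frequent class as the reference level.

Layers on a different grid (same CRS) are resampled at unit-cell
centres: nearest-neighbour for categorical layers, bilinear with edge
clamping for continuous ones; centres outside a layer's extent are
missing. Rows with any missing covariate are dropped with a logged
count — the matching assumes complete covariate data, and silent
imputation would be worse than a visible drop.

VIF_j = 1/(1−R²_j) with R²_j from an OLS regression (with intercept) of
covariate j on all others; categorical covariates enter as their
indicator columns individually (generalised VIF is out of scope).
Perfect collinearity reports +inf. The screening policy
`auto-drop-worst` removes the highest-VIF covariate (a categorical is
removed whole if one of its indicators is worst) and recomputes until
all VIF ≤ threshold (default 5). Greedy dropping need not find the
minimal drop set; it is transparent and reproducible.

## Matching

The default distance is the propensity score from a maximum-likelihood
logistic regression of treatment on the covariates. Distances and
calipers operate on the **logit** of the score, and the caliper is
expressed in standard deviations of the logit scores over all units —
the de-facto convention of mainstream matching software. Continuous
covariates are standardised internally before the fit for conditioning
(scores are invariant; reported coefficients are rescaled to the
original units); if Newton–Raphson fails near separation, an IRLS fit
of the same likelihood is used. Indicator levels containing a single
treatment class are dropped with a warning (their coefficient diverges
and units in such a level cannot be propensity-matched on it); genuine
perfect separation — a hyperplane splitting the classes — is an error.

Nearest-neighbour matching is greedy and sequential: impact units are
processed hardest-first (descending |logit − mean logit|; "data" and
seeded "random" orders are options — the order only matters without
replacement), each taking up to `ratio` nearest eligible controls, with
ties broken by the lowest control id. Without replacement, assigned
controls leave the pool; with a caliper, impact units with no eligible
control are reported unmatched. Mahalanobis matching uses the pooled
covariate covariance, ridge-regularised (1e-10·trace/p on the diagonal)
when its condition number exceeds 1e12. Exact matching pairs each
impact unit with every control sharing its covariate combination,
weighted 1/k.

Balance: SMD = (mean_impact − mean_control)/SD_pooled, with SD_pooled
computed once from the unmatched sample, i.e. √((s²_I + s²_C)/2), and
reused for the after-matching SMD (fixed-denominator convention, so the
before/after values are on the same scale). Matched control means are
weighted by match weights. Variance ratios, per-control selection
counts and 30-bin overlap histograms are exported as data; the Love
plot and overlap plot render them.

## Time series

NDVI = (NIR − red)/(NIR + red), missing on a zero denominator, clipped
to [−1, 1]. A yearly composite is the per-pixel median of the index
over scenes in the selected year/months whose quality mask marks the
pixel valid; scenes above the scene-level cloud-fraction threshold are
discarded outright; an even count takes the mean of the two middle
values; a pixel with no valid observation is missing. Compositing is
per-pixel on the index, not on reflectance first. Real QA-band decoding
is a provider concern: the stack interface takes a boolean mask per
scene, and scenes are read from a manifest CSV (path, date, cloud_pct)
of local multi-band TIFFs — no catalogue access.

Per-pixel metrics over a period: the temporal mean (≥1 year), and the
OLS slope of value on calendar year (units per year, regressor centred
per pixel on its observed years; missing years omitted; requires ≥3
years by default). `intercept_at` evaluates the fitted line at the
period's first or last year.

## Contrast and inference

For impact unit i with matched controls M(i) and weights w:
μ_IB/μ_IA are the unit's own before/after values, μ_CB/μ_CA the
weighted control means over M(i), and

    contrast_i = (μ_CA − μ_CB) − (μ_IA − μ_IB).

Controls matched to several impact units contribute to each
independently. The overall contrast is the unweighted mean of
contrast_i over impact units with at least one match and complete data
(excluded units are counted and reported). Significance is a two-sided
one-sample t-test of {contrast_i} against zero with df = n−1 —
aggregating controls per impact unit first keeps one contrast per
impact unit, which is also what the spatial contrast layer displays. A
Wilcoxon signed-rank p-value is reported alongside as a distribution-
free companion. The t-test assumes independent, roughly normal
per-unit contrasts with homogeneous variance; none of these are tested
by the package, and with heavy control reuse or strong spatial
autocorrelation the p-values are optimistic — use them with caution.
Degenerate cases: a single matched impact unit yields a contrast but no
p-value; zero variance yields p = 0 (contrast ≠ 0) or 1, flagged.

The spatial layer writes contrast_i at each matched impact cell (one
band per observable) plus a band holding the overall p-value at those
cells, for visual inspection of spatial impact patterns.

## Synthetic data

The generator emulates a semi-arid revegetation study at desk scale.
Terrain is a standardised sum of random Gaussian bumps scaled to
800 ± 150 m; land cover thresholds a second smooth field into K classes;
two random polylines act as roads. Intervention sites are square
polygons grown from seed cells drawn with selection weight
sigmoid(Σ β_c z_c) over standardised covariates — by default
β_elevation = 1.0 and β_dist_roads = −0.5, i.e. sites preferentially
sit on high ground away from roads, as restoration sites tend to.

Outcomes are yearly NDVI values
v = base + trend·(t−t₀) + a·z_elev + b·z_elev·(t−t₀) + field + ε(σ)
plus δ at impact pixels in the after period, rendered as NIR/red scene
pairs (red fixed at 0.2) with per-scene observation noise and random
cloud masks. Defaults: base 0.3, δ = 0.1, σ = 0.02 per year,
elevation-level coupling a = 0.05 (cancelled by the
difference-in-difference), elevation-trend coupling b = 0, two scenes
per year in March–May, 10% cloud. The standard simulated study uses a
90×90 grid at 60 m with 4 sites of 5×5 cells (100 impact pixels),
controls from a 1500 m buffer with a 180 m spillover exclusion, and
1:10 propensity matching with replacement — sizes chosen so one
replicate runs in well under a second and a 50-replicate simulation
stays interactive.

The *strongly confounded benchmark* (`pipeline.confounded_scenario`)
raises placement confounding to β_elevation = 2.0, couples the outcome
trend to elevation (b = 0.01 NDVI/yr per SD) and uses 8 sites, so the
naive all-controls estimator is reliably biased while matching on the
same covariates corrects it. With fewer sites or weaker coupling the
naive bias per replicate is comparable to replicate noise and the
matched/naive comparison is uninformative; the chosen strengths make
the confounding signal identifiable without being extreme.

What the generator does **not** emulate: radiometric realism (bands
beyond NIR/red, atmospheric effects, sensor changes), spatially
correlated cloud structure, spatial autocorrelation of the yearly noise
(the static field is spatially smooth, but year-to-year noise is iid
per pixel), and unobserved confounding. Passing tests therefore show
the estimator and its calibration are correct when the matching
assumptions hold — they cannot show robustness to hidden confounders or
autocorrelated errors in real imagery.

## Numerical choices

- Grid-origin rounding: half away from zero; sampling count:
  round-half-even of f·n.
- Median of an even count: mean of the two middle values.
- Matching ties: lowest control unit id.
- Mahalanobis regularisation: +1e-10·trace/p on the diagonal when
  cond(S) > 1e12.
- VIF ≥ 1 up to numerical tolerance; R² ≥ 1 − 1e-12 reports +inf.
- OLS trend regressor centred per pixel; slopes require Σ(t−t̄)² > 0.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seed + spec ⇒ identical outputs.

## Limitations

- Only logistic propensity models (no probit), greedy nearest-neighbour
  (no optimal/genetic/coarsened-exact matching), and no sensitivity
  analysis for unobserved confounding or spatial autocorrelation
  diagnostics — these are deliberate non-goals.
- Polygon-unit workflows are supported at the table level only; zonal
  extraction beyond cell-centre sampling is minimal.
- Vector I/O is GeoJSON; GeoPackage requires a GDAL stack and is
  rejected with a clear error. Raster georeferencing travels in a JSON
  sidecar next to the TIFF.
- No multiple-testing correction across observables; contrasts and
  p-values are reported raw, per observable.
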