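# Methods

## Overview

`routesdm` implements a virtual-ecologist experiment. A synthetic "perfect
knowledge" community — binary occupancy rasters for every species on a
shared lon/lat grid — serves as ground truth. Simulated surveys draw
sampling points inside a frame (the whole sea polygon, or a polyline route
network), record every species occupying each sampled cell (perfect
detection), and the resulting occurrence tables feed the same
stacked-species-distribution-model (SSDM) pipeline one would apply to real
data. Comparing the rebuilt richness surface with the truth isolates the
effect of the sampling design from every other source of error.

## Ensemble SDMs

Each species is modelled by an ensemble of three learners fitted to
presences plus generated pseudo-absences:

- **logistic_background** — L2-regularized logistic regression on presences
  vs random background points. With a large background sample this is a
  maximum-entropy-style estimator of relative suitability. Default 10,000
  background points (reduced profile: 1000).
- **spline_interactions** — degree-1 (piecewise-linear) spline basis per
  predictor plus pairwise products of the raw predictors, combined in a
  regularized logistic fit; an adaptive-regression-splines analogue with
  first-order interactions. Default 1000 pseudo-absences drawn beyond the
  exclusion buffer (reduced: 200).
- **bagged_trees** — random-forest *regression* on 0/1 labels, default 5000
  trees with terminal node size 5 (reduced: 100 trees), an equal number of
  buffered pseudo-absences as presences.

The learner contract is three methods (`fit(X, y)`, `predict(X)`, `name`),
so a true MaxEnt or MARS implementation can be dropped in.

Pseudo-absence schemes: `background` samples uniformly over sea cells;
`exclusion_buffer` restricts to cells beyond a great-circle buffer from
every presence, default 2.0 degrees of arc (~222 km) — the conventional
"two-degree" rule; `equal_n` is the buffer rule with n equal to the
presence count. Cells are pre-filtered by center distance with a
half-diagonal margin, then sampled points are re-checked against the exact
buffer, so the buffer invariant holds pointwise.

Cross-validation: three random 70/30 splits, presences and pseudo-absences
stratified separately so both classes appear in every test set. A learner's
weight is its mean test AUC (Mann–Whitney pairwise form, ties counting
one-half); weights are split-averaged. The learner is then refit on all
data, and the ensemble probability is the weight-normalized mean.

**Binarization.** The sensitivity = specificity threshold is found by grid
search over t ∈ {0.000, 0.001, …, 1.000} with the rule "present iff
p ≥ t"; the smallest minimizer of |sensitivity − specificity| wins ties.
The negative scores for this scan come from a background sample restricted
to cells holding no presence record. Under dense data these are exactly the
true absences, so thresholds converge to the optimum; under sparse data the
restriction removes only the few visited cells and the scan degrades to a
plain background comparison. (Scanning against the training pseudo-absences
instead biases thresholds low — heavy overprediction — because buffered
pseudo-absences are far from the decision boundary; scanning against
unrestricted background biases them high, because the background is
contaminated by true presences in proportion to prevalence.)

Stacking is the sum of the per-species binary maps. Evaluation reports
per-species sensitivity and specificity at evaluation cells (default: all
sea cells), summarized as mean ± SD across species, and the signed
(predicted − true) richness error per cell. Species without evaluation
presences (or absences) are excluded from the respective mean.

## Occurrence preparation

`quality_filter` drops records before a year cutoff (default 2000; records
with missing year are dropped unless a flag keeps them), records whose
*printed* longitude or latitude has fewer than a minimum number of decimal
places (default 3) — this operates on the CSV text because trailing zeros
are unrecoverable from floats, and numeric inputs bypass it with a log
notice — plus malformed or out-of-range coordinates and exact duplicates on
(species, lon, lat, year, month). An optional pass drops the later record
of same-species/year/month pairs within a radius (default 1 km), the
cross-database rounding-duplicate case.

`spatial_thin` enforces a minimum nearest-neighbour distance (default
10 km, haversine) by randomized greedy deletion — repeatedly remove a
record with the most violating neighbours, random tie-break — restarted
`n_repeats` times (default 10), keeping the pass that retains the most
records. Exact maximum retention is a maximum-independent-set problem, so a
restarted greedy heuristic is used, as in standard thinning tools.
`min_records_filter` keeps a species when its thinned count meets a
threshold (default 40), falling back to the unthinned set when that meets
the threshold, else dropping the species.

## Sampling designs

Polygon random: rejection sampling, uniform over sea area. Polygon regular:
square lattice with spacing √(sea_area/n) degrees and uniform random
origin, clipped to sea — the realized count may differ slightly from n;
forcing exactly n would distort the spacing. Network sampling concatenates
routes in listed order into one chainage [0, L): random draws n ~ U(0, L);
regular places points at u + i·L/n with u ~ U(0, L/n). Allocation across
routes is therefore proportional to length; a `per_route` switch applies
the design to each route separately. Chainage maps to lon/lat by linear
interpolation along segments; all geographic distances are haversine
(spherical Earth, R = 6371.0088 km).

Extraction emits one record per (point, occupying species) at the point's
raw coordinates; co-located points deliberately produce duplicate records
(rebuilds do not thin). Species with strictly more than `min_occ` records
(default 20) are retained for modelling.

## Bias statistics

The environmental-variability index is a PCA collapse of the layer stack
over sea cells: covariance-matrix PCA of the already-[0,1] layers (no
re-standardization; a correlation option exists), k = the smallest number
of components whose cumulative explained variance exceeds the target
(default 0.8), index = Σ w_i · score_i with w_i the variance share among
the k kept components, min–max normalized to [0, 1]. Component signs are
fixed by making each component's largest-magnitude loading positive.

The climatic bias index compares cell-proportion histograms over five
0.2-wide bins ([0, 0.2), …, [0.8, 1.0]; an index of exactly 1.0 falls in
the top bin): CBI = Σ_b |frame_b − whole_b|. The "sum of differences" is a
sum of absolute differences — the signed sum is identically zero — giving
the [0, 2] range of a total-variation-style distance. Histograms, not
kernel densities: the binning is part of the definition, and a histogram
reproduces it exactly.

Richness comparison is the Pearson correlation over sea cells; constant
maps raise an explicit undefined-correlation error that campaign tables
record as missing.

## Route composition and subnetworks

A route's community is the number of distinct grid cells it traverses in
which each species occurs. Traversal is exact line–rectangle intersection
(shapely); touching only a cell corner (zero-length intersection) does not
count. Rows are Hellinger-transformed (√ of row-relative abundance), which
removes route-length inflation, then Bray–Curtis dissimilarity and NMDS.

NMDS is SMACOF with isotonic regression (weak monotonicity, ties averaged),
reporting normalized Kruskal stress-1. It starts from the classical
(Torgerson) scaling configuration plus n_starts − 1 random starts and keeps
the best: purely random starts can settle into partially degenerate
solutions whose disparities collapse into ties, which the metric start
avoids. Two dimensions by default.

Clustering is average linkage on the Bray–Curtis matrix. The tree is cut at
a *relative* height — `cut` (default 0.5) times the maximum merge height —
because Hellinger/Bray–Curtis values of overlapping communities rarely
exceed ~0.6, so a fixed absolute cut tends to return a single cluster
regardless of structure; `relative=False` restores absolute semantics. The
subnetwork constructions: *biased* = the largest cluster; *community* = one
route drawn per cluster; *environment* = greedy set cover of the occupied
variability-index bins (reporting any uncoverable bins); *random_k* = k
routes uniform without replacement.

## The synthetic world

`make_world` builds a connected, roughly convex sea blob (union of jittered
ellipses, largest connected component) on a default 30 × 70 grid of 0.5°
cells — a basin roughly 35° × 15°, so that the two-degree pseudo-absence
buffer occupies about the same fraction of the domain as it would in a
Mediterranean-scale study. Layers are smooth trends plus spatially
correlated Gaussian noise, min–max normalized over sea; the first layer is
always a distance-from-shore transform (so a coastal gradient exists) and
the second carries a west–east basin trend.

`make_species` gives each species a logistic-scale suitability — random
linear plus quadratic coefficients over the layers — with class structure:
the two fish-like classes (default 20 + 13 species) get a strong nearshore
affinity, the mammal-like class (9 species) a mild offshore tilt, and
basin affinity is a 70/30 sign mixture so most species favour the same
basin (a net richness gradient) while a minority prefer the other
(composition turnover between basins). Occupancy is the top (1 − q)
fraction of sea cells by suitability, with q drawn so prevalences span
5–60%; the rank-based rule makes prevalence exact and the degenerate
quantiles (1 → empty, 0 → full range) well defined. Response parameters
are retained on the truth object for recovery tests.

`make_routes` draws port-to-port chords between sea cells on the mask edge.
The representative mode emulates a commercial network crossing the gradient
unevenly: chord lengths are skewed short (most routes are coastal hops
through the high-richness band) and 60% of routes have both ports in the
western half — the high-traffic hub — so route density is biased toward one
basin. `clustered` confines all routes to the densest-port quadrant;
`extremes` threads routes through the lowest and highest cells of the
variability index. Chords are checked against the sea mask by dense
sampling and redrawn on failure (up to 200 retries per route).

What the generator does *not* emulate: real bathymetry or coastlines,
ferry schedules and seasonal effort, temporal dynamics, imperfect or
method-dependent detection, taxonomic misidentification, and spatial
sampling bias within the truth data itself. Passing campaign tests
therefore show that the *pipeline* recovers designed-in structure under
perfect detection — not that any particular real network is adequate.

One structural difference from empirical truth communities matters when
comparing magnitudes: a truth SSDM fitted to real repository data is itself
a heavily overpredicting binary model, so its effective prevalences are
much higher than this generator's 5–60% calibration. Detection is
therefore more limiting here — notably, spreading 50 points over many
routes can retain fewer species than concentrating them on two — which
flattens and roughens the correlation-vs-route-count ramp relative to what
higher-prevalence truths produce. The campaign-level assertions are
accordingly directional, at Monte-Carlo (2 SE) tolerance.

## Determinism and seeds

Every stochastic operation takes an explicit seed and uses
`numpy.random.default_rng`. Campaign replicate seeds are derived by CRC32
hashing of (master seed, arm label, frame, strategy, n, replicate), kept
below 2³¹, so arms are mutually independent but the whole campaign is
bit-reproducible from one integer. Identical seeds reproduce worlds,
species, routes, fits and tables exactly.

## Problem sizes

The default test and acceptance profile (`SDMConfig.fast`,
`CampaignConfig.fast`) uses 1000 background / 200 buffered pseudo-absences,
100 trees, 100–200 detection replicates and 2–3 SSDM rebuilds per arm on
the 30 × 70 default world; the full-scale profile (10,000 background
points, 5000 trees, 1000 detection replicates, 40 rebuilds) is the plain
`SDMConfig()` / `CampaignConfig()` default for production runs. The
acceptance script reports the arm sizes it used in each entry's `n` field.

## Known limitations

- Ensemble learners are surrogates, not the historical MaxEnt/MARS/RF
  implementations; coefficients are not comparable to those tools, only
  the pipeline structure is.
- The greedy thinning and greedy set cover are heuristics; both are exact
  only on small or well-separated inputs (the regimes the oracle tests
  cover).
- Regular polygon sampling returns the lattice's realized point count, not
  exactly n; campaign tables record realized counts.
- Pearson correlation of richness surfaces treats cells as independent;
  no spatial autocorrelation correction is attempted.
- The CLI exchanges rasters as CSV grids and routes as GeoJSON; no
  GeoTIFF/projection handling is included, and coordinates are assumed
  WGS84 lon/lat throughout.
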