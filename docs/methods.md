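# Methods

`nes_atlas` implements a conservation-prioritisation pipeline for narrow
endemic plant species (NES) on gridded landscapes, together with a
ground-truthed synthetic landscape generator that makes every stage
testable without access to herbarium data.  This note records the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic experiments do and do not demonstrate.

## Spatial reference

All distances and areas are computed on a metric plane.  Occurrence
records arrive in WGS84 degrees and are projected with a spherical
transverse Mercator centred on the study extent
(`projection.TransverseMercator`); for an extent a few degrees across the
planar scale error stays below ~0.1%, far inside the 1% error that would
matter for a 10-km threshold rule.  Grid cells are half-open squares
`[x0 + i·w, x0 + (i+1)·w)`; a point on a shared edge belongs to the cell
to its east/north, so every point has exactly one cell.  Rasters are
stored south-to-north in memory and serialised as ESRI ASCII grids
(plain text).

## Narrow-endemism classification

A species' *locations* are the connected components of the graph linking
any two of its records strictly closer than 10 km (single linkage).
Chaining is intentional: a continuous ribbon of records with no 10-km
discontinuity is one location, however long it is.  Species with 1, 2 or 3
locations are NES 1/2/3; anything else is not narrow-endemic.  The
10-km threshold and the strictness of the inequality are configurable.

Range metrics follow the IUCN definitions: area of occupancy (AOO) is the
number of occupied 2-km cells times 4 km², on the same grid origin as the
hotspot analysis (the origin is configurable, and a shift-sensitivity scan
is provided because any grid-based statistic depends on it); extent of
occurrence (EOO) is the convex-hull area of the records.  Degenerate hulls
(fewer than three distinct points, or collinear ones) get EOO 0 plus an
explicit flag rather than an imputed floor — the smallest-area category is
a binning decision, applied only when frequency distributions are built.

Frequency-distribution comparisons between classes use Pearson correlation
on identically binned counts, with a two-sided t-test on `bins − 2`
degrees of freedom.  Zero variance in either binned vector returns an
explicitly undefined result instead of propagating NaNs.  Bin edges are a
parameter (log-spaced by default); published analyses of this kind report
that reasonable re-binning does not change the conclusions, and the same
holds for the synthetic worlds.

## Hotspot grid

Distinct NES are counted per 2 × 2 km cell; a species counts once per cell
no matter how many records it has there, so `n_nes1 + n_nes2 + n_nes3 =
n_nes_total` by construction.  A *hotspot of plant narrow endemism*
(HPNE) is a cell with strictly more than 7 distinct NES (8 or more).
Named geographic features (massifs, valleys) aggregate species as the set
union over the cells whose centres the feature polygon covers; overlapping
polygons assign contested cells by feature-name order with a warning — a
deterministic replacement for expert judgement about boundary records.

Sampling-bias checking is Pearson correlation between per-cell collection
effort and per-cell NES richness; the synthetic `effort_field` provides
uniform and covariate-biased effort at a configurable strength so the
machinery can be tested under a known truth.

## Threat overlay

Point-in-polygon tests count boundary points as inside.  Per species we
report the fraction of records inside protected areas and inside mining
footprints, plus list-based protection; the priority flags are
`all_mined_unprotected` (every record mined, no listing, no protected
record) and `half_mined_unprotected` (at least half the records mined,
same protection bar), in that precedence.  Requiring *both* the absence of
listing and the absence of protected records is deliberately conservative.

A hotspot cell is protected if it intersects a protected polygon and
mining-impacted if it intersects *or shares an edge with* a mining polygon
(corner-only contact does not count) — "adjacent" needs a reproducible
definition and edge-sharing of the 2-km cell is the conservative one.  The
cell's substrate label is the modal class of the fine geology cells under
it, reported as a mixed label `A/B` when the top two classes each cover at
least 40%.

The packaged `data/hpne_table.csv` is a transcription of the published
table of 36 New Caledonian HPNE (name, province, per-class counts,
coordinates, protection, mining, substrate).  One printed row ("Mont
Ignambi 2") has class counts summing to 7 against a printed total of 8;
the transcription keeps the printed values and `summarize_hpne_table`
reports the mismatch count rather than silently repairing it.

## Environmental stack

Slope comes from Horn's 3 × 3 weighted finite differences; the DEM is
padded by linear extrapolation, which degrades gracefully to one-sided
differences at edges and is exact for planar terrain.

Rainfall interpolation is a two-step scheme in the tradition of
topography-aware precipitation mappers.  Step one describes the
topography around every cell by the raw elevations in square windows of
radius 1, 2, 4 and 8 cells (the columns are centred by the PCA itself), and
keeps the leading principal components — by default enough to explain
99.9% of window-elevation variance, typically ~10 components.  The kept
set must span per-cell elevation well: with only the first two or three
broad components the regression cannot represent an elevation-linear
rainfall trend, which is the dominant signal.  Station rainfall is then
regressed by OLS on scaled (x, y) plus the component scores at station
cells.  Step two fits an exponential semivariogram to the regression
residuals (empirical semivariances on 12 distance bins up to half the
maximum pairwise distance, weighted least squares with Cressie weights
N(h)/γ²; the nugget can be freed or pinned to zero) and interpolates the
residuals by ordinary kriging.  Kriging weights satisfy the unbiasedness
constraint (they sum to 1), and with a zero nugget the prediction at a
station reproduces the observation to machine precision.  Predictions are
truncated at a ceiling (default 4900 mm — linear trends overshoot on
extreme terrain) with the truncated fraction reported.

The jackknife comparison predicts each station from the others, for this
method and for a trivariate thin-plate spline on (x, y, elevation) with
coordinates scaled to unit variance (otherwise the vertical axis is
numerically invisible).  The residual variogram is estimated once from the
full-station fit and reused across folds; refitting it per fold adds noise
and an order of magnitude of cost without changing the verdict.  On
rainfall fields with a genuinely topographic component (an
orographic-exposure term proportional to local relief, which a smooth
trivariate spline cannot represent but multi-scale window components span),
the two-step method wins the jackknife in ~90% of seeds.  On fields that
are exactly linear in elevation both methods are near-exact and the
comparison is uninformative.

Temperature is consumed as an input layer (in the synthetic worlds, an
exact lapse of elevation), not interpolated: real analyses of this kind
take temperature from an external climatology.

## Ecological grouping

Each species is summarised by the means of altitude, slope, annual
rainfall and mean temperature over its valid record cells and the mode of
the substrate class (ties broken in the documented order U < V < L < R).
Gower distance averages range-normalised absolute differences for the four
continuous variables and a 0/1 mismatch for the categorical one, so a lone
substrate mismatch contributes exactly 0.2.  Zero-range variables are
dropped with a warning.

Three structure finders run on the distance matrix: partitioning around
medoids (greedy BUILD then best-improvement SWAP, deterministic, objective
never increasing), average-linkage (UPGMA) hierarchical clustering, and
non-metric multidimensional scaling (SMACOF with monotone regression,
Kruskal stress-1 with primary tie handling, a classical-scaling start plus
eight seeded random restarts).  The Calinski–Harabasz index needs
coordinates, so it is evaluated on a classical-scaling embedding of the
distances (dimension `min(n − 1, 10)`); silhouettes are computed directly
on the distances.

**Group-number selection.**  Mean silhouette alone is unreliable on this
kind of data: a medoid partition will happily slice a continuous
environmental gradient into bands, and such slices can out-score the real
structure.  The selection rule therefore formalises the classic visual
override ("are the clusters actually isolated?") as follows.  Candidate
partitions are the PAM result, the UPGMA cut and the single-linkage
(connectivity) cut at every k, each after absorbing clusters of fewer than
3 members into their nearest cluster (stragglers, the formal counterpart
of ignoring isolated points on an ordination plot).  A candidate is
*admissible* only if every pair of its clusters is separated by a
single-linkage gap of at least 4 median nearest-neighbour spacings — a
gradient slice has a gap of about one spacing, while substrate-separated
clouds in Gower space sit at least 0.2 apart (7–15 spacings in practice).
Among admissible partitions the finest (largest k) wins, because one never
merges two genuinely isolated clusters; silhouette breaks ties, and if
nothing is admissible the best-silhouette candidate is kept with a note.
Connectivity cuts matter because within-substrate clouds are connected
gradients: compactness-driven methods mix low-altitude members across the
substrate boundary, whereas connected components respect the
discontinuity.  The agreement between the PAM partition and the tree cut
at the chosen k (adjusted Rand index) is always reported.  A recursive
sub-group search (per-group silhouette maxima) is available and on by
default in `run_grouping`.

## Habitat suitability (maximum entropy)

The presence-background model gives cell x the probability
`p(x) = exp(λ·f(x)) / Z` over the background sample, with features f built
from the stack: each continuous covariate is min-max scaled over the
background (clamped at prediction time, clamping reported) and contributes
a linear and a quadratic feature; the substrate contributes one indicator
per class; optional left-hinge features at background quantile knots exist
behind a flag (off by default — the small-instance oracle used in testing
stays tractable, and the quadratic set is sufficient at these sample
sizes).  The weights maximise the L1-penalised presence log-likelihood

    L(λ) = mean_presence(λ·f) − log Z(λ) − Σ_j β_j |λ_j|,

with `β_j = multiplier · sqrt(Var_presence(f_j) / m)` (multiplier 1 by
default), which is the maximum-entropy distribution subject to
`|E_model f_j − mean_presence f_j| ≤ β_j`.  The optimiser is cyclic
coordinate ascent: the coordinate gradient is the presence-model mean gap,
the curvature is the model variance of the feature, the L1 penalty enters
by soft-thresholding, and each step backtracks until the objective does
not decrease — so the objective trace is monotone and the per-coordinate
gains can be accumulated into per-covariate *percent contributions*.
Iteration stops when a full sweep improves the objective by less than
1e-5 (cap 500 sweeps).  Defaults mirror the standard desktop
configuration: at most 10000 background cells sampled without replacement
(presences not removed), a 25% seeded test split, prevalence τ = 0.5.

The logistic output is `τ e^H p(x) / (1 − τ + τ e^H p(x))` with H the
entropy of the raw distribution over the background, so a model that has
learned nothing scores τ = 0.5 everywhere.  AUC is the rank probability
that a presence out-scores a background cell (ties at 0.5).  Permutation
importance permutes one covariate across the pooled presence+background
table, rebuilds features, and averages the training-AUC drop over 10
seeded permutations, normalised to sum to 100 over covariates.  Marginal
response curves come from single-covariate refits, with a direction label
(increasing / decreasing / unimodal / bimodal / flat) from the sign
changes of the smoothed derivative.  When two covariates are exactly
collinear — in the synthetic worlds temperature is an exact lapse of
elevation — the attribution of their shared signal between them is
arbitrary in principle; interpretation of importances should treat such
pairs jointly.

Hotspot-model comparison resamples the suitability surface to the hotspot
grid by the mean and cross-classifies cells into hotspot-and-suitable /
hotspot-only / suitable-only / neither at a 0.75 cutoff; the
suitable-only list is the candidate set of under-sampled sites.

## The synthetic landscape

`synthetic_data.generate_world` builds, from a single seed (bit-identical
reruns):

- **Terrain** — a sum of 24 Gaussian bumps (300–1100 m high, 4–12 km wide)
  saturated smoothly at 1650 m, the maximum relief of the study system;
  saturation matters because unbounded bump sums produce implausible
  3-km peaks whose altitude bands masquerade as ecological clusters.
- **Substrate** — 150 Voronoi patches labelled U/V/L/R with target shares
  (0.33, 0.45, 0.12, 0.10); ultramafic covers about a third of the land.
  The mosaic is deliberately fine-grained: with few large patches,
  single-location species inherit their patch's mean environment and the
  species cloud clumps patch-by-patch, which is not how a real
  fragmented substrate map behaves.
- **Climate** — temperature is an exact lapse `t0 − 0.0065·z`; rainfall is
  `1500 + 1.2·z` mm plus a Gaussian random field with exponential
  covariance (sd 150 mm, range 30 km), sampled exactly by random Fourier
  features (the 2-D spectral measure of the exponential kernel has a
  closed-form inverse radial CDF).  60 stations sample the true field.
- **Species** — 200 species in three groups (15% lowland L/R, 42.5% V,
  42.5% U).  Substrate affinity is 0.95 at the level of both location
  centres and individual records (obligate edaphic specialism with a
  5% allowance for substrate-map error); altitude niches are lowland for
  group 1 and montane-biased (0.3–1.0 of the relief) for groups 2–3, the
  substrate-dominant regime reported for the real flora.  Location counts
  are drawn from a configurable distribution over {1, 2, 3, many}; cluster
  centres are pairwise ≥ 20 km apart and records stay within 1 km of their
  centre, so re-running the 10-km rule reproduces the planted location
  counts *exactly* — the margins are construction guarantees, not
  statistical tendencies, and configurations that would blur them
  (separation ≤ 10 km, spread ≥ 10 km) are rejected.
- **Hotspots and management** — four planted hotspot cells each receive
  10 extra single-location species (with a margin from cell edges, so the
  default grid origin captures them); two get protected polygons; mining
  polygons are drawn over the full record sets of five known species, so
  threat scoring has an exact truth.

What the synthetic experiments show: that every estimator recovers what
was planted under margins the construction guarantees, that the maxent fit
agrees with an independent convex maximiser, and that the two-step
rainfall interpolation beats a trivariate spline precisely when the field
has multi-scale topographic structure.  What they do not show: robustness
to georeferencing error, taxonomic noise, spatially *ad hoc* collection
effort correlated with diversity, or substrate maps that disagree with
the ground — the known hard parts of real herbarium data.  The bias
machinery is tested under known effort fields, which is a statement about
the machinery, not about any real dataset's bias.

## Problem sizes

Default experiments use 100 × 100 km worlds at 1-km resolution, 200–240
species (~2700 records), 60 stations, and 20 seeds for the recovery
experiments; the grouping-recovery experiment uses the three-substrate
configuration (no riverbank class), where the planted structure is exactly
three isolated groups.  These sizes keep the full test-and-acceptance
cycle in a few minutes while leaving every recovery margin intact.
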