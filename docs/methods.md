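# Methods

This note documents the models and procedures implemented in `geomob`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## From points to trips

**Place detection.** Geotagged posts carry coordinate scatter: a user
tweeting twice from one building or park produces nearby but unequal
coordinates, which must not count as travel. Points are therefore
clustered into *places* with a density criterion: two points within
`radius_m` (default 500 m, a conventional walkable distance) of each
other belong to the same place, with the minimum cluster size set to 1
because post streams are sparse. At minimum size 1 this clustering is
exactly the connected components of the ≤ radius graph, which is how it
is computed (the DBSCAN implementation in scikit-learn, haversine
metric, is the code path for larger minimum sizes and the cross-check
oracle in the tests). Distances are great-circle on a sphere of radius
6,371,000 m; at the 500 m scale the choice of earth model is
irrelevant. A place is represented by the arithmetic mean of its member
coordinates.

**Clustering scope.** Clustering runs *per user per calendar day*
(configurable to per-user-whole-period). A single global clustering at
500 m linkage over a dense city centre would chain most of the centre
into one giant place and destroy trip extraction; the coordinate-jitter
problem the clustering solves is a property of one user's posts.

**Daily trips.** Within each (user, local calendar day) — local time
defaults to Europe/London — points are ordered chronologically and one
trip is emitted per consecutive pair of points assigned to different
places, with distance measured between place centroids. Consecutive
pairs, not all pairs, keep trip counts additive over the day. The
"within 24 hours" windowing is read as the local calendar day, matching
the daily aggregation of the indices; displacements that straddle
midnight are deliberately dropped.

## Mobility indices

For each day, `m_rate` = (number of users with ≥ 1 trip) / (number of
users with ≥ 1 point), and `avg_dis` = the mean over movers of each
mover's *own* mean trip distance that day. The user-weighted (not
trip-weighted) average follows the index's definition as a per-user
quantity; the two differ whenever trip counts vary across movers, and
the test suite pins the user-weighted reading.

Annual summaries report the mover share under two conventions — the
ratio of daily means and the mean of daily ratios — because published
summary tables in this literature mix them; the ratio-of-means
convention is the primary, tested one.

**Decomposition.** The daily index series are decomposed additively by
the classical moving-average method (statsmodels `seasonal_decompose`,
period 7): the trend is the centred 7-day moving average, the seasonal
component the re-centred per-weekday mean of the detrended series. The
additive identity (trend + seasonal + residual = observed where the
trend is defined) and the zero-sum of the seasonal component over one
period are asserted in tests.

## Flow networks and attractiveness

Zone-assigned trips (point-in-polygon of place centroids; boundary
points count as inside, ties broken to the lowest zone index) are
aggregated to Monday-start weeks. Weekly OD matrices keep intra-zone
trips as self-loops. Attractiveness is the *share* reading of weighted
degree centrality: `A(i,t)` = weighted in-degree of zone `i` (self-loops
included) divided by the total trips of the period, so shares sum to 1
and period-to-period differences sum to 0. In-degree ("how much a zone
is visited") is the default; out- and total-degree variants are
exposed. Network summaries count edges as distinct directed zone pairs
excluding self-loops, with self-loop trips reported as the intra-zone
trip share.

**Communities.** Modularity for directed flow graphs has no single
standard definition, so detection runs on the symmetrized graph (edge
weights summed over the two directions, self-loops kept) with the
deterministic greedy (CNM) maximiser; the reported Q is recomputed
independently from the returned labels as a self-consistency check, and
an exhaustive-partition oracle on an 8-node two-clique fixture confirms
the maximiser finds the optimum there. Communities smaller than
`max(1, mean size − 1·SD of sizes)` are flagged *isolated* — the
scattered pockets weakly connected to the rest of the city. The 1·SD
rule and its floor are configurable; with equally sized communities
(SD = 0) nothing is flagged.

## Temporal profiles

Per-zone weekly attractiveness over a fixed Monday-indexed calendar
(112 weeks for the 2019-01-07 … 2021-02-22 study window) forms the
zone's temporal profile; unobserved weeks are 0, a real "no visits"
observation. Zones are clustered by profile *shape* using agglomerative
clustering under correlation distance `d = 1 − Pearson r` — a zone and
its uniformly scaled copy are at distance zero — with average linkage
(a robust default for correlation distances; complete/single are
configurable) and k = 3 by default. Constant profiles have undefined
correlation; they are dropped (detected with a relative variance
threshold, since float roundoff leaves ~1e-16 scatter on a constant
row) and reported. Labels are renumbered by the lexicographically
smallest member zone, making the output invariant to input row order.
Choosing k is left to the analyst via the exposed dendrogram merge
table; no automatic selection criterion is applied.

## Spatial statistics

Queen contiguity (any shared boundary point) is derived from polygon
intersection of the interior-disjoint zones; weights are
row-standardized, islands get zero rows and are logged. Statistics:

* global Moran's I = `(n/S0) Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)²`;
* local Moran `I_i = z_i · Σ_j w_ij z_j` with z the population-SD
  standardization, quadrants HH/LL/HL/LH from the signs of `z_i` and
  its spatial lag;
* bivariate Moran `I_xy = (n/S0) Σ_ij w_ij z_x,i z_y,j / Σ_i z_x,i²`,
  which with population-SD standardization is equivalent to the
  n-denominator form; the local variant is `z_x,i (W z_y)_i`.

Inference is by permutation throughout (999 draws by default): random
relabelling for global statistics, conditional permutation (neighbour
values redrawn without replacement from the other zones) for local
ones, and y-relabelling with x held fixed for the bivariate family.
The pseudo p-value is two-sided with the +1 correction,
`(#as-extreme + 1)/(n_perm + 1)`, extremity measured from the null
expectation (−1/(n−1) for univariate I, 0 otherwise). All statistics
are verified against naive double-loop oracles to 1e-12, and the
type-I error of the permutation test is checked against the nominal
level by simulation.

The weekly correlation suite aligns attractiveness and case counts on
the weight matrix's zone universe: zones without visits enter with
share 0; zones missing from the case table are dropped with the weights
re-standardized on the remainder, and logged. Weeks where either
variable is constant yield NaN statistics rather than errors. Raw
per-week p-values are reported without multiple-testing correction
across weeks; users comparing many weeks should account for that.

## The synthetic-data generator

The generator emulates the structure the pipeline consumes, not urban
behavioural realism. Activity streams: every user posts every day from
a home place sampled centre-weighted (or uniformly) over the zone
system; with probability `p_mover` (default 0.3) a user-day contains
`1 + Poisson(0.5)` trips whose lengths are log-normal with median
5.4 km and log-SD 0.5 — the scale of observed crow-fly trip distances
in a large metropolitan area — truncated below at 1.2× the clustering
radius so planted places remain separable. Points jitter uniformly
within 100 m of the true place and timestamps follow a double-peaked
diurnal profile (morning and late-afternoon peaks). The planted truth
(per-user-day trips with true distances, mover flags) is always
returned beside the stream.

Case surfaces: per week a latent field solves the simultaneous
autoregression `u = ρWu + ε` (|ρ| < 1 keeps the system invertible, and
the SAR construction produces exactly the kind of smooth structure
Moran's I detects); expected cases are
`base_rate + coupling_b · standardized attractiveness + u`, rounded and
floored at zero by default — deterministic rounding keeps coupling
recovery clean at small n, with Poisson sampling available by flag.

What passing recovery tests shows: with jitter ≪ radius and inter-place
distances > radius, the pipeline recovers planted trip counts exactly
and planted distances to centroid-jitter accuracy, and the spatial
statistics detect planted autocorrelation and coupling at the expected
rates. What it does not show: robustness to the features of real
streams the generator omits — uneven user activity and dropout, places
closer together than the clustering radius (where place identity is
genuinely ambiguous), bursty reposting, location spoofing, population
bias of who posts, and reporting artefacts in case data. The cleaning
stage does bite on synthetic data (the abnormal-account rule removes
the heaviest posters, who are disproportionately frequent movers,
nudging the recovered mover share slightly below the planted rate), but
its yearly mean + 1 SD threshold is a heuristic whose real-data
behaviour depends on the actual account mix.

## Problem sizes and numerical choices

The reference synthetic study uses a 12×12 zone grid (~4.5 × 3.3 km
cells over a GLA-sized bounding box) with 2000 users over 30 days
(~113k points, ~27k trips); calibration experiments use 6×6 grids with
50 null replicates at 199 permutations, and oracle comparisons 5×5
grids — sizes chosen so the full check suite completes in minutes while
keeping Monte-Carlo errors well inside the asserted tolerances. Grid
zones are built on shared lattice coordinates so adjacent cells touch
exactly (naive per-cell arithmetic leaves 1-ulp gaps that break queen
contiguity). The mover-rate recovery tolerance is 3 binomial standard
errors of `p_mover` at the user count; distance recovery is bounded by
the jitter radius. Cleaning filters: bounding-box and static-user
removal are idempotent (and tested as such); the abnormal-account
threshold is a one-shot rule — re-applying it re-estimates mean and SD
on the filtered counts and may remove more users, so it is applied
exactly once, in the bbox → abnormal → static order.

## Known limitations

* Attractiveness is degree-based only; eigenvector/betweenness
  centralities can be computed on the exported networks but are not
  part of the tested surface.
* Directed-modularity community detection, gravity-type flow models,
  space–time regression and any causal analysis of the
  mobility–case relationship are out of scope.
* Local Moran permutation p-values are per-zone and uncorrected.
* The calendar-day trip convention undercounts displacements that
  straddle midnight; with the default diurnal profile these are rare.
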