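# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Utilization distributions and home ranges

The UD estimator is the fixed bivariate Gaussian product kernel

    f̂(x, y) = (1/n) Σ_i φ((x−x_i)/h_x)/h_x · φ((y−y_i)/h_y)/h_y,

evaluated on a regular grid and renormalized so the discrete mass
`Σ f̂ · c²` is exactly 1. The bandwidth matrix is restricted to a diagonal:
each axis gets the univariate **two-stage direct plug-in** bandwidth
(normal-scale start for the eighth-derivative functional ψ₈, then two
kernel functional-estimation stages ψ₆ → ψ₄, then
`h = (1/(2√π ψ̂₄ n))^{1/5}`). A diagonal matrix is the standard
reproducible reading of "plug-in" bandwidth selection for telemetry data
and is directly testable against the Gaussian-reference value
`1.06 σ n^{−1/5}` (the suite requires agreement within a factor
[0.7, 1.3] on standard-normal samples). The scale estimate is
`min(sd, IQR/1.349)`; the Gaussian-reference rule is the fallback if ψ̂₄
comes out non-positive (only reachable on pathological inputs).

Grid convention: origin at the lower-left cell corner, row 0 southernmost,
square cells, half-open cell membership. Default cell size 50 m with the
extent equal to the point bounding box padded by 3·max(h_x, h_y); at the
1–25 km² home-range scales this package targets, halving the cell changes
isopleth areas by well under the 3% stability bound the tests enforce.

A home range at level *p* is the **highest-density cell set**: cells
ranked by density (ties broken row-major) and accumulated until the
cumulative mass first reaches *p*. Keeping the region as a cell set — not
a smoothed contour — makes the overlap integrals below exact over the
discrete UD. Areas are reported in km².

Estimation requires ≥ 20 locations by default. The threshold is a
widely-used telemetry inclusion rule; `allow_few=True` overrides it
because field datasets routinely include one individual a fix or two
short. MCP-100% (shapely convex hull, shoelace area) is kept separate
from the kernel estimate and drives the accumulation curves, which are
monotone by construction (hull of a superset contains the hull).
Per-species summaries report median/min/max, since home-range sizes are
right-skewed at these sample sizes. Note that the published
per-individual table bundled in `nichekit.reference` is internally
inconsistent with its own printed summary for one species (the six ocelot
areas have median 7.5 and max 16.1 km², not the printed "8.0 (3.8–6.1)");
`summarize_home_ranges` reports what the table implies.

## Overlap indices

For animals (or pooled species) *i, j* on a common grid:

* `PHR_ij = Σ_{cells ∈ HR_i} UD_j · c²` — asymmetric, in [0, 1]; the
  diagonal equals the isopleth level up to grid discretization (±0.5
  percentage points at the default grids).
* `UDOI_ij = A_ij · Σ_{cells ∈ HR_i ∩ HR_j} UD_i · UD_j · c²`, with
  `A_ij` the area of the home-range intersection. Dimensionless; 0 iff
  the ranges share no cell; 1 for identical uniform UDs over identical
  ranges; > 1 when two peaked UDs coincide (two identical standard-normal
  UDs at the 95% level give `(πq)(1−e^{−q})/(4π) ≈ 1.497`, `q = 5.9915`,
  which the tests check against the closed form).

Species-level matrices **pool all locations of a species into one UD**.
That is the only aggregation that yields a single species-by-species
matrix from per-individual data; an individual-level matrix is provided
alongside. All species UDs are estimated on one shared grid (union extent,
per-species plug-in bandwidths) so no resampling error enters the
integrals; a bilinear `resample_ud`/`align_uds` path exists for UDs built
elsewhere, renormalizing after interpolation.

## Compositional habitat selection

Designs: **Type II** compares habitat proportions inside each
individual's 95% home range (use) against proportions over the species'
study area (availability), where the study area is the convex hull around
the home-range cells of all individuals of that species — a data-driven
polygon that avoids an arbitrary study-area choice. **Type III** compares
the proportions of the radio locations themselves against availability
within the individual's home range. Proportions are measured on the
habitat raster by cell-centre membership; a Monte-Carlo point-sampling
oracle in the tests confirms agreement to ±0.01.

With reference habitat *r* (default: last legend class; the statistic is
invariant to the choice, which the tests verify), each individual yields
`y = (d_k − d_r)_{k≠r}` with `d_k = ln U_k − ln V_k`. The overall test is
the one-sample MANOVA

    Λ = |Σ(y−ȳ)(y−ȳ)'| / |Σ y y'|,   χ² = −N ln Λ on D−1 df,

computed via `slogdet` for stability; a singular total cross-product
matrix raises with advice to merge classes or use randomization.

Two p-values are offered:

* **Parametric** (χ² reference). This is the field's conventional
  computation and reproduces published (Λ, N, χ²) triples exactly through
  the −N ln Λ identity. It is, however, known to be anti-conservative in
  small samples: via the Hotelling T²/F relation its exact size at
  N = 20, D = 5 is 0.090 at nominal 0.05 (a dedicated test pins this
  number down). Treat parametric p-values near the threshold with
  caution at telemetry-scale N.
* **Randomization** (sign-flip of each individual's y-vector; full 2^N
  enumeration when N ≤ 10, otherwise seeded resamples; p = fraction of
  resampled Λ ≤ observed). Exact under the symmetric null; simulation in
  the suite shows empirical size 0.05 ± 0.02 at N = 20, D = 5. This is
  the mode the acceptance suite uses for the size guarantee.

Pairwise structure is summarised by the antisymmetric matrix of mean
log-ratio differences with **paired t statistics and raw two-sided
p-values per pair** (no multiplicity correction — matching the
conventional presentation of such tables, and stated as such in the
output header); habitat ranks count positive row entries, so absent ties
the ranks are a permutation of 0..D−1. Zero-use habitats break the
log-ratio; `zero_replace` substitutes 0.0001 and renormalizes, and it is
**off by default** since compositions without zeros need no repair (the
model front end enables it explicitly).

## Activity patterns

**Sun time.** Detection clock times are rescaled per date with the
double-anchored map sunrise ↦ 06:00, sunset ↦ 18:00; the light period is
divided into 12 equal "day hours" and the dark period into 12 equal
"night hours". The map is a strictly increasing circular bijection that
reduces to the identity on a 12-hour day, and it removes day-length
seasonality before any pooling across months. Sunrise/sunset come from
the standard NOAA solar-position equations (zenith 90.833°, refraction
included), accurate to about ±2 minutes against published calculators;
polar latitudes are rejected. A caller can pass precomputed `SunClock`
values to replicate an external almanac exactly.

**Circular KDE.** The density is the mean of von Mises kernels on the
24-h circle, evaluated on a 1-minute grid (m = 1440; all interval
arithmetic lives on this grid) using the overflow-safe
`exp(κ(cos θ − 1))/(2π I₀e(κ))` form. When κ is not supplied it is chosen
by leave-one-out log-likelihood over the dyadic grid κ ∈ {1, 2, …, 1024}
— the circular analogue of likelihood cross-validation for a smoothing
parameter; the selected κ grows with n as expected for a kernel
concentration (it is not an estimate of the data's own concentration).
Densities are renormalized to exact unit mass on the grid.

**Active periods and overlap.** The 95% and 50% isopleths are
highest-density minute sets (nested by construction, wrap across midnight
allowed; a wrapping interval is reported with end > 24). Published
activity-overlap percentages of this kind do not come with a stated
denominator, so the package defines its headline number explicitly as
**intersection over union** of the two species' isopleths at matched
level — symmetric, bounded in [0, 100], 100 iff identical — and also
emits both directed shares (intersection over each species' own active
period) for readers who want the asymmetric view. This is an interpretive
choice and is labelled as such here.

## Synthetic data and what recovery tests show

The generator emulates the study design, not animal movement per se:

* **Landscape** — Gaussian-smoothed white noise thresholded at the target
  class quantiles: seedable, proportion-exact up to cell rounding, with
  patch size controlled by the smoothing scale.
* **Telemetry** — exact rejection sampling from
  `f(x) ∝ φ(x; μ, Σ) · w_{h(x)}`; with equal weights the locations are
  bivariate normal (analytic 95% ellipse area `π q √|Σ|`, q the 0.95
  χ²₂ quantile), with unequal weights the induced use/availability
  log-ratios are known. One fix per simulated day at a uniformly random
  hour mirrors a realistic once-daily tracking cadence and gives
  accumulation curves a natural x-axis. **No autocorrelated movement**
  (OU/CRW) is simulated: the estimators treat fixes as independent, and
  the generator matches that assumption. Passing recovery tests therefore
  certifies the estimators under their own assumptions; they say nothing
  about bias from serially correlated real trajectories.
* **Activity / camera** — detection times from per-species von Mises
  mixtures; camera streams are Poisson in count
  (`rate · days · stations`) with diel placement proportional to the
  mixture density, i.e. an activity-thinned stream. Spatial heterogeneity
  between stations, bait effects and 10-second burst duplicates are not
  modelled.

Default study scale (`default_study_config`): three species with 6–7
individuals each, 40–90 daily fixes per animal, ~1–25 km² ranges on a
10 km × 10 km five-class landscape, ~1500 camera records — the scale the
recovery guarantees are stated at, chosen to mirror a realistic
mesocarnivore field campaign.

Recovery guarantees enforced by the suite: 95% kernel area within ±15% of
the analytic ellipse in ≥90% of 100 replicates at n = 500; randomization
compositional test size 0.05 ± 0.02 over 1000 nulls at N = 20, D = 5;
95%-isopleth activity overlap within ±5 points of the true-density
overlap (median of 50 replicates at n = 400 records per species).

## Numerical details and degenerate inputs

* Isopleth ties broken by (row, col) order; the included mass is minimal
  in the sense that dropping the least-dense included cell falls below
  the level.
* `estimate_ud` refuses zero-variance axes and < 10 points (bandwidth
  stage) and < 20 locations (inclusion rule, overridable).
* Collinear or < 3 points give MCP area 0 with a warning rather than an
  error, so accumulation curves can start at k = 3 regardless.
* All-identical activity times fall back to the top of the κ grid with a
  warning (a point mass cannot be cross-validated).
* Readers reject individual malformed rows with a logged reason and never
  silently drop whole files; UD/habitat raster round-trips are identity
  to 6 significant digits and exactly for class codes.
* Every stochastic routine takes an explicit seed or Generator;
  `run_pipeline` derives per-stage substreams from one master seed, so a
  config + seed reproduces every output byte-for-byte.

## Known limitations

* Diagonal bandwidth only — no full plug-in bandwidth matrix, no
  LSCV/href options, and no autocorrelation-aware (Brownian-bridge/AKDE)
  estimators.
* Species overlap assumes pooling individuals into one species UD is
  meaningful; with strongly territorial conspecifics the pooled UD can
  be multimodal and the species-level indices should be read with care
  (the individual-level matrix is the alternative).
* The parametric Wilks χ² reference is liberal at small N (see above);
  prefer the randomization p-value for N ≲ 20.
* Sun-time conversion assumes a fixed UTC offset (no DST) and
  non-polar latitudes.
* No geodetic support: coordinates are planar projected metres, and
  callers must pre-project (no shapefile/KML readers).
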