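# Methods

`colonyforage` implements a complete analysis chain linking the physical
heterogeneity of the marine environment around seabird breeding colonies to
foraging behaviour and reproductive success, together with a synthetic-world
generator that provides ground truth for every stage. This note documents the
models, the conventions and numerical choices each stage uses, what the
generator does and does not emulate, and the design decisions taken where more
than one defensible option existed.

## 1. Environmental heterogeneity as multivariate dispersion

The environment available to a colony in a given year is described by six
gridded variables: bathymetry (m), potential tidal stratification
(dimensionless index of vertical water-column structure), sea-surface
temperature (°C), and ocean-front strength, distance (km) and persistence
(fraction of scenes). Grid cells whose centres lie within the colony's
foraging radius (the maximum foraging distance observed in the tracking data,
across all years) form the sample; cells with any missing layer are dropped
and counted.

Heterogeneity H of a colony-year is the mean Euclidean distance of its cells
from their group centre in the space of the six standardized variables — the
multivariate-dispersion statistic of the PERMDISP family. Conventions:

- **Standardization scope.** Variables are standardized (mean 0, SD 1,
  sample-SD convention with denominator *n*−1) pooled across *all*
  colony-years, so every group lives in one shared distance space and H values
  are comparable between colonies. Per-group standardization would erase
  exactly the between-colony differences the statistic is meant to measure.
- **Group centre.** Spatial median by default (Weiszfeld iteration with the
  Vardi–Zhang step for iterates landing on a data point; relative tolerance
  1e-10, max 500 iterations), centroid as an option. Outputs record which was
  used.
- **PCoA equivalence.** Principal coordinate analysis (Gower double-centring
  of −D²/2, symmetric eigendecomposition, coordinates scaled by √eigenvalue)
  is provided and tested, but because the input distances are Euclidean the
  ordination is an isometry: distances to group centres are identical in the
  standardized variable space and in the full ordination (asserted to 1e-9 in
  the tests). The pipeline therefore computes H directly in variable space,
  which is O(nk) rather than O(n³); `use_pcoa=True` forces the ordination
  route. Eigenvalues below 1e-12 of the leading eigenvalue are dropped; an
  eigenvalue below −1e-8 of the leading one (impossible for Euclidean input up
  to round-off) raises an error rather than being silently truncated.
- **PERMDISP.** The F statistic is the one-way ANOVA F of the per-observation
  distances-to-centre across groups. The permutation scheme is free
  permutation of group labels, with centres and distances recomputed per
  permutation; p = (1 + #{F\* ≥ F}) / (1 + n_perm), 999 permutations by
  default, seeded. Residual (Levene-type) permutation is a known alternative;
  free permutation is the simplest exchangeable scheme and its size is
  verified empirically (type-I error within [0.02, 0.09] at α = 0.05 over 500
  null simulations, p-values uniform by a KS check).
- **Follow-ups.** Colony and year effects on H are tested with a two-way ANOVA
  (type-II sums of squares, so unbalanced designs are handled) plus Tukey HSD
  per factor; a factor with one level is skipped with a warning, and a
  zero-variance effect is reported as F = 0, p = 1 rather than 0/0. The
  sensitivity of H to the extraction radius is a linear regression of
  colony-mean H on radius.

## 2. Trip segmentation

Raw GPS fixes are cut into foraging trips with three filters, applied in this
order:

1. **Night window.** Fixes whose local civil time (Europe/London by default —
   the loggers' duty cycle was clock-based) falls in the half-open window
   [23:00, 03:00) are removed: a fix stamped 23:00:00 goes, one at 03:00:00
   stays.
2. **Colony buffer.** Fixes within 500 m (great-circle) of the colony are
   excluded; a fix at exactly the buffer distance counts as at the colony.
3. **Duration filter.** Maximal runs of the remaining fixes form candidate
   trips; a candidate is kept only if its span strictly exceeds 14 minutes
   (short colony departures are disturbance, not foraging). The duration
   filter is applied *after* the buffer exclusion. Night-masked fixes do not
   split a run — a trip whose middle falls in the night window stays one trip
   — but an intervening colony fix does.

Every input fix thus receives exactly one label: night-masked,
colony-proximal, member of a trip, or member of a sub-threshold candidate.

Distances are haversine on a sphere of radius 6371 km. Trip duration is the
time from the first to the last retained fix; no interpolation of the colony
departure/return crossing is attempted (the raw fix interval is minutes, so
the truncation is small and unbiased across colonies). Colony-year summaries
average over trips by default; averaging birds first is available as a
sensitivity option. The colony's foraging radius is the maximum trip distance
over all its years.

## 3. Behavioural classification (hidden Markov model)

Trips are regularized to a fixed time step (default: the 5-minute raw fix
interval) by linear interpolation of planar coordinates in an
azimuthal-equidistant projection centred on the colony; raw gaps longer than
five intervals (including the night window) split a trip into segments rather
than fabricating positions. Step lengths are Euclidean distances between
consecutive regular positions; turning angles are heading changes,
counterclockwise positive, wrapped to (−π, π], and undefined (missing) next to
a zero-length step.

The three-state model (rest < forage < transit, labelled after fitting by
increasing mean step length) uses gamma step lengths (state-specific mean and
SD), von Mises turning angles with means fixed at 0 (estimable on request) and
state-specific concentration κ, a 3×3 transition matrix, and the stationary
distribution of that matrix as the initial distribution of every track
segment. Exact-zero steps, which a gamma density cannot generate, carry a
per-state point mass that is estimated only when zeros occur in the data;
missing angles contribute likelihood one.

Fitting is direct numerical maximum likelihood (not EM): the scaled forward
recursion, batched across all track segments, is minimized by L-BFGS-B on a
working scale (log for means, SDs and κ; multinomial logit per transition row
with the diagonal as reference; logit for the zero mass). The best of
`n_restarts` runs is kept, the first starting exactly at the supplied values
and the rest at ~20% multiplicative jitter. Non-finite likelihood at the start
raises with the offending parameters; optimizer non-convergence is flagged,
never silent. Decoding is log-space Viterbi with ties broken toward the lower
state index; both the forward likelihood and the decoded path are tested
against exhaustive enumeration over all 3^T paths for short tracks. Per-bird
time budgets are the proportions of decoded positions in each state, pooled
over the bird's tracks.

One parameter set is fitted per dataset (pooled over birds and colonies) in
the pipeline; per-colony-year fitting is a matter of grouping the tracks
passed to `fit_hmm`.

## 4. Space use and overlap

Per-bird utilization distributions (UDs) pool all of a bird's trip fixes in a
colony-year, projected to planar km. The kernel is an isotropic bivariate
normal with the reference ("ad hoc") bandwidth h = σ·n^(−1/6),
σ = √((var_x + var_y)/2) with sample variances; birds with fewer than five
fixes are skipped. UDs are evaluated at cell centres of a 1-km grid whose
edges sit at integer multiples of the resolution relative to the colony, so
all birds of a colony-year are co-registered by construction; the grid covers
all fixes plus a 3h margin and the mass is normalized to one.

The 50% core foraging area is the smallest set of cells holding half the
mass. Cells are ranked by mass with a stable sort, so equal-mass cells enter
in a fixed row-major order and the result is deterministic; a "include all
tied cells" rule was considered and rejected because it returns the whole
grid for an exactly uniform UD instead of half of it.

Overlap between two birds is Bhattacharyya's affinity BA = Σ√(p·q) over
cells. Because the analysis frames overlap in terms of 50% *core* areas while
BA is defined on whole distributions, both variants are implemented: the
default restricts each UD to its own 50% core and renormalizes before the
affinity sum; `on="full"` uses the complete UDs. The choice changes
magnitudes, not signs, and is recorded in every output row. All ordered
(focal, other) pairs within a colony-year are emitted — both directions, with
equal BA — because the downstream mixed model uses the focal bird as a random
effect.

## 5. Regression layer

Explanatory variables are standardized to mean 0, SD 1, so estimates are per
SD of colony-mean heterogeneity (the unweighted mean of H over a colony's
years; colony and year themselves are not entered as factors because they
absorb the heterogeneity signal by construction). Test statistics follow the
response type:

- **Trip metrics** (mean duration, total distance, maximum distance per
  colony-year): OLS on log-transformed metrics; the heterogeneity effect is
  tested by the nested-model F test.
- **Time budgets** (per-bird proportions): quasi-binomial GLM with logit link;
  dispersion estimated as Pearson χ²/df of the full model; effect tested by
  the scaled deviance drop against F(1, n−2).
- **Core-area size** (per bird): OLS with the nested F test.
- **Pairwise overlap**: Gaussian linear mixed model with a random intercept
  per focal bird, fitted by maximum likelihood so the heterogeneity effect can
  be tested by a χ²(1) likelihood-ratio test against the intercept-only
  model. A singular random-intercept variance (or a failed fit) falls back to
  OLS with the fallback recorded in the result.
- **Breeding success** (chicks fledged / nests monitored per colony-year): OLS
  with F test and R²; the percent decline across the observed range is
  (ŷ(min H) − ŷ(max H)) / ŷ(min H) × 100, undefined and flagged if the fitted
  value at minimum heterogeneity is non-positive. A leave-one-colony-out refit
  is available for outlier sensitivity.
- **Confound screens**: one OLS per candidate (colony size, breeders within
  the foraging radius, each single environmental-metric mean), plus H against
  each metric mean, with a summary flag at α = 0.05.

No multiple-testing correction is applied across the response set; results
tables carry a note saying so.

The empirical size of each test in the suite (PERMDISP, OLS F, quasi-binomial
F, mixed-model LRT) is verified to lie within [0.02, 0.09] at nominal α = 0.05
over 500 null simulations.

## 6. The synthetic world

The generator produces all four raw inputs — environmental rasters, GPS fix
tables, colony metadata and breeding-success tables — from a single seeded
configuration, so the full pipeline can be exercised against known truth.
All randomness flows from `numpy` generators keyed on (seed, stage, colony,
year, bird); identical configurations reproduce outputs bit for bit.

**Rasters.** Each layer is `base + scale · target · G`, where G is white
noise smoothed by a Gaussian kernel (6 km length scale) and normalized to
unit spatial SD, and `target` is the colony's heterogeneity level. Layers get
independent noise but share the smoothing scale; a target of zero yields
spatially constant layers. The realized dispersion H then grows monotonically
with the target. These are statistical stand-ins: no tides, no dynamically
coherent fronts, no land mask.

**Tracks.** Birds alternate colony-attendance blocks (fixes jittered within
~250 m of the colony) with foraging trips, on a continuous 5-minute timeline
that runs through the night, so colony-proximal and night-window fixes are
present for the filters to remove. Within a trip, behavioural states evolve
by the configured Markov chain and each step draws its length from the
state's gamma and its turning from the state's von Mises — only transit-state
*headings* are biased (toward the destination outbound, back toward it while
on the patch, toward the colony homeward), so state-conditional step-length
distributions are exactly the configured gammas (verified by KS tests).
Trips end when a homeward transit step passes through the colony zone. A
trip that does not fit in the bird's remaining fix budget is not started
(recording ends with colony attendance) because a truncated trip would bias
duration and distance.

**Built-in effects** (`endtoend_world`), the study conditions for the
end-to-end tests:

- *Behaviour:* the stationary state occupancy shifts with standardized
  heterogeneity z: forage 0.40 + 0.075 z, transit 0.35 − 0.075 z, rest fixed
  at 0.25, with 0.8 self-persistence. Trip *duration* rises with z emergently,
  because commuting a fixed distance takes longer when less of the time is
  spent in transit.
- *Distance:* each trip's patch residence is solved from a flight-distance
  budget — twice the direct commute, times a per-bird log-normal multiplier
  (SD 0.25) — so expected total path length is independent of z by
  construction, and destination distances (~16 km) do not depend on z, so
  maximum range carries no signal either. The 16 km scale keeps trips mostly
  within a day; much longer trips collide with the 23:00–03:00 window, whose
  masking truncates recorded durations.
- *Overlap:* each colony-year has K shared hotspots (K shrinking from ~6 to
  ~1-2 with z) evenly spread over a fixed 120° marine sector, at distances
  drawn with small SD (persistent oceanographic features). Each bird commits
  to one destination for the season — a shared hotspot with probability
  0.5 + 0.3 z, otherwise a private location in the sector — so per-bird space
  use is comparable across colonies while *sharing* between birds rises with
  z, raising pairwise BA. Per-bird core-area size carries no built-in effect.
- *Success:* breeding success is intercept 0.8 − 0.18 z plus Gaussian noise
  (SD 0.15), truncated at zero, one draw per colony-year.

Default world scale mirrors the study system (15 colonies, heterogeneity
targets 1.1–2.4, 8 birds per colony-year, 5-minute fixes); the end-to-end
tests and the acceptance script run a reduced desk-scale version (8–10
colonies × 3 years × 5–6 birds × ~400 fixes) chosen so a full multi-seed
replication completes in minutes on one CPU.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the pipeline assumes: Markovian behaviour with the
stated emissions, smooth environmental fields, central-place trips with known
filters, and linear links between heterogeneity and the responses. Real
tracking data violate several of these (location error, irregular sampling
beyond simple dropout, behaviour that is only approximately Markov,
environmental fields with shared physical structure across variables,
density dependence). End-to-end recovery here therefore demonstrates that the
implementation is faithful and the inference chain is calibrated — not that
the scientific conclusions would survive those violations.

## 7. Numerical details and edge cases

- Spherical geometry throughout (R = 6371 km); the azimuthal-equidistant
  projection preserves distances from the colony exactly and its inverse is
  tested to 1e-9 degrees round trip.
- Weiszfeld spatial median: see §1. Exact-fit regressions (zero residual)
  report F = ∞ (p = 0) for a non-zero slope and F = 0 (p = 1) for a zero one.
- The batched forward recursion rescales per time step and per track;
  emission densities are max-shifted before exponentiation so large κ or
  tiny steps cannot underflow.
- Viterbi ties go to the lower state index; equal-likelihood paths are
  accepted by the enumeration oracle via likelihood comparison, not path
  identity.
- Gamma mean/SD parameterization maps to shape (μ/σ)² and scale σ²/μ.
- The raster text format stores one layer per file with an explicit origin
  and cell size; `nan` marks missing cells.

## 8. Known limitations

- PERMDISP recomputes spatial medians for every permutation; for very large
  cell counts (≫10⁴) this is the slowest step and the permutation count
  should be reduced or the centroid used.
- The quasi-binomial F test treats per-bird proportions as independent given
  colony-mean heterogeneity; a shared colony-year environment induces mild
  cluster correlation in real data that the model does not absorb.
- The mixed model for overlap uses a single random intercept (focal bird);
  the dyadic structure of pairwise BA (each pair appears twice) is handled by
  design but not modelled as such.
- No location-error filtering or state-space smoothing of raw fixes is
  implemented; loggers are assumed accurate at the grid scales used.
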