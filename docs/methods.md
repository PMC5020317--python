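# Methods

`citrec` analyses opportunistic citizen-science biodiversity records —
tables of (recorder, date, OSGB grid reference, species) — to describe
*who* records, *where* and *what*. This note documents the statistical
procedures, the synthetic data the package is validated on, and the
design choices made where the methodology was genuinely open.

## Engagement metrics

A volunteer is **active** on a calendar day if they submitted at least
one record that day. Four per-volunteer metrics are computed:

- **n_observations** — total records submitted.
- **Activity ratio (AR)** = active days / linked days, where the linked
  period runs from the first to the last active day, inclusive.  Both
  endpoints inclusive means a single-day volunteer has AR = 1, so
  one-day contributors carry a well-defined metric vector and are
  profiled rather than discarded.
- **Relative activity duration (RAD)** = active days / study-window
  length (inclusive). The window defaults to the dataset's date span
  and can be overridden. Because the linked period is contained in the
  window, RAD ≤ AR for every volunteer.
- **Variation in periodicity (VP)** = the volunteer's mean gap between
  sequential active days divided by the cohort average of those mean
  gaps. The denominator is the *unweighted mean over volunteers* of the
  individual mean gaps (not the pooled mean of all gaps); this reading
  gives the exact invariant that VP averages to 1 over multi-day
  volunteers, which the tests assert to 1e-12. Volunteers with a single
  active day have no gaps; they receive VP = 0 and a `single_day_flag`
  rather than being excluded, so the cohort stays complete.

## Profiling (clustering)

Metrics are min-max normalised to [0, 1] per column (a constant column
maps to 0 with a warning). The candidate partitions are explored three
ways, mirroring standard practice for engagement profiling:

1. **Ward hierarchical clustering** (scipy, Ward/Euclidean) supplies the
   within-group-sum-of-squares (WSS) curve by cutting the tree at each
   k ∈ 1..k_max+1.
2. **k-means** (scikit-learn, Lloyd, k-means++ init, 25 restarts, fixed
   seed) fits each candidate k; the pipeline is deterministic given
   (data, seed).
3. **Average silhouette width** (ASW) validates each k-means partition;
   a partition is *sufficient* when ASW ≥ 0.51.

**Choice of k.** The default policy places k at the *elbow* of the Ward
WSS curve — the candidate maximising the drop ratio
(WSS(k−1) − WSS(k)) / (WSS(k) − WSS(k+1)), i.e. the last large relative
improvement — and then accepts it only if the k-means partition's ASW
reaches the 0.51 sufficiency threshold. The silhouette is used as a
validation check, not as the selection objective, for a structural
reason: engagement cohorts have hierarchical geometry. Enthusiasts are
extreme in observation count, activity duration and periodicity, while
dabblers and steady volunteers sit adjacent after normalisation.
Maximising ASW on such data always collapses to k = 2 (the merged
dabbler+steady cluster against the enthusiasts scores ≈ 0.91 versus
≈ 0.75 for the three-way split), hiding the finer structure that the
WSS curve clearly supports. An `selection="argmax"` policy (pick the
ASW-maximising k) is available for comparison. If no k passes the
threshold the result is flagged "insufficient partitioning" rather than
raising.

Profiles are named **dabbler / steady / enthusiast** in ascending order
of mean raw observation count (for k = 3; otherwise `profile_i`).
`ProfileResults.summary()` reports raw-unit mean centroids, volunteer
counts, whole-number percentage shares and the single-day share per
profile.

## Spatial statistics

Records at ≤ 1 km precision are aggregated to **monads** (1-km British
National Grid cells). Grid references are parsed with the standard 5×5
letter scheme (I omitted) on OSGB36; tetrad (DINTY) suffixes are
supported at 2-km precision; no datum transformation is performed. Per
occupied cell: records, distinct volunteers, distinct informal
taxonomic groups, and productivity = records/volunteers. Cross-dataset
and cross-metric agreement uses Spearman rank correlation; the default
cell pairing is the *union* of occupied cells with absence counted as
zero (the pair count n is always reported so the choice is auditable;
intersection pairing is available). Hotspots are the top-n cells by a
metric, ties broken by monad id so rankings are deterministic.

## Taxonomic tables

Species map to informal recording-community groups nested in higher
groups (birds, invertebrates, plants, ...); unmapped species fall into
("other", "others") and are flagged. Matching is exact on trimmed,
case-folded names — no synonym resolution. Composition tables give
percentage of records per higher group and per invertebrate subgroup;
group statistics give recorders, records, records/recorder and
British-list coverage. The shipped checklist totals are editable
defaults derived from published coverage tables; real analyses should
supply their own checklist CSV.

## Trait screens

The response is records-per-species; each trait is tested in its own
log-link Poisson GLM (statsmodels) with dispersion estimated by the
Pearson statistic — the quasipoisson correction. Significance is an
F-test of the trait model against the intercept-only model:
F = (ΔDeviance/Δdf)/dispersion on (Δdf, df_resid), matching R's
`anova(glm(..., family=quasipoisson), test="F")`, against which the
implementation is verified on a fixed fixture. Traits are fitted one at
a time (separate exclusion sets per trait source are the norm, so df
differ across screens); no familywise correction is applied by default
because such screens are exploratory, but each screen reports
significance at the Bonferroni-adjusted level alongside the raw one.
The adjusted alpha is displayed at 3 decimals with banker's rounding
(0.05/8 → 0.006, 0.05/4 → 0.012). Quasipoisson standard errors are the
Poisson SEs scaled by √dispersion.

## Synthetic data

The generator produces the structure the analyses assume, so the whole
pipeline is testable without proprietary data:

- **Volunteers** are drawn from a three-archetype mixture whose default
  weights and centroid means (observations, AR, RAD, VP) follow
  published profile centroids for a regional records-centre cohort:
  dabbler (67%, 33.0, 0.60, 0.030,
  0.78), steady (32%, 48.0, 0.50, 0.050, 1.08), enthusiast (1%, 1524,
  0.20, 0.220, 4.99). Per volunteer, target AR and RAD are drawn around
  the centroid means (sd(AR) = 0.02, relative sd(RAD) = 0.10,
  lognormal σ = 0.25 for observations — dispersions deliberately small
  so the planted clusters are well separated, and exposed in the spec
  objects); active days = RAD × window; linked period = active/AR days
  placed uniformly in the window with first and last day active and the
  rest sampled without replacement; observation counts are allocated
  over active days with at least one each.
- The **study window** defaults to 1000 days: long enough that dabbler
  active days (~30) stay below their observation target (~33),
  preserving the published ordering.
- **VP is emergent**, not drawn: because the active days span the
  linked period exactly, a volunteer's mean gap is
  (linked−1)/(active−1) ≈ 1/AR, so VP separation follows from AR.
  Directly inverting VP would over-constrain the sampler.
- The enthusiast centroid has RAD (0.22) slightly above AR (0.20),
  which cannot hold per volunteer (linked ≤ window forces AR ≥ RAD);
  cluster means need not satisfy the joint constraint but samples must,
  so the linked period is clamped to the window and realised enthusiast
  AR floors at ≈ 0.22.
- **Landscape**: a 40×50 monad rectangle inside the TQ 100-km square
  (all grid references valid), with 5 hotspot cells at attraction
  multiplier 25; each observation's cell is an i.i.d. draw proportional
  to cell weight. Optional fractions of records are emitted at 10-km
  precision and of recorder names abbreviated to initials, to exercise
  the ingestion filters and synonym collapsing.
- **Species**: lognormal abundances within groups; recording rate
  log-linear in log-abundance (slope 1.0) and identification difficulty
  1–4 (slope −0.4 per step), so abundant, easy species are recorded
  more. A separate `simulate_species_counts` generator produces
  gamma-mixed Poisson counts with specified quasipoisson dispersion for
  calibrating the F-test.

**What the generator does not emulate:** seasonality and weather,
detection distance, volunteer home ranges (cells are i.i.d. draws, real
volunteers cluster their own effort), the engagement continuum (real
cohorts fill the space between archetypes rather than forming separated
clusters), and taxonomic misidentification. Passing recovery tests
therefore show the pipeline is correct and well-calibrated under its
assumed structure — not that real cohorts divide as cleanly.

## Numerical choices and degenerate inputs

- Filter order on ingestion is date → precision → anonymous → group, so
  audit categories are disjoint and counts reconcile exactly.
- Anonymous and group records are flagged and retained by default
  (spatial and taxonomic analyses use them); the engagement stage
  excludes them.
- Synonym collapsing (surname + first initial, lowercased) is off by
  default — synthetic identities are clean — and should be enabled for
  real-world ingestion; namesake collisions are an accepted limitation.
- Constant metric columns normalise to 0 with a warning; < 2 volunteers
  cannot be profiled; a cohort with no multi-day volunteer has no
  defined VP denominator (error from the metric, VP = 0 throughout the
  table builder).
- k-means ties and hotspot ties break deterministically (lowest cluster
  index; lexicographic monad).
- Spearman correlations use average ranks for ties; constant columns
  yield missing correlations rather than errors.

## Problem sizes

Validation uses cohorts of 600 volunteers (50 replicates) for profile
recovery, 150-volunteer landscapes (50 replicates) for spatial
accounting, 1000 replicates of 300 species for F-test calibration, and
10,000 random grid references for round-tripping — sizes chosen to make
Monte-Carlo bounds tight at interactive runtimes.

## Known limitations

- OSGB only; Irish grid and lat/lon conversion are out of scope.
- No species-name reconciliation against taxonomic backbones.
- Region membership (e.g. a city boundary) is a user-supplied cell
  list, not computed from polygons.
- The trait screens are single-trait; confounding between correlated
  traits (e.g. abundance and rarity) is deliberately not modelled.
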