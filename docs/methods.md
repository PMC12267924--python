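# Methods

## The analysis

A species is *naturalized* where it maintains self-sustaining populations
outside its native range, and *threatened* in a native-range country where
a national Red List assessment places it in EX, EW, CR, EN or VU (NT can
be included via a flag; LC, DD and NE never count — absence of assessment
is not threat). Crossing the two tables over accepted names yields the
continuum classification:

| class | naturalized anywhere | threatened somewhere native |
|---|---|---|
| `net_loss` | no | yes |
| `paradox` | yes | yes |
| `net_increase` | yes | no |
| `none` | no | no |

The four classes partition the species set, which every pipeline run
checks. A species recorded as naturalized and native-threatened in the
*same* country is rejected as a data error: the two roles are exclusive
per country, and threat is only meaningful within the native range.

Reported percentages are rounded half-up to one decimal; all internal
arithmetic keeps full precision.

### Category standardization

National Red List schemes differ in language and category systems, so
label → IUCN-category crosswalks are data (CSV per scheme), not code. The
bundled default maps the IUCN codes to themselves plus common variants;
notably `RE` (Regionally Extinct) → EX, and EW counts as threatened
alongside EX at national level. Unmapped labels standardize to NE and are
logged. These mappings are configurable because no universal convention
exists for RE/EW/DD treatment across the ~100 national schemes in use.

### Name harmonization

Raw names are normalized (trim, collapse whitespace, genus capitalized,
author citations stripped on the first token containing `.`/`(`/`&` or a
capitalized mixed-case word) and matched exactly against accepted names,
then against registered synonyms. Fuzzy matching (normalized edit
similarity ≥ 0.95) exists behind a flag, with each match logged, and is
off by default: silently fuzzy joins corrupt the set intersections the
analysis is built on. Hybrids (flag, or `×`/lone-`x` marker in the name)
and members of a configurable apomictic-genus list are excluded before
any counting.

### Gridded area of occupancy

AOO is the summed area of occupied grid cells on a global
longitude/latitude grid anchored at (−180, −90). The default cell size of
0.7° gives (111.195 · 0.7)² ≈ 6058 km² at the equator; each cell's area is
scaled by cos(latitude of its center), since a fixed angular cell shrinks
physically toward the poles. Cell indices are `floor((lon − lon₀)/c)`,
`floor((lat − lat₀)/c)`, with the lon = 180 / lat = 90 edges folded into
the last cell so the grid tiles the globe without overlap.

Occurrence cleaning drops, in order: rows with missing or non-finite
coordinates; coordinates outside [−180, 180] × [−90, 90]; exact (0, 0)
points (a classic database artifact); unknown country codes; points
falling more than 0.1° outside their stated country polygon (tolerance
for coastal jitter — country membership is taken from the record's
country-code column and *validated* against polygons rather than
recomputed, mirroring how occurrence databases are structured); and exact
(species, lon, lat) duplicates. Per-rule drop counts are reported.

Each cleaned occurrence is routed to exactly one partition by its
establishment flag and the status of its country for that species:
native + assessed country → native-threatened or native-ok;
introduced + naturalization record → naturalized; anything else →
a logged `unresolved` bin excluded from all partitions. A cell reached by
native occurrences from both a threatened and a non-threatened country
contributes its area to *both* native partitions (cell-level union per
partition); the overlap count is reported so users can quantify it. The
percentage of native AOO threatened is
`100 · AOO_thr / (AOO_thr + AOO_ok)`, undefined (and excluded downstream)
for species without native occurrences.

### Major axis regression

Both log₁₀ AOO variables carry comparable error, so the line relating
them is estimated by major axis (model II) regression: the direction of
the leading eigenvector of the sample covariance matrix, equivalently the
minimizer of summed squared perpendicular distances (the suite checks the
two agree to 10⁻⁶). The 95% CI inverts the F-test of a hypothesized axis
direction (Jolicoeur–Mosimann form): with eigenvalues λ₁ ≥ λ₂,

    H = 4 F₀.₉₅(1, n−2) λ₁λ₂ / ((n−2)(λ₁−λ₂)²)

and the slope limits are `tan(θ̂ ± asin(√H)/2)`, unbounded when H ≥ 1.
Simulated coverage is checked to lie in 93–97% over 500 replicates. A
percentile bootstrap (2000 resamples) is available behind a flag.
Standardized major axis is deliberately not the headline method; the
analysis compares like-scaled log₁₀ areas.

Species with zero AOO in either compared partition are excluded from
log-scale analyses and counted in a reported exclusion tally. The paired
Wilcoxon test runs on untransformed km² with the classic zero-drop policy
(`pratt` optional; equal vectors give p = 1 under `pratt`, an error under
the default), exact null for ≤ 25 tie-free pairs, tie-corrected normal
approximation otherwise. Compensation classes follow the sign of
(naturalized − threatened) AOO; exact ties form their own class and are
excluded from the two percentages, which sum to 100 over non-tie species.

### Phylogenetic dispersion

Whether paradox species cluster in particular families is tested at
family level on a family-level tree (branch lengths default to 1 when the
Newick lacks them) with three standard community-phylogenetics metrics:
the count of families containing paradox species, the mean pairwise
patristic distance among them, and the mean nearest-taxon distance. The
null redistributes the global paradox total across families by a
multivariate hypergeometric draw with each family's naturalized-species
count as its urn — paradox status assigned at random among naturalized
species, margins fixed. p-values are two-sided,
`min(1, 2(1 + smaller tail)/(1 + n_permutations))`, so they are valid
(never zero) and super-uniform under the null; calibration is checked on
neutral worlds. These metrics and null are this package's own
reconstruction of a family-level dispersion test; they are standard
choices, not a canonical published procedure.

## The synthetic world

The generator emulates the joint structure of a naturalization database,
a stack of national Red Lists, a global Red List, a checklist with
synonyms, and occurrence records:

* **Geometry** — countries are axis-aligned rectangles tiling a 60° × 40°
  region straddling the equator. The analysis needs country membership
  only, so realistic borders would add polygon-validity complexity for no
  inferential gain.
* **Taxonomy** — families receive species with Zipf-skewed sizes; genera
  nest in families; names are deterministic pseudo-Latin binomials. 2% of
  genera are designated apomictic (the exclusion rule needs data to act
  on; membership is configuration, not biology).
* **Roles** — an exact-count random subset of species is naturalized
  (default 15%), and an exact-count share `paradox_target` (default
  0.273) of those is threatened in ≥ 1 native country. Exact-count
  assignment (rather than per-species Bernoulli draws) keeps the realized
  prevalence at the target up to rounding, so prevalence-recovery checks
  measure the pipeline, not binomial noise; unbiasedness over seeds still
  holds. Among non-naturalized species 44% are threatened somewhere,
  which reproduces a net-loss : paradox ratio of ≈ 9 : 1. A further 5.2%
  of naturalized species are Near Threatened only, raising prevalence by
  ≈ 3.8 points when NT counts. 7.7% of paradox species are also globally
  threatened (≈ 2.1% of the naturalized flora), with the global category
  never exceeding the worst national one; a few reach EW via a national
  EX listing.
* **Threatened fraction** — each threatened species draws the fraction of
  its native range that is threatened from Beta(0.3, 1.906) (mean 0.136,
  median 0.045, clipped to [0.01, 0.99]), which governs both the share of
  native countries threatened and the AOO split below.
* **Allometry** — paradox species receive a latent position along the
  line `log₁₀ AOO_thr = c₀ + b · log₁₀ AOO_nat` (latent sd 0.8, giving a
  realistic multi-decade AOO range) plus *isotropic* noise
  (`allometry_noise_sd`, default 0.5) on both axes. Isotropic noise is
  essential: the major axis of an x-clean/y-noisy cloud is not the
  generating slope, because MA estimates the principal axis rather than
  E[y|x]. Draws are rejection-sampled inside the representable box (at
  least half a grid cell, at most what the region hosts on each axis) —
  clamping sub-cell draws up to the 1-cell floor would pile probability
  mass on the boundary and bias the realized axis upward by ≈ +0.03. The
  line slope, center and intercept are calibrated by a damped fixed-point
  iteration on a deterministic 120 000-draw Monte Carlo sample so that
  the *truncated* cloud has exactly the configured major axis and keeps
  its marginal medians at the anchors 60 593 km² (naturalized) and
  37 066 km² (threatened). Undamped updates oscillate because slope and
  intercept are coupled through the truncation. Calibration is a pure
  function of the config, independent of the world seed.
* **Occurrences** — target AOOs convert to occupied-cell budgets
  (`round(AOO / mean cell area)`, ok-budget derived from the realized
  threatened budget as `thr · (1−p)/p` so the threatened share of native
  cells stays at the Beta draw); distinct cells are sampled inside the
  species' countries with 1–2 points each, and country allocations grow
  as needed to host the budgets (threatened and naturalized budgets take
  precedence). Species outside the allometry construction draw log-normal
  occurrence counts (mean `occ_per_species_mean`) scattered uniformly in
  their countries. Every point lies inside its stated country by
  construction.
* **Determinism** — one integer seed feeds named sub-streams per table;
  identical configs yield byte-identical worlds.
* **Name noise** — `inject_name_noise` swaps an exact-count fraction of
  table names for invented registered synonyms (invertible by
  harmonization, which the round-trip test exercises) and marks a
  fraction of species as hybrids by inserting the `×` marker consistently
  everywhere.

### What the generator does *not* emulate

No climate, dispersal, temporal dynamics, or realistic country shapes and
sizes. Family sizes are Zipf-skewed but the world has only ~60 families,
so almost every family with naturalized species ends up containing a
paradox species; real floras, with hundreds of mostly small families,
show materially lower family coverage. Occurrence records are clean by
default (noise is injected only in tests), so the cleaning rules are
exercised against constructed corruption, not GBIF's full pathology
(centroids, rasterized coordinates, basis-of-record issues). Passing
tests therefore demonstrate correctness of the *pipeline logic and
estimators* under the stated statistical structure — not robustness to
every artifact of the real data sources.

## Problem sizes and numerical choices

* Parameter-recovery suites run on worlds of ~1700 analysable paradox
  species (slope recovery, 50 replicates), 5000 species (prevalence
  recovery) and 400 species × 200 replicates (permutation calibration);
  the acceptance script uses a 12 000-species world. These sizes put
  Monte Carlo error well inside the tolerances being checked while
  keeping a full run in minutes on one core.
* Ties in MA input are impossible in continuous data but the degenerate
  isotropic case (s_xy = 0, s_xx = s_yy) raises an explicit error, as
  does n < 3.
* Cell indices use half-open intervals; the antimeridian and pole edges
  fold into the last cell.
* Country-membership validation uses a 0.1° tolerance buffer; the demo
  grid keeps |latitude| ≤ 20° so cell areas stay within ~6% of the
  equatorial value.
* The permutation p-value includes the observed value in both tails
  (add-one formula), making it conservative at small permutation counts;
  n_permutations ≥ 99 is enforced.

## Known limitations

* The MA slope CI assumes bivariate normality of the log AOO pair; the
  bootstrap flag exists for heavy-tailed data.
* `pct_native_threatened` treats assessed-but-unlisted countries as
  non-threatened; countries with no assessment at all route occurrences
  to the unresolved bin rather than guessing a role.
* Family coverage and country means depend on the world's composition
  (see above) and should not be read as calibrated to any real flora.
* Crosswalks ship with a small default table; real multi-scheme use
  requires supplying the full crosswalk CSV per national scheme.
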