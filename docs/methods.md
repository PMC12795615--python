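# Methods

This note documents the models, conventions and numerical choices behind
`phylotrends`, and what the synthetic experiments do and do not establish.

## Cleaning and assemblage construction

Occurrence rows pass four sequential rules: non-empty species name
(whitespace-normalized; exact string identity, no synonym resolution),
parseable in-bounds coordinates (|lat| ≤ 90, |lon| ≤ 180), a parseable
collection year, and a barcode length L with 600 ≤ L ≤ 700 bp (600 and
700 pass; removal is for strictly shorter or longer sequences, matching
the expected COI-5P fragment). A row is charged to the *first* rule it
fails, so the report always balances: input = output + Σ removed.
Unparseable numeric fields count toward their rule and are additionally
reported in a `malformed` subcount rather than being silently dropped.

Assemblages are keyed by (lat, lon, year) with coordinates rounded to
2 decimals (~1 km). Rounding is **half-away-from-zero applied to the
decimal representation** of the value: a coordinate written `10.005`
bins at 10.01 even though the nearest binary double sits fractionally
below the tie. Bin membership on boundary values depends entirely on
this convention, so it is fixed and tested rather than left to `round`.
Species are deduplicated within an assemblage; assemblages with fewer
than 10 distinct species (configurable) are dropped and counted.

Continental regions are half-open lat/lon rectangles assigned
first-match-wins; the default six-region set (North America, South
America, Europe, Africa/Arabia, Asia — two boxes — and Australasia) is
mutually disjoint and config-overridable. Points outside every box
(ocean, Antarctica) stay "unassigned" and are excluded from regional
fits. Site covariates (mean annual temperature °C, precipitation mm,
elevation m, land-cover class of up to 18 levels) join by exact 2-dp
key; assemblages without a covariate row remain usable for
latitude × year models and are flagged out of environmental models.

## Diversity metrics

Patristic distances are path-length sums computed by a postorder
pairwise merge. The accumulation order is fixed, so the matrix is
bit-reproducible — this matters because the pipeline promises
byte-identical reruns.

**MPD** is the unweighted mean over unordered distinct pairs
(presence-only; assemblages are deduplicated, so abundance weighting is
not meaningful). **ses.MPD** standardizes MPD against a null in which
each replicate draws the same number of labels uniformly without
replacement from the null pool. The pool defaults to *all* tips of the
distance matrix (the conventional tip-label shuffle) and is exposed as a
parameter because the choice is a genuine convention, not a derivable
fact. The rank p-value uses the add-one formula
p = (1 + #{null ≤ obs}) / (n_rand + 1) so p ∈ (0, 1) always. With 99
randomizations (default) z-scores carry ~1% extra SD from null-moment
estimation; this is inherent to the estimator, not a bug. When the null
SD is zero (assemblage = pool, or a star tree) the result is flagged
degenerate, z is reported missing — never ±∞ — and trend modelling
excludes the row with a logged count. Degeneracy is declared at
`sd ≤ 1e-12 · max(1, |mean|)` to absorb float jitter in an exactly-flat
null.

**Faith's PD** includes the root path by default, which keeps
single-species PD positive and matches the rarefaction closed form; a
tips-only variant (edges with members on both sides only) is provided
since conventions differ. **Rarefied Faith's PD** at subsample size m is
the exact expectation over all C(n, m) subsets: each branch with n_b
assemblage members below it contributes its length times

- rooted: 1 − C(n − n_b, m) / C(n, m)
- tips-only: 1 − [C(n − n_b, m) + C(n_b, m)] / C(n, m)

with binomial ratios evaluated as products of m factors, so no large
binomials are formed. m defaults to 10, mirroring the minimum assemblage
size, and rarefaction units are species incidences (consistent with
deduplicated assemblages). Assemblages below m report a missing value.

Per-assemblage randomization seeds derive from one root seed and the
assemblage's index in sorted site-key order, so results never depend on
input row order or on serial vs. chunked execution.

## Trend models

The response is the ses.MPD z-score. Fixed effects: |latitude|
(degrees), year centered and scaled by its SD, hemisphere (two-level
factor, N reference), optional environment, and year interactions.
Categorical terms use treatment coding with the first level as
reference. Rank-deficient designs drop aliased columns greedily
left-to-right with a named warning.

The mixed model has marginal covariance

Σ = σ²_sp·K_ν(D/ρ) + σ²_grp·GGᵀ + σ²_res·I

with D the haversine great-circle distance matrix (Earth radius
6371 km), K the Matérn correlation with smoothness fixed at ν = 1.5 by
default (ν = 0.5, the exponential model, is the alternative), and G the
decade/site indicator (decade = ⌊year/10⌋·10). Everything is fitted by
**maximum likelihood, never REML**, so AIC is comparable across
fixed-effect menus. The variance parameters are profiled on the residual
scale (V = I + φ_sp K + φ_grp GGᵀ; σ²_res and β have closed-form profile
solutions) and the remaining log-parameters are optimized by Nelder–Mead
from three fixed starting points seeded from the median pairwise
distance (function tolerance 1e-8, parameters clipped at |log θ| ≤ 25).
Non-convergence after all starts is reported via `converged=False`,
never silently. When every decade/site group is a singleton — the common
case in sparse surveys — GGᵀ = I exactly and the group variance is
unidentifiable; it is then pinned to zero with a warning rather than
letting the optimizer split the residual arbitrarily.

AIC = 2k − 2·loglik with k counting the intercept, every coefficient
column, the residual variance, and each free covariance parameter.
Candidates within 2 AIC units of the best resolve toward fewer
parameters. All candidates must share identical response rows (checked
by hash).

VIF uses the correlation matrix of the centered design columns;
multi-column terms get the generalized VIF det(R₁₁)det(R₂₂)/det(R).
Perfect collinearity reports ∞ with the columns named.

Moran's I per distance bin uses binary pair-in-bin weights and a
two-sided permutation p-value (1 + #{|I_perm| ≥ |I_obs|}) / (n_perm + 1),
invariant to residual scaling; empty bins and zero-variance residuals
report missing values. The pipeline computes the correlogram before
(OLS residuals) and after (Cholesky-whitened mixed-model residuals)
spatial correction.

Marginal-effect grids fix non-focal continuous predictors at their
training mean and categorical ones at their mode, and flag grid points
outside the observed |latitude|/year range as extrapolation.

## The synthetic generator

The generator emulates the *schema and failure modes* of a barcode
repository export, not lepidopteran biology:

- **Tree**: pure-birth (Yule) with the final inter-speciation interval
  included, so E[height] = (1/λ)Σ_{k=2..n} 1/k; ultrametric, 150 tips and
  λ = 1 by default. No attempt to mimic real clade shape or names.
- **Trait**: Brownian motion (σ² = 1) supplies a phylogenetically
  conserved environmental tolerance — the mechanism that converts trait
  filtering into phylogenetic clustering.
- **Assemblages**: one signed scalar d per site × year cell.
  d < 0 draws species with weight exp(−|d|·(z-trait − optimum)²)
  (optimum uniform over the standardized trait range); d > 0 builds the
  set sequentially with weight ∝ (min patristic distance to the chosen
  set)^d; d = 0 is uniform without replacement and matches the
  randomization null *by construction*. The d ladder is monotone in
  expected ses.MPD — this is the generator's defining, tested property —
  but the d → E[z] link is nonlinear and asymmetric (repulsion acts more
  strongly than filtering at equal |d|), so planted dispersion
  coefficients are recovered in sign and ordering, not as numeric
  equalities on the z scale.
- **Design**: d = β0 + β_lat·z(|lat|) + β_year·z(year) +
  β_int·z(|lat|)·z(year), standardized over the site × year grid; the
  constants are recorded in the truth sidecar. Defaults: 15 sites on a
  ±60° latitudinal transect, years 2003–2022, richness uniform 10–30
  from 150 species, (β0, β_lat, β_year, β_int) = (−0.5, 0.2, 0.2, 0.6) —
  equatorial clustering with diversity rising through time at high
  latitude, the gradient the trend models are meant to detect. The
  resulting ~300 assemblages keep every experiment on one CPU at
  interactive speed.
- **Contamination**: clean rows draw lengths uniformly on [620, 680] bp;
  each violation rule adds round(rate × clean rows) extra rows (5% per
  rule by default) crafted to fail exactly its own rule under sequential
  charging; length violations draw from [300, 599] ∪ [701, 1200] bp;
  duplicate rows copy an existing row's species/site/year so they
  survive filtering and exercise deduplication. Missing fields are empty
  strings in the CSV. Exact per-rule counts are recorded, so filter
  accounting is testable as an equality, not a tolerance.

What passing tests therefore show: the metrics are exact, the null is
calibrated, the cleaning is bookkeeping-perfect, and the modelling stack
can recover a planted monotone spatiotemporal dispersion gradient of
realistic size. What they do not show: robustness to taxonomic sampling
bias, spatially structured record density, coordinate error, or synonymy
— real-repository pathologies the generator deliberately leaves out.

## Seeds and determinism

One root seed governs a run. Sub-streams derive via
`SeedSequence(root, spawn_key=(crc32(stage), index))`, so stages and
per-assemblage draws are independent and reorder-proof. Reruns with the
same config are byte-identical for every CSV output; only manifest wall
timestamps differ.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive ses.MPD
enumeration on 6 tips (sizes 2–5, 10,000 null draws); rarefaction checks
on 20 random 15-species assemblages (m = 10, 20,000 Monte-Carlo draws);
null calibration on 500 uniform assemblages and 200 each at d = ±2;
interaction recovery on 100 replicate surveys of ~300 assemblages
(20 in the acceptance script); Wald-CI coverage on 100 (script: 50)
model-simulated spatial datasets of n = 150; Moran type-I calibration on
1,000 (script: 400) iid datasets of 40 points with 199 permutations.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted 3-SE bands while keeping the whole suite at a few minutes.

## Known limitations

- The repulsion sampler is greedy-probabilistic, not an exchangeable
  point process; its d is a ranking knob, not a calibrated effect size.
- The Matérn fit is O(n³) per likelihood evaluation and is intended for
  the 10²–10³ assemblage scale; larger problems need sparse or
  low-rank approximations that are out of scope.
- Wald p-values for the mixed model use the normal reference; no
  small-sample (Kenward–Roger-style) correction is attempted.
- Land-cover enters as plain treatment dummies; with many rare classes
  per region the term is frequently dropped as aliased, which mirrors
  how little information sparse regional data carry about it.
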