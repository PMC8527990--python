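# Methods

## Data model

All analyses run on three objects: a `CountTable` (samples × taxa,
non-negative integers, six-rank lineage per taxon), a `StudyDesign`
(sample → facility / bioreactor / month; facility → coordinates and annual
average environmental covariates, any of which may be missing), and labelled
distance matrices (scikit-bio `DistanceMatrix`, symmetric within 1e-9 and
symmetrized by averaging on load). Months are 0-based study-relative integers;
only month differences enter any analysis.

## Preprocessing

Profiles are rarefied to a fixed depth by a single exact without-replacement
draw per sample (multivariate hypergeometric), deterministic given the seed;
samples below depth are dropped and logged. Defaults are 4,336 sequences for
OTU-level work and 7,805 for genus-level phylotypes — the coarser profiles
carry less richness, so more depth is affordable. "Detected" always means
count > 0 in the rarefied table, because every downstream analysis consumes
rarefied profiles. OTUs collapse to phylotypes by exact six-rank lineage
equality; a lineage ending in `unclassified` never merges with a classified
genus.

## Dissimilarity and distance

Sørensen (presence/absence), Bray-Curtis (counts) and weighted UniFrac
(abundance-weighted branch lengths) are the three community metrics; weighted
UniFrac defaults to the normalized variant so values lie in [0, 1], with the
raw variant exposed. Shannon diversity uses natural log. Geographic distance
is haversine on a 6371.0-km sphere — at the 10–450 km scale of a regional
survey the difference from an ellipsoid geodesic is far below the noise.
Environmental difference matrices are |vᵢ − vⱼ| of annual averages; facilities
missing a variable are excluded from that matrix (pairwise deletion) and
reported, never zero-filled.

## Decay regression

Facility-pair dissimilarity is the arithmetic mean over all cross-facility
sample pairs, restricted by default to pairs collected in the same month:
"annual average" is otherwise ambiguous, and month-matching keeps seasonal
turnover out of the spatial signal (an all-pairs option exists for
sensitivity analysis). Pairs at zero distance are excluded from log-log fits
with a warning. The fit itself is OLS of log10(DS) on log10(D); the p-value
is the two-sided t-test on Pearson's ρ with n−2 df. A flat response (zero
variance in log10 y) returns slope 0, ρ 0, p 1 rather than an error, so a
taxon-volume fit on constant richness is well defined.

The sliding-window analysis fits the decay inside [lo, lo+200 km) windows,
lo advancing in 10-km steps from 10 km until a window holds fewer than 10
pairs (windows below that are unstable three-point fits). Window membership
is by distance interval, not pair rank, so the printed km ranges are exact.
Monthly series fit each month's facility-averaged pairs separately; months
with fewer than three facility pairs are reported as insufficient, and
months failing α are flagged, not dropped.

## Permutation statistics

The study-wide significance level is α = 0.001 — with ~190 facility pairs,
weak correlations would otherwise reach nominal significance. Mantel tests
use Spearman correlation of the off-diagonal triangles, 999 simultaneous
row/column permutations, upper-tail p (positive association is the working
hypothesis throughout); AMOVA uses the distance-based sum-of-squares
decomposition (SS_total = Σd²/N within and among groups), an F-ratio on
(g−1, N−g) df and 1,000 label permutations. Both are bit-reproducible given
a seed. Rank ties always take average ranks. The Wilcoxon rank-sum test uses
the normal approximation with tie correction and no continuity correction.

One caution on permutation floors: the minimal attainable AMOVA p is set by
the number of distinct label arrangements — for two groups of three, 10% of
permutations preserve the partition, so even perfect separation cannot go
below p = 0.1.

## Variation partitioning

Community tables enter CCA as facility × phylotype annual-mean relative
abundances (bioreactors averaged; never-observed taxa dropped). Inertia is
the chi-square statistic of the table over its grand total; constrained
inertia comes from row-weighted regression of the standardized chi-square
residuals on the predictors, verified against vegan's `cca` on a fixture to
seven digits. Spatial predictors are raw (longitude, latitude) columns — the
minimal faithful encoding; the functions accept arbitrary user-supplied
spatial predictor tables. Environmental predictors default to the three
nitrogen variables (influent TKN, effluent TKN, effluent NH₃). Fractions are
pure-env = inertia(env|space)/total, pure-space = inertia(space|env)/total,
shared = joint − pure terms (small negative shared values are reported as
computed), unexplained = remainder; they sum to 1 to 1e-9 by construction.
Rank-deficient predictors are handled by an SVD basis whose cutoff is scaled
to the predictor magnitude *before* conditioning, so duplicated predictors
yield exactly zero pure fractions instead of numerical noise. Model
significance is a permutation test on the (residualized) predictor rows with
999 permutations.

## Seasonal classification

Within each bioreactor, every sample pair with Δ ≥ 1 month contributes
(Δ, Bray-Curtis) to two OLS models, DS ~ Δ and DS ~ Δ + Δ², each tested by a
model F-test. `cyclic` requires the quadratic model significant at α, concave
(a < 0), and peaking at −b/2a ∈ [5, 8] months — a rising-then-falling
dissimilarity that returns after a year; a convex fit with an interior axis
is not a seasonal return. `linear` requires the linear model significant;
both conditions give `both`, neither gives `neither`. The quadratic
significance is the model F-test (the Δ² t-test is also computable from the
reported coefficients). At least 6 pairs are required — three parameters plus
an F-test need residual df — and bioreactors with fewer than 6 samples are
skipped and reported.

## Synthetic studies

The generator emulates the *output* of a regional activated-sludge survey,
not sequencing itself. Structure, with defaults:

* **Design**: 20 facilities (A–T) uniform in a mid-latitude box rescaled so
  the maximum pairwise distance is 442 km; facilities C and G have two
  parallel bioreactors and S has four (25 total); 12 monthly samples per
  bioreactor; 300 genus-level phylotypes at depth 7,805.
* **Environment**: influent TKN is a Gaussian field with exp(−D/150 km)
  correlation — the planted driver; effluent TKN and NH₃ are noisy copies of
  it; the remaining Table-S1-style covariates (flow rate, pH, MCRT, CBOD,
  TSS, phosphorus, NOₓ) are independent draws, so driver *ranking* is testable.
* **Community**: taxon log-abundance = lognormal rank-abundance baseline
  (σ = 2.0 natural-log units) + taxon-specific linear response to the TKN
  field (gain σ = 0.55) + per-taxon spatially autocorrelated residual field
  (σ = 0.55) + bioreactor offset (σ = 0.06) + per-sample noise (σ = 0.30);
  counts are multinomial at depth. Archaea (11% of taxa) share the abundance
  distribution but are shifted to a 0.3% expected community share and form a
  clade in the random coalescent tree. Two realism guards: per-facility
  single-taxon dominance is capped at 35% (hyper-dominated profiles are both
  unrealistic and numerically inert under relative-abundance metrics), and
  the rare half of taxa receives an additional, boost-capped environmental
  response so presence/absence turnover is spatially structured — without it
  Sørensen shows no decay even when Bray-Curtis does.
* **Calibration**: the realized Bray-Curtis decay slope is measured on a
  pilot build and the distance-dependent variance rescaled once
  (slope responds about linearly near the operating point); if the result is
  still >15% off, one secant refinement using the measured local response
  exponent runs. Across seeds this keeps the realized β within ±10% of the
  planted 0.12; the contract is ±25%. A pilot slope ≤ 0 with a positive
  planted β raises an error suggesting stronger gradients.
* **Temporal structure**: every facility drifts in a fixed direction at
  0.015/month, and designated bioreactors (all reactors of every other
  facility — seasonality is facility-driven, so parallel reactors cycle
  together and stay AMOVA-indistinguishable) add a 12-month sinusoid through
  two orthogonal loading vectors, tracing a closed annual loop with peak
  dissimilarity at Δ = 6 months. Drift and seasonal loadings are normalized
  by their abundance-weighted magnitude so the planted effect size does not
  depend on which taxa the random loadings happen to hit.
* **Randomness**: one seed, split into independent child streams per
  component (geography, environment, taxa, fields, reactors, samples,
  counts, tree), so outputs are byte-identical across runs.

What the generator does **not** emulate: sequencing error, chimeras and
classification noise; OTU-level (97%) richness scaling (so the taxon-volume
exponent z on synthetic data is ~0, matching the absence of a planted
richness–flow relationship — genus-level profiles are too coarse for one);
compositional covariance beyond the multinomial; non-sinusoidal seasonality;
and facility-specific sampling gaps. Passing tests therefore demonstrate that
the pipeline recovers planted power-law, driver and seasonal structure at
realistic noise levels — not that real communities follow these models.

## Problem sizes

The test suite and the acceptance script run the full default study
(300 samples × 300 taxa), 500-replicate slope-recovery and permutation-
calibration simulations, exhaustive AMOVA enumeration at 6 entities, and
100 random-tree UniFrac oracle comparisons; the complete suite finishes in
well under a minute on one core.

## Known limitations

* The variation-partitioning encoding of "geography" as raw coordinates is
  one of several defensible choices (distance eigenvectors would be another);
  fractions depend on the encoding.
* Facility-pair annual means weight every qualifying sample pair equally, so
  facilities with more bioreactors contribute more pairs to their own mean —
  matching the arithmetic-mean convention, not a balanced design.
* The normalized weighted UniFrac is the default; raw values are not bounded
  by 1 and should not be compared across trees.
* AMOVA assumes exchangeable entities under the null; strong within-group
  temporal autocorrelation (present in monthly series) makes the facility
  test anti-conservative, which is acceptable here because the facility
  effect is orders of magnitude larger than the violation.
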