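# Methods

## The screening model

A species' vulnerability to trout pressures is summarised as a weighted sum
of seven integer trait scores. Each factor is scored 1–3 against fixed
criteria (e.g. larval dispersal: diadromous = 1, non-diadromous widespread
= 2, non-diadromous limited = 3); the weight vector is (1,1,1,2,1,2,2) —
double weight on fecundity/egg size, larval dispersal and adult body size,
the factors most tied to population resilience (r- vs K-selected life
histories). Totals therefore range from 10 (all ones) to 30 (all threes).
The data model also defines an optional eighth factor for national
threat-classification status (Declining/Naturally uncommon/Nationally
vulnerable/Data deficient → 2, Nationally endangered/critical → 3), but it
is excluded from the default totals: the packaged matrix's published totals
are exactly reproduced by the seven factors above, and those printed
numbers are the reference surface for this package. Species are keyed by
binomial name normalised to lowercase underscores; common names are display
metadata.

Missing or out-of-domain scores are rejected at load time, never imputed:
the source assessment scores every cell, and silent defaults would bias
totals downward or upward invisibly.

## Monte Carlo uncertainty

Score allocation and weighting involve judgement, so uncertainty is probed
by perturbation rather than by a sampling model. Per iteration
(default 10,000):

1. start from the pristine matrix and weights (iterations are independent);
2. draw `n_elements` (default 30) elements uniformly **without replacement**
   from the pooled set of all score cells and weight entries (35×7 + 7 =
   252 for the packaged matrix);
3. a drawn score moves ±1 with equal probability and is **clamped** into
   {1,2,3}; a drawn weight equal to 2 is re-drawn uniformly from {1,2};
   a drawn weight of 1 is left unchanged — weight perturbation is
   deliberately downward-only, which is why perturbed totals live in
   [7, 30] under the default weights (the floor drops when double weights
   collapse to 1; the ceiling cannot rise);
4. totals are recomputed.

Choices the procedure description leaves open — with/without replacement,
clamping versus reflecting at the score boundaries — are fixed as above
and exposed in `PerturbationConfig`; clamping preserves the declared score
domain without inventing asymmetric dynamics. Randomness comes from one
root seed with per-iteration counter-derived substreams
(`numpy.random.SeedSequence.spawn`), so results are independent of
execution order and bit-reproducible. Summaries are per-species medians and
quartiles plus the Spearman correlation between unperturbed totals and
medians ("rank stability"). On the packaged matrix the medians coincide
with the raw totals for every seed we have run, and rank stability is 1.0:
the ranking is insensitive to this perturbation scale.

## Natural-breaks classification

Scores (raw totals or MC medians — both entry points accept either, and
integer or half-integer medians are equally valid) are split into k = 3
contiguous classes of the sorted values. Two algorithms are implemented:

- **Fisher's exact dynamic programme** (`jenks_breaks`): minimises total
  within-class sum of squared deviations (SSD); breaks are placed only
  between distinct values so tied scores share a tier; among SSD-equal
  partitions the one with the smallest highest class is chosen (then the
  next class down, and so on) — deterministic and conservative about the
  High label. Verified in the test suite against an exhaustive enumeration
  oracle (`brute_force_breaks`, guarded to n ≤ 200).
- **Classic iterative refinement** (`jenks_caspall_breaks`): classes start
  with equal counts; each sweep moves, per boundary, the observation
  strictly closer to the adjacent class mean, until stable; boundaries that
  land inside a run of equal values are snapped so the run joins the upper
  class. This is the algorithm family behind many widely used
  natural-breaks implementations. It is a local search: it can stall at a
  partition the exact programme beats.

On the packaged 35-species totals the two differ materially: the exact
optimum is a 17/8/10 split (SSD 59.265, boundaries 18|19 and 22|23) while
the iterative method converges to 15/8/12 (SSD 59.767, boundaries 17|18
and 21|22, i.e. High = totals ≥ 22). The published tier assignments for
this matrix — 12 High, 8 Moderate, 15 Minor, produced with a third-party
natural-breaks routine — match the iterative partition, not the exact
optimum. `classify` therefore defaults to the iterative method so that the
packaged matrix reproduces its published classification, and exposes
`method="fisher"` for the exact optimum; both partitions and their SSDs are
asserted in the tests so the disagreement stays visible. Goodness of
variance fit is 1 − SSD_within/SSD_total, defined as 1 for a zero-variance
input to avoid 0/0. Tier names for k = 3 are High, Moderate, Minor.

## Threat-status regression

Threat categories are encoded ordinally: Not Threatened = 1, Naturally
Uncommon & Relict = 2, Recovering = 3, Declining = 4, Nationally
Vulnerable = 5, Nationally Endangered/Critical = 6. Data Deficient has no
defensible rank and is excluded with a warning under the default encoding;
the encoding is fully user-overridable. The regression of risk score on
threat ordinal is ordinary least squares in closed form (the levels are
treated as numeric, matching the original analysis; no ordinal-aware model
is attempted): slope = Sxy/Sxx, R² = Sxy²/(Sxx·Syy), adjusted
R² = 1 − (1−R²)(n−1)/(n−2), F = R²(n−2)/(1−R²) on (1, n−2) df, p from the
exact F survival function (scipy), formatted "< 0.001" below threshold.
The per-species status table underlying the original fit is not shipped —
those statuses are not published as machine-readable text and are not
invented here; supplying a status table enables the stage, and the
published adjusted R² ≈ 0.29 is a documented, non-gating reference point.

## Reach overlap

The co-occurrence summary operates on per-reach attributes only (reach id,
length in km, occurrence values); no network topology, flow direction or
geometry is processed. Probabilistic occurrences are binarised at a
threshold τ (default 0.5, always recorded in the output) with the ≥
convention. A reach counts toward a tier if **any** species of the tier is
present; reaches hosting several tiers count toward each, so per-tier
overlaps may sum to more than the any-species overlap. All trout species
are treated as a single occurrence layer. A tier with zero extent reports
its percentage as undefined (`None`), never 0 or NaN. The national headline
figures (25,059 km trout–native overlap; 16,179 km High-tier extent with
1626 km ≈ 10% trout overlap; 8.9% and 7.5% for the Moderate and Minor
tiers) require the external national prediction dataset and an unstated
binarisation threshold, so they are not reproduced here; the synthetic
planted-fraction recovery below stands in for them structurally.

## Synthetic data

`generate_reach_table` emulates the statistical shape of national
occurrence predictions: lognormal reach lengths with mean 0.7 km (the
national network's average reach length; dispersion σ = 0.8 chosen as a
realistic spread for stream segment lengths), tier extents planted on
disjoint random reach subsets totalling set fractions of network length
(defaults 3.9% / 14.5% / 58.4% for High/Moderate/Minor, the national
proportions), and trout planted on a length-weighted fraction of each
tier's extent (defaults 10% / 8.9% / 7.5%). Planting is greedy over a
shuffled reach order, so the cut-off error is at most one reach length —
negligible at 10⁴ reaches, which is why recovery tests use ±1 percentage
point. In probability mode occupied cells draw from Beta(0.8c, 0.2c) and
unoccupied from Beta(0.2c, 0.8c) (concentration c = 10 by default), whose
medians straddle τ = 0.5; thresholding then recovers the planted layout up
to the beta tail mass (~3–5% of cells), so probability-mode checks are
correspondingly looser. What the generator does **not** emulate: dendritic
topology and spatial autocorrelation of occurrence, environmental
covariates, and correlated species distributions — passing tests show the
summary arithmetic is right, not that real predictions share these
statistics. `generate_trait_table` draws i.i.d. uniform scores, giving
E[total] = 2·Σw = 20 under default weights, used as a closed-form check.

## Problem sizes and numerics

The Monte Carlo runs at its full default scale (10,000 × 30) throughout the
tests and the acceptance script — it takes under a second on the packaged
matrix. Break-finding is exact DP in O(k·m²) over m distinct values;
float comparisons in the DP reconstruction use exact equality of
identically-formed prefix-sum expressions with an epsilon fallback.
Degenerate inputs are handled explicitly: empty tables, constant score
vectors (classification refuses when distinct values < k), zero-variance
GVF, zero-extent tiers, and an all-elements perturbation draw.

## Known limitations

- The classification default reproduces a published grouping that is
  provably not SSD-optimal for the packaged matrix; users who want the
  strict optimum must ask for `method="fisher"`.
- Weight perturbation is downward-only by construction; the uncertainty
  analysis does not explore up-weighting single-weight factors.
- The regression treats an ordinal scale as numeric and inherits that
  interpretation's limits.
- Overlap percentages depend on the binarisation threshold τ, which the
  original analysis does not state; τ is therefore always explicit in
  outputs.
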