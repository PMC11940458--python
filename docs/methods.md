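# Methods

## The analysis

The pipeline operationalises a norming study of abstract vocabulary: many
raters judge words on 15 variables, eight of which are semantic
dimensions (introspection, mental states, quantity, space, social,
moral, theoretical, economic) hypothesised to ground the meaning of
abstract concepts. After cleaning and aggregation, each abstract word is
summarised by its eight dimension means, and its **exclusivity**

E = (max − min) / sum × 100

measures how strongly a single dimension dominates. E is bounded below
by 0 (all dimensions equal) and above by 100·(U − L)/(U + 7L) — 42.857
on a 1–7 scale — attained when one dimension sits at the ceiling and the
rest at the floor. E is computed from trimmed per-word means, not as a
per-rater score averaged later: the statistic characterises the word's
aggregate profile, and per-rater ratios would be noisier and biased for
small sums.

Stratification uses the 25th and 75th percentiles of the E distribution.
The default percentile convention is linear interpolation between order
statistics (position (n−1)p + 1); the SPSS weighted-average convention
(position (n+1)p) is available as `percentile_method="spss"` because
norming studies analysed in SPSS may differ in the second decimal. The
medium band is closed on both sides: low is E < p25, medium p25 ≤ E ≤
p75, high E > p75, so boundary ties never fall out of the partition.

## Cleaning rules

Two numeric rules, applied in order:

1. **Careless raters.** A rater whose modal Likert response accounts for
   *strictly* more than 85% of all their Likert responses (pooled across
   variables; AoA, an open-ended age, is excluded from the pool) is
   dropped entirely. Pooling across variables follows the reading that a
   careless participant is careless throughout, not per scale. Raters
   with missing responses are handled by a separate completeness rule
   (default: 100% of the expected list × variable responses).
2. **Response trimming.** One sweep over every word × variable cell
   removes responses with |value − cell mean| > 3 × cell SD. The SD is
   the sample SD (n−1); the candidate response is included in its own
   cell statistics (the simplest reading of "distance from the item
   mean"); a leave-one-out variant is exposed as `trim_leave_one_out`.
   A zero-SD cell loses nothing. The sweep is single-pass by design — a
   second pass could remove more (trimming shrinks the SD), and the
   pipeline never applies one.

A property of the single-pass rule worth knowing: when two planted
extreme responses land in the same ~25-response cell they inflate the
cell SD enough to shield each other, so sensitivity to planted outliers
degrades as contamination grows (≈95% at 0.5% contamination, ≈88% at 1%
in our simulations, with per-variable removal always under 2%). This is
a property of the rule itself, not of its implementation.

## Reliability

Cronbach's alpha treats raters as the scale's items and words as cases —
the standard convention for inter-rater consistency in norming work:

alpha = k/(k−1) · (1 − Σᵢ s²ᵢ / s²_total),

with k raters, s²ᵢ the variance of rater i across words and s²_total the
variance of per-word sums (sample variances throughout). Because raters
rate disjoint word lists, no complete words × raters matrix exists;
alpha is computed within each list (a complete block) and pooled as the
unweighted mean over lists. Unweighted, because list sizes are nearly
equal by design and weighting would suggest a precision argument the
statistic does not support. After trimming, a block can have holes; the
raters with missing cells in a given list × variable block are dropped
from that block (they are typically very few — trimming removes <2% of
responses). A variable is acceptable when its pooled alpha exceeds 0.6.

## Classification and the network

A word *represents* a dimension when its mean exceeds 3.5 — strictly, so
a word at exactly the threshold does not qualify; means are compared
unrounded by default (`round_norms_decimals` exists for thresholding
published, rounded norms). Words representing no dimension are kept but
reported separately, excluded from intersection rows. The intersection
table counts words per exact dimension combination over the 2⁸ subsets;
its invariants (counts sum to the representative-word count, marginals
equal the sums of combinations containing the dimension) are enforced by
tests, not trusted. The co-occurrence network projects the
word–dimension bipartite graph: per dimension pair, the shared-word
count and the Jaccard index. Clustering is average-linkage on 1 −
Jaccard cut at k = 2 — the simplest reproducible method that yields the
qualitative two-group structure; dimensions are ordered
lexicographically before the linkage so ties break deterministically.
Force-directed layout is cosmetic and not computed.

## The synthetic generator

The generator emulates the study design, not real Italian words. Its
defaults are the study's stated conditions: 964 items of which 157
concrete fillers; 24 lists filled round-robin (≈40 words each); raters
assigned to consecutive list pairs, 22 per pair, so every word receives
22 ratings on every variable (the study reports 20–27).

Latent structure per abstract word: k relevant dimensions drawn from a
count distribution over 1..8 (default pmf 0.09, 0.17, 0.21, 0.24, 0.15,
0.08, 0.04, 0.02 — single-dimension words a small minority, most words
recruiting 2–5 dimensions, as in observed norms); relevant means uniform
on (4.5, 6.5), irrelevant on (1.2, 3.2). Latent SEM_DIV is
linear-Gaussian in standardised −E: s = ρ·z(E) + √(1−ρ²)·ε mapped to
4 + s and clipped to [1, 7], so the population correlation with E equals
ρ (default −0.47; clipping attenuation is negligible at the default
spread — Monte-Carlo at n = 2000 recovers ρ within ±0.05). Other
variables draw from plausible uniform bands (abstract CNC low, concrete
CNC near ceiling, AoA 3–13 years).

Responses: value = clamp(round(true_mean + rater_offset + noise), 1,
scale max), with noise ~ N(0, noise_sd) per response and a rater offset
~ N(0, noise_sd/2) creating inter-rater spread (the study reports only
aggregate reliability, so any rater model is a choice; this one yields
pooled alphas in the observed 0.8–0.96 range at noise_sd = 1). Rounding
is half-away-from-zero — any fixed convention works, this one is
symmetric about the scale midpoint. AoA gets uniform ±2-year noise,
floored at 0, no offset. Careless injection replaces a fraction of
raters' responses with a per-rater constant; outlier injection pushes a
fraction of Likert responses to the scale extreme opposite their item
mean (always in bounds by construction). Ground truth (latent E,
relevant sets, altered raters/responses) is returned for recovery tests.

Because responses live on an integer scale, a noiseless run reproduces
*rounded* latent means; exact E recovery is therefore only defined for
profiles already on the integer grid. The generator's
`integer_levels=True` draws latent means on integer scale points, and
the exact-recovery tests use it; the default stays continuous, which is
the realistic condition.

What the generator does not emulate: real lexical structure (frequency,
length, morphology), non-uniform rater drop-out, response styles beyond
a constant offset, and any true contamination process (the planted
outlier mechanism is one simple choice). Passing recovery tests
demonstrates the pipeline's correctness under the generative
assumptions, not the validity of the dimension ratings themselves.

## Problem sizes and determinism

Tests run the pipeline at reduced but structurally faithful sizes
(40–240 items, 2–4 lists, 20–25 raters); parameter-recovery checks use
2000 items for the E-error bound and 20 seeded replicates of 807 items
for the E–SEM_DIV coupling — sizes at which the Monte-Carlo error of the
checked quantities is comfortably below the asserted tolerances. The
acceptance script runs the full study scale (964 × 15 × 22 ≈ 320k
responses, a few seconds). All randomness flows from explicit seeds
through `numpy.random.default_rng`; writers emit byte-identical files
for identical inputs.

## Known limitations

* The per-list alpha pooling is one defensible convention; published
  alphas computed under a different (unstated) convention will differ
  slightly.
* The reproduction mode requires a user-supplied column map for external
  norms deposits; it cannot guess column semantics.
* Exclusivity is not computed for concrete fillers: their grounding
  dimensions (sensorimotor) are outside the eight rated here.
* The 2-cluster cut is descriptive; no significance test of cluster
  structure is attempted.
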