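# dimnorms

Multidimensional semantic norming of abstract concepts: a pipeline from
raw multi-rater Likert ratings to trimmed word-level norms, an
**exclusivity** score quantifying how uni- vs multidimensional each
abstract word's meaning is, representative-dimension labels,
exact-intersection (UpSet) tables and a dimension co-occurrence network.

## Who this is for

Researchers in psycholinguistics and semantic memory who collect rating
norms — words judged by many raters on Likert scales — and want to
characterise abstract vocabulary not by a single concreteness score but
by the *profile* of experiential dimensions that ground each word's
meaning. The package covers the full analysis chain for a norming study
with 15 variables: concreteness (CNC), imageability (IMG), familiarity
(FAM), age of acquisition (AoA), semantic diversity (SEM_DIV), valence
(VAL), arousal (ARO), and eight semantic dimensions — introspection
(INTRO), mental states (MENT_ST), quantity (QUANT), space (SPACE),
social (SOC), moral (MOR), theoretical (THEOR) and economic (ECO).

## The statistic at the core

For each abstract word with dimension means $m_1,\dots,m_8$ on a 1–7
scale, exclusivity is

$$E \;=\; \frac{\max_d m_d - \min_d m_d}{\sum_d m_d} \times 100 .$$

A word rated equally on all dimensions has $E = 0$ (fully
multidimensional); a word rated 7 on one dimension and 1 on the others
attains the scale maximum $(7-1)/(7+7\cdot 1)\times 100 \approx 42.86$.
Words are stratified into low / medium / high exclusivity at the 25th and
75th percentiles of the $E$ distribution (medium closed on both sides).
Validity is checked through the negative correlation between $E$ and
semantic diversity: words used in many contexts recruit more dimensions.

Around the statistic the pipeline implements:

* **QC** — raters giving one Likert value for more than 85% of their
  responses are excluded (strict inequality), then a single 3-SD sweep
  removes responses far from their item mean;
* **reliability** — Cronbach's alpha per variable, computed within each
  word list (raters rate disjoint lists) and pooled, acceptable above 0.6;
* **norms** — per word × variable mean / sample SD / n, a Welch contrast
  of concrete fillers vs abstract words on CNC and IMG, and the full
  15 × 15 Pearson correlation matrix;
* **classification** — a word *represents* a dimension when its mean
  exceeds 3.5; exact combinations are counted UpSet-style and crossed
  with exclusivity levels;
* **network** — the word–dimension bipartite graph projected to pairwise
  shared-word counts and Jaccard indices, clustered (average linkage on
  1 − Jaccard) into two groups of co-occurring dimensions;
* **synthetic data** — a generator with latent per-word dimension
  profiles, rater offsets and noise, careless raters, planted outliers
  and a tunable latent E–SEM_DIV coupling, so everything above is
  testable against known ground truth.

## Worked example

Run the whole pipeline on a synthetic study at the design scale of the
real one (964 words, 807 abstract, 24 lists, 22 raters per list pair):

```sh
dimnorms run --simulate 1 --out out/
```

prints (abridged):

```json
{
  "n_abstract": 807,
  "E_range": [2.24, 22.4],
  "cutoffs": {"p25": 12.159999999999998, "p75": 15.996492326565036,
              "method": "linear"},
  "level_counts": {"low": 201, "medium": 404, "high": 202},
  "validity_r": -0.394,
  "clusters": [["INTRO", "MENT_ST", "SOC", "MOR", "THEOR", "ECO"],
               ["QUANT", "SPACE"]]
}
```

Reading this: the 807 simulated abstract words span exclusivity scores
from 2.2 to 22.4; the quartile cutoffs put 201 words in the low band, 404
in the medium band and 202 in the high band (ties at the cutoffs are
medium); the correlation between E and semantic diversity is negative
(−0.39), as the generator's latent coupling dictates; and the 2-cluster
cut of the co-occurrence network groups dimensions that label the same
words. `out/` receives the full artifact set: `norms.tsv`, `labels.tsv`,
`intersections.tsv`, `network_edges.tsv`, `network.graphml` and
`report.json`.

With a local copy of a deposited word-level norms table you can skip the
rater-level stages and recompute every norms-level result, printed next
to the study's published values:

```sh
dimnorms reproduce --norms norms.tsv --column-map map.json
```

Library use mirrors the CLI: `run_pipeline(...)`, `reproduce(...)`, or
the individual stages (`flag_careless`, `trim_responses`,
`cronbach_alpha`, `aggregate`, `exclusivity_score`, `assign_levels`,
`representative_labels`, `intersection_table`, `cooccurrence`,
`cluster_dimensions`).

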