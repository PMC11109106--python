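# Methods

## The model

`ecaspread` scores the spreading tendency of an invasive population per
region using only accumulated presence locations. The core idea: a
cluster's occurrences, ordered from its densest core outward, form a
surrogate for the unavailable temporal record of colonisation. Treating the
rasterized snapshots of that ordering as successive states of a
one-dimensional binary automaton, the *evolution rule* that best explains
the transitions summarises how presence propagates locally; the rule's
simulated long-run growth is the region's spreading intensity.

### Elementary cellular automata

An ECA state is a binary array; cell *i*'s next value is a fixed function
of cells *i−1, i, i+1*. The 256 possible functions are Wolfram-numbered:
bit `4l + 2c + r` of the rule number is the output for neighbourhood
`(l, c, r)`. Only the 128 even rules (all-zero neighbourhood → 0) are
admissible here: an odd rule would create presence out of complete absence,
which has no biological reading for an established invader. The lattice has
fixed zero boundaries — virtual 0 cells flank both ends — so presence
cannot wrap or enter from outside the cluster.

A 20×20 presence image maps to a 400-cell state by row-major flattening
(row 0 = northernmost band, column 0 = westernmost). The flattening order
is a modelling convention, not a physical adjacency: cells 20 apart in the
array are vertical neighbours on the map and the automaton does not see
that. The method's claim is only that the *statistics* of rule-governed
growth discriminate spreading from static patterns; alternative array
arrangements are a known open end.

### Pipeline stages

1. **Divisive clustering** (`regional_clustering.divisive_cluster`).
   Recursive bisection: the cluster with the largest within-cluster sum of
   squared Euclidean distances is split by 2-means (10 restarts, fixed
   seed) until *k* clusters exist. Ids record formation order; at each
   split the larger child keeps its parent's id. Distances are raw
   (lon, lat) degrees — adequate for study areas of a few degrees; no
   geodesic correction is attempted. Default *k* = 25, matching
   administrative-district-sized regions in the motivating data.
2. **Inclusion ordering** (`agglomerative_order`). Single-linkage (Ward
   optional) agglomerative clustering on the cluster's points; merges are
   traversed in distance order; the sequence starts at the first merged
   pair and each merge touching the growing main component appends a
   snapshot. Side components join wholesale when connected. This yields a
   strictly nested sequence ending in the full cluster — the
   "core-outward" pseudo-time series. Equal-distance merge ordering is
   delegated to `scipy.cluster.hierarchy.linkage`, which is deterministic
   given input order.
3. **Rasterization**. Each subset is binned on the *full cluster's* 20×20
   bounding-box grid (so frames share a grid and 1s only accumulate); a
   cell is 1 iff ≥ 1 point falls in it — observation density is discarded,
   the data being presence-only. Cells are half-open intervals with the
   last edge closed; a degenerate (zero-width) bbox axis is padded by
   1e-6°.
4. **Rule inference** (`rule_learning`). See below.
5. **Spreading intensity** (`assessment.spreading_intensity`).
   SI = Σᵢ P(xᵢ) · intensity(xᵢ), where intensity(x) is the mean simulated
   presence count under rule x over generations 1..400 divided by the
   initial 100. The per-rule simulation seeds 100 of 400 cells uniformly
   at random, evolves 400 generations, and averages 10 repetitions (one
   RNG substream per repetition). `convergent_mean` — the mean over the
   final 100 generations — is also reported; for fast-converging rules the
   two are close (rule 206: intensity ≈ 3.23, plateau ≈ 323).
   Generation 0 is excluded from the average; the identity rule scores
   exactly 1 either way.
6. **Assessment**. SA = SI × HS with HS ∈ [0, 1] supplied per cluster
   (typically a species-distribution-model summary; computing HS is out of
   scope — it is an input table). Groups: I (SA > 2), II (1.5 < SA ≤ 2),
   III (1 < SA ≤ 1.5), IV (SA ≤ 1). The interval endpoints are assigned to
   the lower group — the conservative choice; no decision in the motivating
   data sits on a boundary. A greedy collinearity filter
   (`collinearity_filter`, drop the variable with the largest mean |r|
   while any pair exceeds |r| > 0.80) is provided for preparing the
   environmental variables that feed the external HS model.

## Rule learning

**Corpus.** For each even rule and each density in {100, 200, 300}, random
20×20 images with exactly that many 1s are evolved one step, giving
labelled (before, after) pairs — 500 × 3 × 128 = 192,000 at full scale.
Every pair is validated against the exact engine at generation time.

**Classifier.** A one-step ECA transition is decodable from purely local
evidence: each neighbourhood occurring in `before` reveals one output bit
of the rule in `after`. The classifier therefore reduces a pair to 16
transition-pattern features — per neighbourhood, the fraction of positions
carrying that neighbourhood with after-bit 0 and with after-bit 1 — and
feeds them to a scikit-learn multilayer perceptron (two 64-unit hidden
layers, early stopping) with a 128-way softmax. The architecture is a
configuration choice, not a contract: any model emitting a normalized
probability vector over the even rules plugs in. The local-feature
reduction is lossless for this task, which is why a small network reaches
the ≥ 99% held-out accuracy plateau at only ~150 pairs per rule within
seconds on a single CPU.

**Accuracy ceiling.** When some neighbourhood never occurs in `before`
(likelier at extreme densities), several rules reproduce the pair exactly
and the label is formally unidentifiable; such pairs cap accuracy slightly
below 100%. `consistent_rules` — an exact decoder enumerating every rule
compatible with a pair — quantifies this, and
`oracle_consistent_accuracy` (predicted argmax lies in the consistent set)
is reported alongside plain accuracy.

**Cluster distribution.** The default aggregates by averaging the softmax
over all consecutive pairs of the image sequence (`mode="aggregate"`);
`mode="final_pair"` scores only (Cₙ₋₁, Cₙ). Aggregation was chosen because
a per-cluster rule *distribution* is naturally an average over observed
transitions and is far less noisy than a single pair; the two modes
coincide for two-image sequences.

## Synthetic data

The generator (`synthetic_data`) emulates what the pipeline assumes of real
archives: spatially separated occurrence clusters (isotropic Gaussian blobs
plus a corridor fraction jittered along a random segment, mimicking
riverside concentration), per-cluster HS scalars, and image sequences
evolved under a known rule. Defaults are matched to the motivating survey
conditions: 25 clusters, 30–267 points each, a ~2° × 2° coastal window,
HS drawn from Beta(9.1, 6.9) (mean ≈ 0.57, range concentrated in
0.33–0.80). Cluster centres keep ≥ 8 σ pairwise separation (the recovery
contract requires ≥ 4 σ), so divisive clustering recovers the truth with
adjusted Rand ≥ 0.95 averaged over seeds.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: survey effort and detection bias, temporal
revisit structure, anisotropic habitat geometry, and occurrence sequences
that actually follow an ECA rule. Real inclusion sequences follow no rule
exactly; the inferred distribution is a descriptive projection onto the
rule basis, validated here only in the recoverable synthetic regime.

## Numerical choices

- Generation averaging: means over post-update generations 1..400;
  configurable window for the plateau (last quarter).
- RNG: every stochastic stage (centre placement, state seeding, train/test
  split, MLP init) derives from one explicit seed;
  `numpy.random.SeedSequence.spawn` isolates repetition substreams. Runs
  are bit-reproducible.
- Ties: bisection candidates with equal SSE split lowest-id first;
  collinearity-filter ties drop the earlier table column; boundary SA
  values go to the lower group.
- Degenerate inputs: singleton clusters yield a length-1 sequence (warning)
  and, in the pipeline, a point mass on the identity rule 204 — a cluster
  showing no transition is treated as static; all-zero image pairs are
  consistent with every even rule and any normalized output is accepted.

## Problem sizes

The test suite trains at 50 seeds per density (150 pairs per rule, 19,200
pairs) — past the accuracy plateau for this feature set — and verifies the
full 192,000-pair corpus generation exactly. The acceptance script uses
10 master seeds for plateau estimates and 3 training seeds; both finish in
well under a minute of simulation plus a few seconds per training run.

## Known limitations

- The inclusion order is a modelling surrogate for time; nothing guarantees
  colonisation actually proceeded core-outward.
- SI is relative, not a forecast: it measures how rule-like growth in the
  flattened image space would continue, not population dynamics.
- Saturated regions score low SI by construction (little observable change)
  even where the invader is abundant — low SI is not evidence of decline.
- HS weighting is a straight product; threshold re-weighting (e.g. a
  sigmoid on HS) is deliberately not implemented.
- Euclidean degree distances and the row-major flattening are conventions;
  results at very different latitudes or grid aspect ratios were not
  studied.
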