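# Methods

## Problem and data model

The pipeline ranks candidate effector genes lying in the intersection
of two phenotype-associated gene sets.  Gene symbols are opaque labels,
normalized by trimming and uppercasing only; identifier-system
conversion is out of scope.  The canonical input sizes — an "aging" set
of 243 genes, an "exercise" set of 634, a 37-gene intersection and
hence a 206-gene training set — are the study conditions the synthetic
generator reproduces by construction.

### Training/test partition

The test (candidate) set is always the intersection.  The training
rule defaults to `aging_unique` (training = aging \ intersection,
which yields 243 − 37 = 206); the alternative reading in which the
training set is the full symmetric difference (206 + 597 genes) is
available as `training_rule="symmetric_difference"`.  The default was
chosen because only the aging-unique rule reproduces the 206-gene
count that anchors the partition arithmetic.

## Enrichment statistics

Over-representation of a size-*n* query against a term of size *K* in
a universe of *N* genes is the hypergeometric upper tail
P(X ≥ k), computed with the survival function at k − 1 (never as
1 − CDF).  The universe precedence is: explicit argument → library
field → 20,000.  Within a library, Bonferroni and Benjamini–Hochberg
corrections are both reported; ties in p are ordered by descending k,
then term identifier, so output is deterministic.

Regulator enrichment mirrors the KEA3/ChEA3 scheme: per source, a
one-sided Fisher exact test on the 2×2 query × target table (universe
defaulting to the source's target union plus the query), BH correction
within the source, integer ranks 1..m by ascending raw p (ties by
symbol), and aggregation across sources by **MeanRank** (mean of the
integer ranks over the sources containing the regulator) and best
scaled rank (min of rank/m).  A regulator absent from a source
contributes nothing to its mean by default; a penalty policy that
charges rank m + 1 is selectable, since the treatment of missing
regulators in MeanRank integration is not standardized.

## Functional similarity scoring

The training profile summarizes the seed genes per annotation
category: for categorical annotations, weight(term) = fraction of
training genes carrying the term; for quantitative annotations, the
coordinate-wise mean vector over annotated training genes.

"Fuzzy" similarity of a candidate to a categorical profile is
implemented as the cosine between the candidate's binary term vector
and the term-frequency profile — a parameter-free reading that rewards
carrying high-frequency profile terms and dilutes genes with many
off-profile terms.  A best-match Jaccard alternative (maximum term-set
Jaccard against any single training gene) is selectable by
configuration.  Quantitative similarity is the Pearson correlation
against the profile mean; zero-variance vectors score 0 with a
warning.

Similarities become empirical p-values by comparison with genes
sampled from the annotation universe minus the training set, using the
add-one estimator p = (1 + #{null ≥ observed})/(M + 1) with M = 999 by
default, so p ∈ [1/(M+1), 1] and never 0.  One null sample per
category is drawn and shared across candidates; this makes scoring
O(M + candidates) per category and leaves the marginal null
distribution of each p-value unchanged (p-values of different
candidates share a sampling threshold and are therefore weakly
correlated — irrelevant for ranking, and the calibration check in the
test suite draws independent samples per candidate).  Correction is
applied per category, then combined, because per-score correction
keeps the number of combined categories constant across candidates.

Candidates unannotated in a category receive similarity 0 and p = 1
rather than being dropped, so S_combined has the same χ²(2n) reference
for every candidate.  Fisher's statistic X = −2 Σ ln p_i is referred
to χ²(2n); S_combined = 1 − P_fisher.  A p of exactly 0 (impossible
from the add-one estimator, possible from user input) is clamped to
the smallest positive float with a warning; at such extremes the
χ² survival can underflow and S_combined reaches 1.0 exactly.

For categorical annotations the null similarity distribution is
discrete (many genes share a similarity of 0), so empirical p-values
are conservative — stochastically larger than uniform.  Quantitative
categories yield continuous similarities and calibrate exactly.

## Network scoring

The PPI network is an undirected graph, optionally confidence-weighted
in (0, 1]; self-loops are rejected.  Both walk models share one
column-stochastic transition matrix: an edge is traversed in both
directions with probability proportional to its weight, and dangling
(isolated) nodes return their mass to the prior, so every score vector
sums to 1.

* **PageRank with priors**: power iteration of
  x ← (1 − d)·prior + d·(W x + m_dangling·prior), prior uniform over
  the seeds present in the network, d = 0.85, L1 tolerance 1e−10,
  max 1,000 iterations (non-convergence returns the last iterate with
  a warning).  With a uniform prior this is exactly classical
  PageRank; with the seed prior the uniform teleport (1 − d)/N is
  replaced by (1 − d)·prior(u), which is what seed semantics require.
* **K-step Markov**: start uniform over seeds, apply the undamped walk
  k = 3 times, report the per-node mass averaged over steps 1..k
  (cumulative, not final-step: the average preserves the strong
  step-1 seed-adjacency signal that a final-step readout dilutes).
* Degree (unweighted incident-edge count) and unnormalized betweenness
  (fractional shortest-path counts) are reported as diagnostics.

The value fed to integration defaults to the PageRank-with-priors
score; `net_statistic` can select the K-step mass or an average of the
descending ranks of all four statistics.

## Integration

Both channels are min–max scaled **over the candidate set only** (the
score is a relative statement about the 37 candidates, not the
genome); constant vectors scale to all zeros with a warning.  The
⌈0.05·m⌉ candidates with the highest raw network scores receive
IsTopNet = 1 (ceiling so the set is non-empty for small panels).
FinalScore = α·Gene_scaled + (1 − α)·Net_scaled + β·IsTopNet with
α = β = 0.5.  The β term is *added* by default; because an indicator
bonus for highly connected genes can equally be read as something to
penalize, `beta_sign="penalty"` subtracts it instead.  Ranking is by
descending FinalScore, ties by descending Gene_scaled then symbol.

## Synthetic study bundles

The generator emulates the statistical structure the scoring chain
assumes, with all randomness flowing from a single integer seed
through one `numpy.random.Generator`:

* **Gene sets** of exactly 243 and 634 symbols with a forced 37-gene
  overlap, sampled uniformly from a 2,000-gene universe of abstract
  symbols (`G000001`…).  The universe is deliberately smaller than a
  genome so a full pipeline run takes seconds; enrichment uses the
  universe size as N.
* **Annotation categories** (5 by default; all but one categorical).
  Each categorical category has 3 "profile" terms, each annotating a
  training gene with probability 0.7 (a clear majority feature),
  a planted effector with probability `enrichment_strength` (0.9),
  and any other gene at `background_annotation_rate` (0.1), plus 10
  decoy terms at the background rate.  The quantitative category
  places training genes at a profile mean vector (dimension 8) plus
  N(0, 0.5²) noise; planted and background genes follow the profile
  with probability `enrichment_strength` / `background_annotation_rate`
  respectively and are independent N(0, 1) otherwise.  Setting
  `enrichment_strength` equal to the background rate therefore makes
  planted genes statistically indistinguishable from background — the
  null configuration.
* **Regulator libraries**: two sources, each with one planted
  regulator covering 60 % of the aging set plus random extras, and 20
  decoys targeting random genes.
* **Network**: 1,500-node preferential-attachment topology (3 edges
  per new node) whose nodes are a random assignment of all set-member
  genes plus random filler; each planted effector then gains 4 extra
  edges to distinct training genes (`seed_wiring = 0` disables the
  wiring for null bundles).

What the generator does *not* emulate: correlated annotation
categories, annotation-coverage bias toward well-studied genes,
degree-correlated annotation (in real databases hubs are also heavily
annotated), edge confidence structure, or any biological identity of
the symbols.  Passing tests on these bundles show the statistical
machinery is correct and calibrated, not that the biological
conclusions of any particular study are right.

## Determinism and numerics

Every stage writes its artifact before the next starts; tables are
TSVs with `%.10g` floats, gene-sorted rows, and Unix newlines; the run
manifest carries no timestamps — two runs with the same configuration
and seed are byte-identical.  Convergence and tolerance defaults:
PageRank L1 1e−10; empirical sampling M = 999; hypergeometric and χ²
tails via survival functions; BH correction restores input order.

## Known limitations

* **Hub capture of the top-network bonus.**  At d = 0.85 the
  stationary distribution of the seeded walk is ~85 % global,
  degree-driven structure and only ~15 % seed proximity.  On a
  scale-free network, a randomly placed candidate of degree 15–30 can
  out-score a planted effector that gained 4 seed edges, take the
  top-5 % IsTopNet bonus (worth as much as the entire network
  channel), and win rank 1 whenever its functional score is moderately
  high.  In replicated default bundles a planted effector holds rank 1
  in roughly half to two-thirds of runs rather than nearly all of
  them; `scripts/acceptance.py` reports the measured rate.  The
  penalty reading of β (`beta_sign="penalty"`) suppresses this failure
  mode entirely in the same experiments, at the cost of inverting the
  bonus semantics; the K-step statistic (`net_statistic="kstep"`)
  reduces it partially.  Under null bundles the ranking shows no
  preference for planted genes (goodness-of-fit p ≈ 0.16 over 200
  replicates), so the effect is a property of the score composition,
  not a bias of the implementation.
* Categorical empirical p-values are conservative (discreteness), so
  S_combined under-uses categorical evidence for sparsely annotated
  genes.
* The shared-null-sample optimization weakly correlates candidates'
  p-values within a category.
* Betweenness is exact and therefore O(V·E); for the 1,500-node
  default network it is computed only in the file-based pipeline, not
  in the replicated in-memory experiments, where it is reported as 0.
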