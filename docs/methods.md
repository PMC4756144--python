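# Methods

## The model

`aptaselect` treats recognition of aptamer–compound binding as a binary
classification problem over fixed-length feature vectors. Each
interaction pair is encoded as

    v = (aptamer block, compound block)

where the aptamer block holds the 4 mononucleotide frequencies
(counts / L, alphabet {a, c, g, u} with t read as u) followed by the 16
overlapping dinucleotide frequencies (counts / (L − 1)); each block
sums to 1 and the dinucleotides are counted with step 1. The compound
block holds named molecular descriptors from the five classical
families (constitutional, electrostatic, geometrical, quantum-chemical,
topological). Descriptor tables are filtered before use: a descriptor
is dropped iff it is missing for at least one compound or is exactly
constant across compounds (an epsilon on the variance is exposed for
noisy inputs but defaults to 0); compounds are never dropped. With 301
retained descriptors the pair vector has 321 components.

Frequencies are length-normalized proportions rather than raw counts.
This is a design choice: counts would confound composition with
sequence length, and normalization makes each block a probability
vector comparable across aptamers.

Negative pairs are constructed by random pairing: uniform sampling
without replacement from the compound × aptamer product set minus the
known positives, at a configurable ratio (default 2 negatives per
positive). The implicit assumption is that a random pairing is very
unlikely to be a true binder, so label noise among negatives is
negligible.

## Feature ranking

Relevance is mutual information with the class-label vector c,

    I(x, y) = Σ p(x, y) log₂ [ p(x, y) / (p(x) p(y)) ]   (bits),

estimated by the plug-in rule on empirical joint frequencies.
Continuous features are discretized into three states at mean ± t·σ
(population σ, default t = 1, the convention of the original mRMR
program); a constant column maps to the middle state; the integer label
is used as-is. Quantile (3 equal-frequency bins) and pass-through modes
are available. The estimator choice matters: published rankings from
other estimators are not expected to be bit-reproducible, and the
discretization is therefore part of the configuration surface.

The MaxRel list sorts features by descending I(f, c). The mRMR list is
greedy: with Ω_s the selected set and Ω_t the rest, each step selects
the f ∈ Ω_t maximizing D − R, D = I(f, c),
R = (1/|Ω_s|) Σ_{fᵢ∈Ω_s} I(f, fᵢ), with R = 0 when Ω_s is empty (so
both lists share their head element). All ties — in MaxRel order, in
D − R, and in nearest-neighbor distances — break toward the lower
original index, making every ranking deterministic. Pairwise feature
MIs are accumulated incrementally, so each of the n(n−1)/2 pairs is
computed once; the greedy step is verified against an exhaustive
per-step maximization in the test suite.

## Classification and evaluation

The native engine is the nearest neighbor algorithm: a query receives
the label of the training sample at minimum Euclidean distance,
computed on min-max-normalized features whose bounds come from the
training fold only. Normalization is a deliberate choice — raw
descriptors span orders of magnitude and would otherwise dominate the
distance; zero-range features normalize to 0 and are inert. Random
forest, an SMO-style SVM and a bagging meta-classifier are bound to
scikit-learn estimators at default parameters behind the same
fit/predict contract; the name `dagging` is attached to
`BaggingClassifier` as the closest maintained meta-ensemble (bootstrap
rather than disjoint-subset aggregation). Custom engines can be
registered by name.

Performance is summarized from the pooled confusion matrix of a
stratified, seeded tenfold cross-validation (each sample predicted
exactly once by a model trained without its fold):

    SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N,
    MCC = (TP·TN − FP·FN) / √((TN+FN)(TN+FP)(TP+FN)(TP+FP)).

MCC is the key measurement because it remains balanced under the 1:2
class ratio. A zero MCC denominator is reported as 0 with an explicit
`mcc_undefined` flag. Pooling (rather than per-fold averaging) matches
reporting a single SN/SP/ACC/MCC per model. If k exceeds the smallest
class count, stratification is impossible and the splitter falls back
to a plain shuffled k-fold with a warning.

Incremental feature selection evaluates every prefix of the mRMR list
and selects the prefix with maximum MCC; ties go to the smallest prefix
(parsimony). Reporting tabulates, for a ranked-list head (default: the
top 10%, head size round(0.10·n)) or for the optimal set, the count per
feature-type category and that count's share of the category's total.

## The synthetic generator

The generator emulates the *structure* of a curated interaction study:
aptamer sequences uniform over {a, c, g, u} (lengths 25–80 nt, the
typical SELEX range), a per-compound descriptor table, and a labeled
pair list at a 1:2 positive:negative ratio. Planted structure:

* k informative columns ~ N(0, 1) i.i.d. per compound;
* redundant columns = an informative parent + N(0, sd²) noise
  (default sd 0.3, i.e. ≈ 0.96 correlation with the parent);
* pure-noise columns ~ N(0, 1), independent of everything;
* a latent score per grid cell,
  z = effect_size · (Σⱼ xⱼ)/√k + β_apt · v_a + ε, ε ~ N(0, pair_noise_sd²),
  with v_a the standardized adenine frequency of the aptamer (β_apt = 0
  by default, so the signal is purely compound-sided and the aptamer
  block is a built-in negative control; setting β_apt > 0 plants
  aptamer-side signal for sequence-recovery tests);
* positives are exactly the top round(p·n_pairs) cells by z — the
  steep-threshold limit of a logistic response, with the threshold the
  order statistic that makes the realized positive fraction exact —
  and negatives are drawn by the random-pairing rule from the rest.

Default study conditions: 450 pairs (comparable to a 477-pair curated
study) on a 400-compound × 20-aptamer grid, k = 3 informative columns,
2 redundant, 21 noise, effect size 2, pair noise sd 1. The wide
compound grid is essential, not cosmetic: descriptor values repeat
across all pairs of a compound, so the effective sample size for any
column–label association is the number of distinct compounds involved.
A narrow grid concentrates positives on a handful of compounds, and
chance compound-level correlations then hand noise columns spuriously
large MIs. Real curated datasets are often exactly that narrow (tens of
compounds), which is why column-level relevance claims on such data
deserve caution; the generator instead uses a geometry where planted
relevance is identifiable. Descriptor categories are assigned
round-robin over the five compound families so reporting code sees
every category.

What the generator does **not** emulate: real physicochemical
descriptor distributions (heavy tails, block correlations), 3-D
structure, SELEX-biased sequence composition, or the extreme compound
reuse of curated interaction lists. Passing recovery tests therefore
demonstrates correctness of the machinery — ranking, redundancy
handling, model selection — not expected performance on any real
descriptor set.

## Numerical choices and degenerate inputs

* MI is clipped at 0 against round-off; log base 2 throughout (base
  affects scale, never ranking).
* Discretization of a constant column yields the middle state; MI with
  anything is then exactly 0.
* `filter_descriptors` rejects single-compound tables (every column has
  zero variance) and tables where nothing survives.
* Duplicate (compound, aptamer) pairs are rejected at every boundary
  (interaction files, datasets).
* Bundle outputs use fixed float formatting (`%.10g`, 10-digit rounded
  JSON) so identical configurations produce byte-identical files.

## Known limitations

* The IFS curve typically plateaus once all informative features are
  included; under cross-validation noise the argmax can drift a few
  features past the planted count even though the plateau starts at it.
  Recovery checks therefore assert a bracket
  [n_informative, n_informative + n_redundant] over a panel of seeds,
  and that bracket is tight only when the plateau is well separated
  from the rise.
* With noisy redundant copies, a copy can carry marginally more MI with
  the label than its parent; greedy mRMR then keeps the copy and
  demotes the parent. Demotion of a *specific* column is guaranteed
  only for exact duplicates; for noisy copies the guaranteed statement
  is per parent/copy group.
* The plug-in MI estimator is biased upward at small effective sample
  sizes; rankings are comparable within a dataset but MI magnitudes
  should not be compared across datasets of different size.
* The nearest-neighbor engine stores its training fold and computes a
  full distance matrix per prediction; at the intended study scale
  (hundreds of pairs, tens to hundreds of features) a full IFS sweep
  takes seconds, but the implementation is not tuned for corpora orders
  of magnitude larger.
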