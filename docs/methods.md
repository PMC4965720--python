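# Methods

## Problem and model

`semforest` addresses a binary classification task from pharmacovigilance:
given a *care episode* — a contiguous block of one patient's recorded
activity, delimited by at least three whole days without any registered
event — decide whether the patient experienced a particular adverse drug
event (ADE), operationalized as the assignment of a specific ADE-related
diagnosis code within the episode. Each episode is described by four
heterogeneous event streams: free-text note words (in sentences),
diagnosis codes, drug codes and measurement types (measurement values are
ignored; only the type is kept). Datasets are balanced case-control
samples: positives contain the target code, negatives are an equal number
of episodes in which that code was never assigned.

The method has two stages.

**Representation.** For every data type and every context window size
*w*, a *semantic space* is learned with the skip-gram objective: items
that occur in similar sequential contexts receive similar
*V*-dimensional vectors. Time-ordered code sequences (one per episode)
and note sentences are the training sequences; context is a symmetric
window of *w* items on each side. The grid of T data types x P window
sizes forms an *ensemble of semantic spaces*. An episode's representation
at window *w* is a count-weighted bag of embeddings: per data type, each
distinct event's vector is multiplied by its occurrence count and summed,
and the four blocks are concatenated (fixed order: word, diagnosis, drug,
measurement), giving V x T features; representations at different windows
are concatenated in ascending window order where needed. The target
diagnosis code is removed both from the embedding training sequences and
from the visible diagnosis stream at featurization, so the
label-defining code can never leak into the features.

**Classification.** Forests of randomized trees are built from bootstrap
replicates of the (transformed) training set under three utilization
strategies:

| strategy | representation per tree | features per tree |
|---|---|---|
| FDR | all P windows concatenated | floor(sqrt(V*T*P)) random columns |
| RDR-FS | one window drawn uniformly per tree | floor(sqrt(V*T)) random columns |
| RDR-ALL | one window drawn uniformly per tree | all V*T columns |

All strategies expose V*T*P features to the ensemble as a whole. Base
learners are fully grown Gini-impurity binary trees (minimum leaf size 1).
Prediction is unweighted majority vote; an episode's score is the
fraction of trees voting positive, with exact ties at the decision
threshold resolved to the negative class.

Evaluation uses accuracy (% correct), AUC (probability that a random
positive outscores a random negative, ties counting 1/2, computed from
midranks), average tree accuracy (each tree scored under its own
representation) and *diversity*, crudely estimated as ensemble accuracy
minus average tree accuracy on the fraction scale. For averaging
ensembles in the regression setting the exact ambiguity decomposition
E = A − D (squared ensemble error = average squared base error − average
squared deviation of base predictions from the ensemble prediction) is
provided and tested as an identity. Strategies are compared across
datasets with the Friedman rank test in its chi-square form (rank 1 =
best, average ranks on ties), followed by pairwise z-tests on mean ranks
adjusted with the Bergmann–Hommel exhaustive-set procedure (implemented
by enumerating the exhaustive hypothesis sets via set partitions,
feasible for up to 4 methods; Holm is the fallback beyond that).

## Skip-gram trainer

No embedding library is a dependency; the trainer is part of the package.
It implements skip-gram with negative sampling: item-context pairs are
materialized from fixed symmetric windows (the window is never randomly
shrunk, so a pair at distance d receives signal iff w >= d), negatives
are drawn from the unigram distribution raised to 0.75, and the input and
output matrices are optimized by mini-batch SGD with a linearly decaying
learning rate. Two numerical choices matter:

* **Batch-accumulated updates with a per-row step cap.** Within a batch,
  gradients are accumulated per vocabulary row; rows hit many times in
  one batch (frequent tokens in small vocabularies) would otherwise take
  compound steps and diverge, so each row's accumulated gradient is
  norm-clipped at 2.0 before the update.
* **Defaults: 20 epochs, learning rate 0.05, batch size 256, 5
  negatives, min_count 1.** Mini-batch training takes far fewer SGD steps
  per epoch than word2vec's per-pair updates, so it needs more epochs and
  a larger step size; with fewer epochs the vectors stay near their
  initialization and collapse onto a shared direction (all cosines near
  1). The defaults were chosen by measuring within- versus
  between-cluster cosine separation on the synthetic generator's synonym
  clusters.

Training is single-threaded and deterministic for a fixed seed; vocabulary
order is frequency-descending with lexicographic tie-break, so results
are bit-for-bit reproducible. Tokens below `min_count` are removed from
the sequences before windows are formed (their neighbours become
adjacent), and the learned input-layer vectors are the semantic vectors.
Spaces persist in the word2vec text format.

## Randomness and reproducibility

Every source of randomness derives from explicit integer seeds through
`numpy.random.SeedSequence` with counter-based keys: grid cells get
per-(data type, window) sub-seeds; forest tree *i* derives its window
choice, bootstrap, feature subset and tree tie-break seeds from
`(master_seed, i)`, so any tree is reproducible in isolation. Refitting
with identical inputs reproduces all predictions and report numbers
exactly (asserted by tests).

## Synthetic data generator

Real clinical corpora cannot be shipped, so the generator emulates the
statistical skeleton the method relies on:

* **Latent-state mixture with synonym clusters.** Each episode draws one
  of 4 latent clinical states; each state has its own categorical
  distribution over *latent meanings* per data type (Dirichlet(0.5)
  draws); each emission picks a meaning, then a uniformly random surface
  token from that meaning's synonym cluster (default cluster size 4).
  Distinct surface tokens thus share distributional profiles — learnable
  by embeddings, invisible to raw counts.
* **ADE mechanism.** With probability 0.35 an episode is positive: one of
  5 reserved ADE codes is inserted into its diagnosis stream, and all
  four emission distributions are shifted toward that code's linked
  meanings with mixing weight `signal_strength` (default 0.4). ADE codes
  belong to no synonym cluster and are never emitted by the background
  process, so the leakage guard cannot be circumvented by a synonym and
  negatives provably lack the code.
* **Desk-scale defaults.** 300 patients with 1-3 episodes each;
  vocabularies 400/60/40/30 (word/diagnosis/drug/measurement); 2-3
  sentences of 5-9 words and 2-5 events per structured stream per
  episode; V = 25; windows {2, 5, 8}; 50 trees. The full pipeline runs in
  minutes. Event streams are deliberately sparse and the emission shift
  moderate: per-episode surface counts are then a noisy sample of the
  underlying meaning distribution while pooled synonym embeddings
  estimate it well — the regime the method is designed for. (With dense
  streams or a near-deterministic shift, the task saturates and raw
  counts match the embeddings; that regime exercises nothing.)

What the generator does *not* emulate: realistic ICD-10/ATC code
hierarchies, visit-level temporal dynamics, missing-data mechanisms,
note grammar/lexical structure, or corpus-scale vocabularies (millions of
word types). Passing tests therefore show that the pipeline's mechanics
and its relative orderings behave as designed under the intended
statistical regime — not that the absolute scores transfer to real EHR
data.

## Benchmark protocol and problem sizes

The strategy benchmark evaluates 5 balanced datasets (20-30 positives
each, one per reserved ADE code) per seed, sharing one background corpus.
Semantic spaces are pretrained once per corpus — an unsupervised step
independent of the labels — with word/drug/measurement spaces shared
across datasets and diagnosis spaces retrained per target code with that
code excluded. Each (dataset, method) cell is scored on a stratified
70/30 train-test split shared by all methods, which keeps the benchmark
paired for rank tests; 10-fold stratified cross-validation is available
in the library (`cross_validate`) and used where single-dataset reports
are wanted. The pool-size experiment follows the all-subsets design: for
pool size s, every C(P, s) window subset is evaluated on a randomized
stratified 70/30 split and averaged.

## Degenerate inputs and tie-breaks

Empty corpora, single-class training sets, over-large fold counts,
duplicate windows, exclusion codes on non-diagnosis streams, and
malformed corpus/space files all raise informative errors. Out-of-
vocabulary events contribute zero vectors at featurization. Same-day
events keep their input order (the data model has no sub-day timestamps).
Rows of a score matrix where all methods tie contribute nothing to the
Friedman statistic; all-tied matrices give statistic 0 and p = 1.

## Known limitations

* The count baseline builds its vocabulary from the full dataset before
  splitting (test-only tokens appear as columns the trees never use);
  this is harmless for trees but differs from a strict
  train-only-vocabulary protocol.
* The Bergmann–Hommel implementation enumerates exhaustive sets and is
  restricted to at most four methods (three are compared here).
* `subspace_per_node` (random forest proper) is provided for comparison
  but is not the headline method and is not benchmarked.
* The trainer materializes all item-context pairs in memory; fine at
  desk scale, not meant for hundred-million-token corpora.
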