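# Methods

## The problem

Docking-based virtual screening against a flexible protein must choose which
experimental structure(s) of the target to dock into. All-against-all
ensemble docking — dock every compound against every structure and keep the
best (lowest) score — improves on single-structure docking on average, but
it systematically inflates decoys: taking a minimum over many noisy columns
is an extreme-value statistic, so a presumed-inactive compound that happens
to score well in *any one* structure contaminates the top of the hit list.

The method implemented here replaces the all-against-all reduction with
*learned structure selection*. One binary random-forest classifier per
protein structure is trained to predict whether the docking protocol will
rank a given compound correctly on that structure; a query compound is then
docked only against the structure whose classifier returns the highest
"correctly predicted" probability. This keeps the per-compound cost at one
dock call while letting the ensemble's diversity work in favor of, rather
than against, the screen.

## Correctness labels

For one structure's rank-ordered hit list over a training library with `n`
actives, a compound is labeled

* **correct** if it is an active with rank ≤ n, or a decoy with rank > n;
* **incorrect** otherwise.

The threshold `n` is the number of actives actually present in the ranked
list (after missing-score exclusions), not the nominal library size, so the
threshold lives on the same list as the ranks. Because exactly `n` compounds
occupy the high ranks, the number of misranked actives always equals the
number of misranked decoys; the labeler asserts this identity on every call.
Labels depend only on the ordering of scores and are therefore invariant
under any strictly monotone transform. Compounds whose docking failed
(missing score) are ranked after every scored compound, ordered by
compound id, and labeled like any low-ranked compound: "failed to dock" is
information the classifier should see.

Labeling uses the training split only; the test split never reaches the
battery.

## Classifier battery

* **Features.** Default descriptor: hashed circular (Morgan-type)
  fingerprints, radius 2, 1024 bits. MACCS structural keys and RDKit's full
  2D physicochemical descriptor set (an open, documented stand-in for
  proprietary 2D descriptor suites) are available grid axes. Abstract
  compounds carrying precomputed `raw` bit vectors are first-class so the
  synthetic benchmark bypasses chemistry entirely.
* **Model selection.** Grid search over descriptor kind, number of trees
  {50, 100, 500} and `max_features` {sqrt, 0.2, 0.4, 0.6, 0.8, None} under
  stratified 10-fold cross-validation, scored by the fold-averaged Matthews
  correlation coefficient (MCC). CV fits weight classes inversely to their
  frequencies. One global setup per target is selected by maximizing the
  MCC averaged over all structures' classifiers (ties break toward fewer
  trees, then `sqrt`).
* **Final fits.** The per-structure training sets are rebalanced by SMOTE
  (synthetic minority oversampling: interpolation between a minority sample
  and one of its k = 5 nearest minority neighbours, seeded) and one forest
  per structure is fit with the selected setup. The asymmetry — class
  weights during CV, SMOTE for the final fits — is deliberate and part of
  the protocol being reproduced.
* **Selection.** The selection statistic is the probability of the
  "correctly predicted" class. Exact ties break toward the
  lexicographically smallest structure id, making hit lists reproducible
  across runs and platforms.

Structures whose labels are single-class (degenerate docking columns) are
dropped from the battery with a warning and excluded from that target's
ensemble comparison, keeping all methods on the same ensemble.

## Comparator protocols

* **single:S** — conventional docking against one fixed structure.
* **ensemble** — best (lowest) score over all structures. The aggregation
  scheme is user-defined in principle; best-score is the conventional
  all-against-all reduction and the default here.
* **similarity** — dock against the structure whose co-crystallized ligand
  has the highest Tanimoto similarity (same fingerprint configuration) to
  the query; the classical ligand-similarity baseline.

With a one-structure ensemble all four protocols provably coincide; this
reduction is tested exactly.

## Scores

Scores follow binding-free-energy semantics: lower is better, stored raw,
never negated. When a compound has several representations
(tautomers/protomers), the most favorable representation score is kept.
Missing scores are explicit (never coerced to a number), rank last, and a
compound with no score anywhere is excluded from ensemble reduction with a
warning.

## Evaluation

* **ROC/AUC** via trapezoidal integration of the ROC curve, which equals
  Mann–Whitney pairwise concordance with 0.5 credit per active–decoy tie
  (docking scores can tie); the equivalence is enforced against an
  independent pairwise oracle to 1e-12 in the tests.
* **Enrichment factor** EF_f = active rate in the top ⌈f·N⌉ ÷ library-wide
  active rate. The ceiling keeps the top set non-empty; EF values are
  sensitive to this convention and to data-set composition, so cross-study
  EF comparisons are disclaimed.
* **MCC** from the 2×2 confusion matrix, 0 when a margin is empty.
* **Y-scrambling**: labels permuted uniformly (seeded, default 10 repeats),
  cross-validated MCC recomputed per repeat with the same protocol as model
  selection. A sound setup collapses to MCC ≈ 0.
* **Selection diagnostics**: per-structure selection counts (they must sum
  to the library size) and per-structure active proportions, to check that
  selection does not funnel actives into "good" structures and decoys into
  "bad" ones.

## Synthetic benchmark

The generator emulates only the statistical structure the method exploits:

* Compounds belong to one of K feature clusters. Each cluster owns 40
  disjoint signature bits out of 1024; a member sets its own signature bits
  with probability 0.9, foreign signature bits with 0.05 and background
  bits with 0.02. Within-cluster Tanimoto similarity therefore exceeds
  between-cluster similarity, mimicking chemical series.
* Each cluster has exactly one planted compatible structure (identity map
  by default, 10 clusters onto 10 structures). An active's latent affinity
  is 4.0 on its compatible structure and 0.0 elsewhere. A decoy acquires a
  spurious affinity of 3.0 independently per structure with probability
  0.05 — with 10 structures, 1 − 0.95¹⁰ ≈ 40 % of decoys have at least one
  spuriously favorable structure, which is precisely the ensemble-docking
  false-positive mechanism.
* Observed score = −affinity + Gaussian noise (σ = 1.0). Lower is better.
* Library: 200 actives, 2000 decoys (a 1:10 ratio typical of
  actives/decoys benchmarks), split 80:20 stratified by activity.
* The similarity baseline's "co-crystallized ligand" of a structure is one
  active sampled from its compatible cluster.

All generation is deterministic given the spec seed (default 7), with named
substreams for assignment, features, affinities, noise and ligand sampling.

### What the generator does and does not show

Passing the end-to-end tests demonstrates that the implementation recovers
planted structure–compound compatibility from rank-derived labels and that
learned selection beats the best-score ensemble reduction *when such
compatibility structure exists*. It does not demonstrate performance on
real chemistry: cluster signatures are far cleaner than chemical series,
decoys are feature-indistinguishable from actives of the same cluster, and
docking-score noise is homoscedastic Gaussian.

Two honest consequences of that design are worth recording. First, because
feature clusters map one-to-one onto compatible structures, the
ligand-similarity baseline is a near-oracle selector on synthetic data and
scores *above* the learned battery there — on real chemical data the
relationship is typically reversed, but reproducing that requires real
chemistry, and no test here asserts the learned method beats the
similarity baseline.
Second, absolute per-structure CV MCC is low (≈ 0.02) on the synthetic
benchmark: features carry no within-cluster activity signal, so absolute
correctness is barely predictable even though the *relative* probabilities
across structures — all the selector uses — are informative.

## Problem sizes and defaults

The package-wide random-forest default is 100 trees with `sqrt`
max_features. The benchmark pipeline's default grid is a single cell
(500 trees, `sqrt`, the configuration full-scale cross-validated model
selection favors), with 5-fold CV for the selection metadata; the full
18-cell grid and 10-fold CV
remain available through `HyperparameterGrid` and the `cv_folds` argument.
Y-scrambling runs 10 repeats of 10-fold CV on one structure's label set
with the package default forest. On the default benchmark
(2200 compounds × 10 structures, 1024-bit features) the full method
comparison takes about three minutes and the scrambling control about one
minute on a single CPU.

## Numerical conventions

* Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  compounds always score 1).
* Ranking ties break by compound id; structure-selection ties break by
  structure id.
* Stratified splitting raises if any class has fewer than two members;
  cross-validation raises if any class has fewer members than folds.
* SMOTE requires at least two minority samples; `k` is clipped to the
  number of available minority neighbours.
* Seeds: every stochastic stage (split, CV folds, SMOTE, forests,
  scrambling) draws its seed from one global seed via named substreams;
  manifests record all of them.

## Known limitations

* Only random forests are implemented as the correctness learner (the
  plug-in seam exists; nothing else is specified).
* Exactly one structure is selected per compound; top-k selection is out of
  scope.
* No pose handling: only scores flow through the pipeline, so pose-level
  analyses (binding-mode inspection, RMSD) are impossible by design.
* The 80:20 split is stratified and seeded; published train/test counts of
  the reference data sets deviate slightly from an exact 80 % and are not
  reproduced exactly.
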