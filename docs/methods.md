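# Methods

## Problem and model

The package infers a tumor's tissue of origin from two molecular modalities
measured on the same samples: bulk gene expression (TPM) and somatic
mutations reduced to per-gene counts. The classifier is a bagged ensemble of
CART-style decision trees; feature selection uses the same ensemble's Gini
variable importance. Both the selector and the classifier are implemented
natively so that every intermediate of the importance computation — per-node
class weights, impurities, per-split decreases, per-tree and forest-level
accumulators — is inspectable and re-derivable from the stored trees.

## Feature construction

Mutation records arrive as one row per called mutation with key (donor,
chromosome, locus, affected gene). Records are deduplicated on the full key
— the same physical mutation reported twice counts once — with chromosome
names compared after normalization (`chr1` ≡ `1`) and loci treated as
1-based positions. All allele classes are collapsed: any mutation in a gene
increments that gene's count for that donor. Ensembl IDs are mapped to gene
symbols; IDs missing from the map, and IDs mapping to more than one symbol,
are dropped with logged counts (the mapping table's granularity, not the
classifier, should resolve ambiguity).

Merging keeps exactly the samples present in both modalities and carrying a
retained class label. Samples absent from one modality are excluded, not
zero-filled: a zero count from a sequenced sample is informative, absence of
the sample from the table is missingness, and conflating them would let the
classifier read missingness as biology. Expression values enter untransformed
(TPM); `log2(TPM+1)` is available behind a flag but off by default — the log
scale is used only for display tables. Feature names carry modality prefixes
(`expr:`/`mut:`) so the two modalities share one namespace without collision.

## Trees, forests, importance

* Node impurity: `G(p) = 1 − Σ pₖ²`, bounded by `1 − 1/K` for K classes.
* Splits: thresholds are midpoints between consecutive distinct sorted
  values; at each node `mtry` features are sampled without replacement
  (default ⌊√N⌋, the canonical random-forest choice); the split maximizing
  the impurity decrease is taken. Any impure node with a valid threshold and
  ≥ `min_samples_split` (default 2) samples is split, even at exactly zero
  decrease — the XOR configuration requires zero-decrease root splits, and
  by concavity of the Gini index the child-weighted decrease is never
  negative. There is no depth cap.
* Determinism: split ties (which arise as exact rational ties and may differ
  by one ulp in float arithmetic, so ties are detected at 1e-12) resolve to
  the lowest feature index, then the lowest threshold; vote ties to the
  lexicographically smallest class label. Every tree draws its bootstrap
  resample and candidate features from an independent substream of one
  seeded generator, so a forest is a pure function of (data, hyperparameters,
  seed).
* Importance conventions. The per-split decrease is computed either as
  `G(parent) − (n_l/n) G(left) − (n_r/n) G(right)` (**weighted**, default) or
  as the unweighted difference `G(parent) − G(left) − G(right)` (**literal**).
  Accumulation into a feature's tree-level importance follows the convention:
  under `weighted`, each node's decrease is additionally scaled by the
  fraction of the tree's training samples reaching the node — the standard
  mean-decrease-impurity accumulation. Unscaled accumulation measurably
  inflates deep splits on continuous features: on reference synthetic
  cohorts it ranked sparse integer mutation markers below hundreds of
  pure-noise expression genes, an artefact rather than a signal, which is
  why the scaled form is the default. Under `literal` the decreases are
  summed as printed, and nodes whose best split has negative literal
  decrease become leaves, giving deliberately conservative trees.
* Forest importance is the plain sum of tree importances; unused features
  get importance 0 and rank last, alphabetically. Ties in the ranking break
  by feature name.

## Selection protocol

`select_top` takes the first H features of the ranking. The sweep evaluates
a schedule of H values (default 5, 10, 20, 30, 40, 50, then 55–120 in steps
of 5) by cross-validation, re-fitting the ranking **inside each training
split**: ranking once on the full data before splitting leaks the held-out
labels into the selector and inflates accuracy. The leaky protocol remains
available (`rank_once`) for comparison. Best H is the accuracy argmax, ties
to the smallest panel.

## Evaluation

Per class: precision TP/(TP+FP), recall TP/(TP+FN), F1 as their harmonic
mean, specificity TN/(TN+FP), support; overall accuracy is the fraction
correct. Zero-denominator metrics are reported as 0 with a warning flag
rather than NaN so cohort-level (unweighted macro) means stay defined — with
20-fold class imbalance a small class can legitimately receive no positive
predictions in a fold. Cross-validation is repeated stratified k-fold
(default 10×10); stratification keeps rare classes in every training split
(the smallest class is ~7× rarer than the largest under the default cohort
profile), with a `--no-stratify` escape hatch and automatic fold-capping when
a class has fewer members than folds. Fold partitions come from
scikit-learn's `StratifiedKFold`/`KFold` with per-repeat substream seeds; the
metrics themselves are computed natively from the confusion tallies.

Class-mean summaries for heatmap tools are `log10(mean + 1)` per class and
feature; base 10 and pseudocount 1 keep all-zero mutation features at
exactly 0.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, not the biology
underneath it:

* Expression: gene g in class k is `exp(Normal(μ_{k,g}, σ²))` with σ = 0.5
  on the log scale; informative genes add a mean shift δ (default 2.0) in
  their assigned class. This gives TPM-like non-negative, right-skewed
  values.
* Mutations: per-(sample, gene) Poisson counts, background λ₀ = 0.05
  mutations/gene/sample (sparse, like real somatic data), multiplied by a
  rate ratio (default 10) for an informative gene in its class. Counts are
  expanded into individual records with distinct synthetic loci, and 5% of
  records are duplicated verbatim so the deduplication path is always
  exercised.
* Class sizes default to the published 20-type cohort's imbalance profile
  (7,008 samples, largest:smallest ≈ 8:1) scaled by largest-remainder
  rounding to any requested total.
* Informative genes are assigned to classes round-robin; mutation markers
  continue where expression coverage stopped, so when expression markers do
  not cover every class the two modalities are complementary by
  construction.

What the generator does **not** emulate: gene–gene correlation, mutational
signatures, batch effects, library-size artefacts, or biologically realistic
marker effect sizes. Passing the synthetic checks therefore demonstrates the
machinery (selection recovers planted signal, combination helps when
modalities are complementary, the null is calibrated) — not clinical-grade
accuracy on real cohorts.

## Reference experiment sizes

The reproduction experiments (`toome.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) use fixed problem sizes
chosen as the smallest cohorts at which the measured effects are stable
across seeds:

* **Recovery**: the generator's reference cohort — 20 classes with the
  published imbalance scaled to 400 samples, 500 expression + 200 mutation
  genes, 20 + 5 planted markers, δ = 2.0 — one 150-tree ranking forest per
  replicate, 10 replicates; recovery is the fraction of the 25 planted
  features inside the top-80 panel (the panel size the published method
  settles on). Typical value ≈ 0.84: all 20 expression markers plus the
  mutation marker of the largest class; mutation markers of small classes
  sit below the noise floor at λ-ratio 10, which is the expected behaviour
  at these rates, mirrored by reference implementations.
* **Modality comparison**: 6 balanced classes × 40 samples, 60 + 40 genes,
  4 expression markers (classes 1–4) and 14 mutation markers (two each on
  the expression-dark classes 5–6); top-20 selection re-fit per fold, 3-fold
  × 2-repeat CV, 80 trees, 6 replicate cohorts. Combined ≈ 0.83 versus
  expression-only ≈ 0.77 and mutation-only ≈ 0.59.
* **Null calibration**: 5 balanced classes × 24 samples with labels
  randomly permuted after generation; 5-fold × 2-repeat CV. Accuracy sits at
  1/K within sampling error.
* **Determinism**: the full pipeline (simulate → merge → rank → select →
  cross-validate) run twice at one seed on a 120-sample cohort must produce
  byte-identical matrices, rankings and reports.

## Known limitations

* Exact importance ties attribute a node's decrease to one of the tied
  features (lowest index); column-permutation invariance of the ranking
  holds up to such ties.
* The printed-table checks reproduce five per-class F1 cells exactly; two
  published rows (READ, BLCA) recompute to values 1–2 in the last digit away
  from print, consistent with rounding of hidden decimals, and one published
  cohort percentage (LUSC) shows the same artefact.
* Tree growth to purity with `min_samples_split = 2` and no depth cap
  overfits individual trees by design (bagging averages it out), so single
  trees from this package should not be interpreted in isolation.
* The headline accuracies published for the real 7,008-sample cohort are not
  reproducible from synthetic data; the experiments here validate mechanism,
  determinism and calibration at desk scale.
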