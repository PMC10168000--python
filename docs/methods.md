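# Methods

## Problem and model

A bare database identifier is a short string whose surface grammar (literal
prefixes, character classes, length) is characteristic of — but not unique
to — the database that minted it.  `bioidkit` treats source-database
assignment as supervised multiclass classification over character-positional
features, with a regex prefilter available for coarse candidate screening.
The pipeline is: corpus generation (or ingestion) → cleaning → fixed-width
integer encoding → class balancing → feature filtering → four classifiers →
vote unification → metric reports.

## Character-positional encoding

Each identifier becomes a row of length *L* (the longest identifier in the
cleaned training table): position *j* holds the integer code of character
*j*, and positions past the identifier's end hold the reserved pad code 0.
The code map is fixed rather than fitted: digits `0`–`9` → 1–10, `A`–`Z` →
11–36, `a`–`z` → 37–62, then `. _ - : / (` `)` → 63–69.  Case matters
(UniProt symbols are upper-case, UCSC ids lower-case), so the map is
case-sensitive.  Identifiers are padded on the right: the informative
prefix stays at aligned positions and the padding accumulates in the
trailing columns, which the feature filter can then judge.  The map is
serialized with every trained model; at prediction time identifiers longer
than the training *L* are truncated with a warning, and characters outside
the inventory map to the pad code with a warning instead of failing.
Encoding is a bijection on valid identifiers of length ≤ *L* (tested by
round trip on generated corpora).

## Synthetic registry and what it does (not) emulate

The built-in registry holds 39 database classes, each with an anchored
regular expression and a structured sampling template (literal prefixes plus
character-class runs with length ranges).  These are plausible emulations of
the real grammars (`^CHEMBL\d+$`, `ENSG` + 11 digits, `HGNC:` + digits, …),
not authoritative identifiers.org entries.  Templates were chosen so that
the 39 sampled distributions are pairwise disjoint or nearly so; the regexes
themselves still overlap (a ChEMBL accession is a legal gene-symbol surface
form), which is faithful to real databases and is why `match()` returns all
matching classes in registry order.

The generator is seeded and draws uniformly within each template, with
uniqueness enforced per class by rejection sampling (a capacity check fails
fast when more distinct strings are requested than the template can
produce).  The bundled reference profile records the per-class corpus sizes
of a real Ensembl-derived retrieval (2,751,478 rows over 39 classes,
≈14,702:1 imbalance); it drives the balancing arithmetic and scaled-down
experiments.

What passing tests on this corpus show: the pipeline separates classes whose
grammar differs anywhere in the encoded window, at realistic imbalance, and
the unification rule repairs individual learners' mistakes.  What they do
not show: performance on real corpora where distinct databases share
*distributions* (not just grammars) — e.g. gene-name-derived classes such as
WikiGene versus UniProt symbols drawn from the same vocabulary — or where
retrieval noise, versions and suffixes depart from the emulated templates.
Real-world accuracy must be established on retrieved data.

## Balancing

Per class of size *n*, the training side keeps round-half-even(0.7·*n*)
rows, evaluated in exact rational arithmetic; the remaining rows are the
held-out test set.  Classes below the target *T* are topped up to *T* with
synthetic rows; *T* defaults to the ceiling of the mean class count, the
unique constant that reproduces, cell for cell, the published balanced
counts of the 39-class reference corpus (*T* = 70,551).  Majority classes
keep their plain 70% split by default — the reference counts show no
undersampling — but a seeded random cap at `undersample_ratio · T` training
rows is available.

SMOTE here operates on integer codes, which are categorical at heart: a
synthetic row interpolates between a real row and one of its *k* = 5 nearest
same-class neighbours (Euclidean distance on the codes, λ ~ U[0,1]) and is
then rounded coordinate-wise to the nearest integer, so children stay within
the parents' per-position code range.  *k* is clipped to class size − 1;
single-row classes fall back to duplication with a warning.  Synthetic rows
are never placed in the test set.

## Feature filtering

Two criteria act in sequence.  (1) Importance: per-position mean Gini
impurity decrease from a seeded random forest; positions below
`importance_fraction` (default 0.01) of the maximum are dropped.  (2)
Redundancy: among survivors, visited in decreasing importance, a position
correlated above `corr_threshold` (default 0.95, |Pearson r| on the numeric
codes) with an already-kept position is dropped.  The thresholds are
configurable because no canonical values exist; the defaults remove
all-pad trailing columns (zero importance) while keeping positions that
carry length information.  Constant columns get correlation 0 off-diagonal
by convention, so padding columns are judged by importance alone.  The rule
is monotone in the importance fraction, never empties the feature set, and
is invariant under feature permutation when importances are distinct (ties
break by position index).

## Learners

Reference hyperparameters (defaults):

| learner | settings |
|---|---|
| CART | complexity (cost-complexity α) 0.00053, max depth 24, min node 4 |
| RF | 385 trees, max depth 368, Gini criterion, OOB evaluation on |
| XGBoost | η 0.29, max depth 8, subsample 0.84, gbtree, γ 0, λ 0.92, α 0.014, 10 rounds, column sampling 0.99 |
| MLP | two hidden layers of 40 ReLU units, softmax output, Adam, batch 128, 64 epochs, cross-entropy |

Notes on mapping: the CART complexity parameter is implemented as sklearn's
cost-complexity pruning α (the scales are comparable but not identical to
rpart's relative `cp`); the RF `minprop` value 0.017 belongs to the
maximally-selected-rank split rule and is inert under the Gini criterion, so
it is carried in the spec but not mapped to an estimator argument.  The
network standardizes its inputs (the integer codes span 0–69, and Adam
converges much faster on standardized features); tree learners consume raw
codes.  Labels are integer-encoded internally (XGBoost requires it) and
mapped back on prediction.  All estimators are seeded and single-threaded,
so training is deterministic given the seed.

## Hyperband tuning

The tree learners can be re-tuned by hyperband with halving factor η = 3 and
four stages: maximum resource R = η³ = 27, brackets of n = ⌈(s_max+1)/(s+1) ·
ηˢ⌉ configurations (27, 12, 6, 4 — 49 sampled in total), resources growing
η-fold per stage, and only the lowest-loss ⌊n/η⌋ configurations surviving
(ties break by sampling order).  The resource unit is the fraction of
training rows: a configuration at resource *f* trains on a seeded
*f*-fraction subsample of an 80% tranche and is scored by classification
error on the fixed remaining 20%.  Search spaces are bounded boxes around
the reference configuration.  Tuning is off by default (the reference
values are used); `tune=True`/`--tune` enables it.

## Unification and evaluation

Votes with a ≥ 3-of-4 majority win directly; otherwise each model's vote is
scored as F1 times the product of `c + (1−c)·P(y|x)` over dissenters (see
README).  Design choices: "majority" excludes 2–2 and 2–1–1 splits (both go
to scoring); *c* defaults to 0.5; P(y|x) is read as the probability that a
true-*x* sample is predicted *y*, i.e. the row-normalized held-out confusion
matrix; score ties break toward the higher-macro-F1 model, then by the fixed
order rf → xgb → mlp → cart.  A qualitative sensitivity statement holds by
construction: the score is affine and non-decreasing in each dissenter
probability, with slope proportional to (1 − c), vanishing at c = 1.
Classes absent from a model's held-out partition would make P(·|x)
undefined; they receive uniform rows with a logged warning.

Metrics use the standard one-vs-rest definitions Pre = TP/(TP+FP),
Rec = TP/(TP+FN), F1 = 2TP/(2TP+FN+FP), Acc = (TP+TN)/total.  (Some
published presentations of these formulas swap FN and FP in precision and
recall; the implementation follows the universal definitions.)  0/0 cells
are reported as 0 with an `undefined` flag so tables stay rectangular.

## Reproducibility and problem sizes

A run is a pure function of (config, seed): the global seed fans out to
per-stage seeds by stable hashing of stage names, every estimator is seeded
and single-threaded, and TSV outputs use fixed float formatting, so repeat
runs are byte-identical.  The scaled-down experiment used by the test suite
and the acceptance script draws 1,000 identifiers per registry class
(39,000 rows; 27,300 training after the 70% split, no SMOTE needed since the
profile is already uniform) and reduces the network to 10 epochs; it
completes in a few minutes on one CPU and reaches ensemble held-out accuracy
above 99%.  Tuning-stage, correlation, importance and confusion plots are
written as PNG next to their TSVs.

## Known limitations

- Synthetic corpora overstate separability relative to real retrievals with
  shared vocabularies (see above); the headline accuracy here is a property
  of the emulated grammars.
- The integer codes are ordinal at best; Pearson correlation and Euclidean
  SMOTE distances treat them as numeric, a pragmatic simplification.
- CART's pruning constant is scale-sensitive: at small corpus sizes it can
  prune away splits separating rare classes.
- The ensemble requires exactly the four trained learners; it does not
  degrade gracefully to subsets.
- Live database retrieval and URL/keyword validation of candidate IDs are
  out of scope; the registry is an offline emulation.
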