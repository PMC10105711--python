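# Methods

## Data model

A `RelationalUniverse` holds five entity registries (drugs, cell lines,
protein targets, proteins, metabolites) and eight relations: drug→target
edges, undirected protein–protein edges (stored with endpoints sorted),
target→metabolite edges, three binary target↔attribute association sets
(gene mutation, gene expression, differential methylation), and a per-drug
real chemical vector. Genomic attributes are modeled as binary indicators,
not continuous values, because the feature matrix treats them as 1/0
relations. Registries are sorted lexicographically on load so that every
downstream column layout is a pure function of the data on disk.

Serialization is one headered TSV per relation. Registry sidecar files
(`drugs.tsv`, `targets.tsv`, `proteins.tsv`, `metabolites.tsv`) keep
entities with no incident relation alive across round-trips; when present
they are authoritative, so a relation row referencing an unlisted
identifier fails validation with the offender named.

## Pair-vector assembly

A drug's profiles are derived from its target set: the DT indicator row,
and — through its targets — union PPI-partner, PMI-metabolite and GM/GE/DM
attribute profiles. A pair vector on a cell line is assembled block-wise in
the fixed order DT, GM, GE, DM, CF, SIM, CL:

* union (OR) for DT/GM/GE/DM — symmetric in the two drugs;
* concatenation for CF, in canonical (registry-order) pair order;
* SIM: Russell–Rao similarity `x/d` of the two drugs' PPI profiles and of
  their PMI profiles — the reduction that replaces the two widest blocks
  with one scalar each;
* one-hot CL.

This assignment of combination modes is the only one consistent with all
six cumulative group widths under the preset (odd widths like 333 and 95
cannot arise from per-drug concatenation; 526 chemical columns = 2 × 263).
Chemical vectors are 256 folded circular-substructure count slots (radius
2) plus 7 descriptors; 256 is inferred from the block-width arithmetic, and
both slot count and radius are configurable. A missing chemical vector is a
hard error rather than an imputation.

Descriptors follow the classic Lipinski definitions: H-bond donors are
counted as O–H/N–H hydrogens and acceptors as N+O atoms (the stricter SMARTS
donor pattern assigns water zero donors, which contradicts the physical
reading of "donor count").

## Labels

ComboScore is binarized by sign: positive → 1 (synergistic), negative → 0
(antagonistic), exact zero → excluded (additive). The empirical ranges seen
in screens (≈1..200 and −1..−228) are descriptive only; no clamping is
applied. Replicate measurements of one (drug_i, drug_j, cell line) triple
are averaged *before* binarization (mean is order-independent and
seed-free), with pair order canonicalized first. Class balancing
down-samples whichever class is in the majority to the minority count,
uniformly without replacement under a seed.

## Synthetic universe and planted signal

The generator emulates the relational shape of the curated multi-database
universe: every relation is sampled as independent Bernoulli edges at a
configurable density; substructure counts are Poisson(2); descriptors are
standard-normal surrogates (unitless; they stand in for TPSA, molecular
weight, logP, ring and donor/acceptor counts without mimicking their
scales). Target identifiers are drawn from the protein registry, so PPI
partner profiles resolve. When density is positive, each genomic attribute
is guaranteed at least one association so attribute-registry widths equal
the configured counts (at density zero all relations are empty, as
configured).

The preset universe reproduces the published feature-space arithmetic
exactly: 74 drugs, 60 cell lines, 333 targets, 95/264/334 genomic
attributes, 263 chemical columns per drug → group lengths 393, 488, 752,
1086, 1612, 1614. Protein (700) and metabolite (400) registry sizes and the
0.05 edge density are this package's choices: the source universe's PPI/PMI
blocks are orders of magnitude wider, but only their Russell–Rao scalars
enter the classifier, so what matters is that the similarity distribution is
non-degenerate.

Labels come from a linear-logistic planted signal over the full (group-VI)
pair-vector layout: raw score = w·x + b + N(0, σ). Because every feature
block is non-negative, an arbitrary w shifts all scores by a large common
offset; `center_signal` therefore sets the intercept to minus the median
noiseless score, making the planted classes balanced by construction. A
seeded fraction of records is forced to score exactly 0 so the additive
exclusion rule is exercised. The noiseless part of the score is computed
once per drug pair and the cell-line one-hot contribution added per line,
which makes generation O(pairs) rather than O(records) in vector
assemblies.

What the generator does *not* emulate: real dose–response surfaces,
correlated biological structure (hub proteins, pathway modularity),
realistic chemistry, or the severe class imbalance of real screens. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
calibrated — not that the reported real-data accuracies transfer.

## Models

The conic MLP (hidden 512 → 128 → 32, ReLU, sigmoid output, binary
cross-entropy) is implemented directly on NumPy: He initialization,
minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), learning rate 10⁻²,
batch 128, 100 epochs, no early stopping and no dropout. Optimizer, batch
size and epoch count are this package's defaults (only the learning rate
and architecture are fixed by the design); all are exposed as
hyperparameters. One `Generator` drives initialization, shuffling and
dropout masks, so equal seeds give bit-identical parameters.

Baselines: shallow NN (one hidden layer, width 64 — unspecified upstream,
configurable — inverted dropout 0.8, 300 epochs, same NumPy engine), KNN
(n = 4, Minkowski, p = 2), linear-kernel SVM (degree 3 — inert under the
linear kernel — cache 200), random forest (depth 4, 10 estimators),
gradient boosting (depth 3, 100 estimators), all via scikit-learn. The
SVM's probability output is the sigmoid of its decision margin, so the 0.5
threshold coincides with the SVM's native decision rule and no auxiliary
calibration fit is needed.

All models train on min-max-scaled features fitted on the training rows
only (the design matrix mixes binary, count and real columns). The
classification threshold is fixed at 0.5 because classes are balanced by
construction. Numerical safeguards: the sigmoid is evaluated piecewise to
avoid overflow, and cross-entropy clips probabilities to [1e−12, 1−1e−12].

## Evaluation

Folds are stratified (plain random splitting would make per-fold kappa
ill-defined when a fold drifts from 50/50). Metrics follow the standard
confusion-matrix formulas; kappa's chance agreement is the two-rater
product of marginal rates P_c = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N²; MCC
is defined as 0 when any marginal under the root is zero, and ratio metrics
with an empty denominator return 0. AUC is the Mann–Whitney rank statistic
with ties counted ½ — exact and threshold-free, identical to trapezoidal
ROC integration. McNemar's statistic keeps the continuity correction
(|B−C|−1)²/(B+C) with a χ²(1) null; with no discordant pairs the result
carries a not-applicable flag instead of a statistic. Cross-validation
refits scaler and model per fold; the ablation reuses one fold assignment
across feature groups so group comparisons are paired. Per-fold means are
the headline aggregates; pooled-prediction metrics are also available from
the retained pooled vectors.

## Problem sizes

Tests and the acceptance script run scaled-down universes chosen so the
full suite completes in minutes on one core: planted-signal experiments use
40 drugs × 8 cell lines (2000 balanced records, ~210-column pair vectors),
null-calibration runs 24 drugs × 6 cell lines (1000 records), and the
direction-recovery property uses 72 drugs so that the number of *distinct*
drug pairs (2556) exceeds 2000 — pair diversity, not record count, is what
identifies the planted direction. The preset universe (74 drugs, 1614
columns) is used only for schema arithmetic, which needs no training.

## Known limitations

* The real curated dataset is out of reach offline, so no claim is made
  about reproducing its published accuracy values; the synthetic experiments
  check calibration, ordering and machinery instead.
* The planted signal is linear; it cannot probe the MLP's advantage over
  linear baselines (on such data a linear SVM is near-Bayes-optimal, as the
  comparison output shows).
* PPI/PMI similarity is the only channel through which interaction data
  enter; with sparse random graphs the two scalars carry little signal, so
  group VI typically improves on group V only marginally — consistent with
  the small increment the reduction is designed to give.
* The one-hot cell-line block assumes the panel is closed; unseen cell
  lines cannot be encoded.
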