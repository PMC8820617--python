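# Methods

## Problem and model

`cypscreen` treats CYP2C9 inhibition as a binary classification problem over
small molecules, with two coupled feature families:

- **ligand-based**: 2D/3D physicochemical descriptors of the molecule;
- **structure-based**: interaction energies (IEs), the best docking score of
  the molecule against each of seven receptor conformations — the crystal
  structures 1R9O and 5XXI and five MD-derived snapshots MD1–MD5 — in
  kcal/mol, more negative meaning stronger predicted binding.

Two classifiers are trained on the combined matrix: a random forest
(bootstrap trees, majority vote) and an RBF-kernel support vector machine.
For screening, their **consensus** (both must predict "inhibitor") is
combined with a strict per-conformation IE filter. The design premise is
that the two model families fail differently, so their intersection trades
sensitivity for precision — the right trade when selecting a handful of
compounds for experimental follow-up.

## Curation

- **Labels.** Inhibitor iff AC50 (or IC50) ≤ 10 μM, boundary inclusive.
  Non-inhibitor iff % inhibition at 50 μM < 10 and no qualifying AC50.
  Everything else is ambiguous and excluded from modeling. If both rules
  fire for one record the evidence is contradictory and the package raises
  an error rather than picking a side.
- **Soft drug-like filter** defaults: MW ∈ [100, 800], logP ∈ [−4, 8],
  HBD ≤ 7, HBA ≤ 14, rotatable bonds ≤ 20, TPSA ≤ 250 Å². These are
  deliberately looser than Lipinski-style rules: the goal is to drop clearly
  non-drug-like chemistry while keeping the broad space CYPs actually bind.
  PAINS/electrophile alerts are *not* removed by default (reactive compounds
  can be genuine CYP inhibitors); a small alert set exists behind a flag.
- **Deduplication** is by canonical SMILES. Same-label duplicates merge
  provenance; conflicting-label duplicates are dropped entirely and logged —
  a coin-flip label would inject irreducible noise into training.
- **Diversity clustering** (cutoff 0.85) and the train/test split are
  described below.

## Fingerprints and leader clustering

All diversity clustering is sphere-exclusion (leader) clustering on bit
fingerprints: candidates are processed in descending order of neighbor count
at the cutoff (ties by ascending id); each unassigned candidate becomes a
centroid and absorbs every unassigned molecule with Tanimoto similarity ≥
cutoff. This is deterministic given the input and guarantees that members
are within the cutoff of their centroid and centroids are pairwise below it.
The neighbor-count order favors centroids in dense regions; an "input"
order policy exists for experiments. Fingerprints are open substitutes for
the proprietary descriptors used in common desktop tools: an RDKit path
fingerprint (default, and screening stage 2 at cutoff 0.70), 166-bit MACCS
keys (screening stage 1 at 0.80), and a Morgan circular fingerprint. The
kind used is recorded in every cluster assignment.

## Descriptors

The matrix uses an open descriptor set, namespaced `d2.*` / `d3.*`:

- 86 2D descriptors: constitution (MW, heavy atoms, ring/aromatic counts,
  rotatable bonds, …), lipophilicity (Crippen logP/MR), topology (Balaban J,
  Bertz, kappa shape, Chi indices), Gasteiger partial-charge extremes, and
  the PEOE/SlogP/SMR/EState VSA series partitioning molecular surface area
  by charge, logP, refractivity and E-state — these carry the
  charged/hydrophobic-surface information that matters for CYP binding.
- 11 3D descriptors from one ETKDG conformer embedded at a fixed seed:
  principal moments of inertia and ratios, asphericity, eccentricity,
  inertial shape factor, radius of gyration, spherocity, plane-of-best-fit.

A molecule either yields the full column set or is moved to a rejects list
(`embed_fail`, `descriptor_nan`, `smiles_parse`); no partial rows.

**Pruning.** Near-zero-variance columns are removed first (constant, or
most-frequent:second-most-frequent ratio > 19 with < 10% distinct values —
the conventional two-part rule; both thresholds configurable). Then
correlation pruning scans column pairs left-to-right: of a surviving pair
with |Pearson r| ≥ 0.85 the lower-variance member is removed (variance tie:
the alphabetically later name). A single pass suffices — every pair is
examined while both members still survive — so the post-condition (no
surviving pair at |r| ≥ 0.85) is exact, and is verified in tests against an
exhaustive direct-formula oracle.

**Standardization** (mean 0, sd 1, ddof = 1) applies to the SVM path only;
the forest consumes raw values. Fitted means/sds travel with the model and
are applied unchanged to test and screening data, never refit.

Every transform appends a provenance entry holding its surviving column
list, so replaying the chain on the raw matrix reproduces the processed
matrix exactly.

## Interaction energies

Docking is external. The package parses engine output (the `RESULT:`-line
dialect, the console score table, or a generic `mode,score` form), keeping
the **minimum** (best) mode score per conformation. Default job settings —
one 25 Å cube centered at (8.208, 32.219, −1.923) with exhaustiveness 8,
10 output modes, 1 Å grid — are shared by all seven conformations.
kcal/mol is the only unit.

The screening filter passes a molecule iff its score is **strictly below**
the threshold for *every* conformation; a score exactly at the threshold
fails, and an incomplete profile is an error rather than an implicit fail,
so missing docking runs surface instead of being masked. The default
threshold is −8.5 kcal/mol, with a utility that re-derives it as the
q-quantile (default q = 0.75) of the pooled molecule × conformation scores
of training inhibitors. The "75%" phrasing admits several readings
(pooled quantile, per-conformation quantiles, fraction of inhibitors
passing); the package implements the pooled-quantile reading as the default
and keeps the threshold a single global number applied per conformation,
which is the simplest semantics consistent with one published constant.

## Feature selection and training

- **Cross-validation**: stratified 10-fold, repeated 5 times; repeat *r*
  uses seed + *r*. The same folds are reused across every hyperparameter
  point of one scan, so accuracy comparisons are paired.
- **Forest grid**: *ntree* ∈ {25, 50, 100, 200, 300, 400, 500} (the range
  endpoints are fixed; the intermediate points are a log-ish default),
  *mtry* from 5 up to ⌊√p⌋ (13 at p = 177). Winner = best mean CV accuracy;
  ties prefer smaller *ntree*, then smaller *mtry* — the cheapest
  equally-good forest.
- **Importance protocol**: at the winning hyperparameters, many forests are
  grown with seeds seed + run (default 2000 runs) and their mean
  decrease-in-Gini vectors averaged. Selection is by rank (top-k) or by an
  absolute importance threshold; rank-based selection is preferred since the
  absolute Gini scale depends on sample size. All ranking ties break
  alphabetically for determinism.
- **SVM**: cost ∈ {2⁻², …, 2⁷} (10 points); the RBF width uses the median
  heuristic (γ = 1 / median pairwise squared distance, subsampled above
  2000 pairs) with {0.5×, 1×, 2×} multipliers. Ties prefer the smaller
  cost. Input must be standardized (checked); the bundle stores the scaling
  and applies it internally at prediction time, so `predict` always takes
  raw descriptor values for both algorithms.
- **Scores**: RF reports the fraction of tree votes; the SVM passes its
  decision value through a logistic link fitted on the training decisions.
  Consensus screening consumes hard labels only; scores are auxiliary.
- Bundles persist via a versioned joblib archive (schema version, selected
  descriptor names, hyperparameters, scaling, training-data fingerprint);
  loading refuses a mismatched schema version.

## Evaluation

Positive class = inhibitor. Accuracy, sensitivity, specificity, balanced
accuracy as percentages (2 decimals in reports); MCC as a fraction, also
reported ×100 for table parity. MCC returns 0 when a marginal is zero.
Classifier pairs on a common test set are compared with the **exact McNemar
test** on discordant correctness pairs — two-sided
p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½) — the natural paired
test when both models score the same molecules; an unpaired two-proportion
z-test is available behind a flag for sensitivity analysis. The exact-test
implementation is cross-checked against statsmodels in the test suite.

## Screening cascade

prioritized = (RF says inhibitor) ∧ (SVM says inhibitor) ∧ (IE < threshold
in all 7 conformations). Counts are monotone along the cascade by
construction and asserted at run time. Prioritized hits are clustered on
MACCS keys at 0.80; the stage-1 centroids are re-clustered on the path
fingerprint at 0.70. One candidate (the centroid) is drawn per final
cluster; clusters with more than 10 members yield ⌈size/15⌉ picks, extras
chosen by greedy max-min Tanimoto dissimilarity so an 18-member cluster
gives 2 picks and a 37-member cluster 3. Known inhibitors can be excluded
up front via a user-supplied id list; no knowledge base is bundled.

## Synthetic study conditions

The fixtures module defines the conditions everything is tested under:

- Descriptor tables: `n_active = n_inactive = 300`, 5 informative + 100
  noise descriptors. Informative columns are Normal(±effect/2, 1) by class
  (default effect = 1.5, i.e. a standardized separation of 1.5); noise is
  Normal(0, 1). Column names carry the planted truth (`inf.*`, `noise.*`).
- IE profiles: actives Normal(−10, 1), inactives Normal(−6, 1) kcal/mol per
  conformation, independent across conformations by default (a correlation
  knob exists, default 0). This brackets the −8.5 threshold between the
  class modes, mimicking the observed shift of inhibitor score
  distributions toward stronger binding.
- An embedded list of 45 entries: 42 generic public-domain drug-like
  structures, two deliberate out-of-bounds molecules and one invalid SMILES
  for negative tests. No identity with any experimentally tested compound
  set is claimed.
- A mock docking scorer: hash-seeded deterministic scores in [−12, −4]
  kcal/mol, independent-looking across conformations; used in tests and
  demos only.

What the generator does **not** emulate: real descriptor correlation
structure (QSAR descriptors are heavily collinear; the generator's columns
are independent), activity cliffs, assay noise and label error, class
imbalance drift between sources, and any true structure–activity coupling
(the synthetic IEs are label-conditioned, not structure-derived). Passing
tests therefore demonstrate that the machinery — labeling, pruning,
selection, training, filtering, clustering — behaves correctly and
recovers planted signal at realistic effect sizes; they do not certify
real-data predictive accuracy.

## Problem sizes and numerical choices

- The importance protocol's default is 2000 runs, but only the stability of
  the *mean* matters; the test suite and acceptance script use 200 runs
  with 25-tree forests (mtry = 10) on the 600 × 105 fixture, which already
  ranks all five planted descriptors in the top 10 across seeds.
- Model tests use reduced grids (e.g. *ntree* ∈ {25, 50, 100}, one or two
  cost points) on 200–600-molecule fixtures; the full default grids remain
  the library defaults.
- Sample standard deviations use ddof = 1 throughout; standardization
  round-trips to 1e−9.
- Quantiles use linear interpolation (the numpy default), matching the
  sort-based oracle in tests.
- Pearson r for pruning is computed on complete rows; an undefined r
  (constant column) never triggers a correlation removal — constants are
  the variance pruner's job.
- All randomness flows through explicit integer seeds; derived seeds are
  seed + k offsets.

## Known limitations

- Protonation at physiological pH is not modeled; molecules are used in
  neutral canonical form (a config hook accepts pre-protonated SMILES).
  Tautomers are not enumerated.
- The descriptor set is an open substitute, category-faithful but not
  numerically comparable to commercial descriptor packages; likewise the
  fingerprints substitute for proprietary ones (cutoffs kept as published).
- The absolute Gini importance scale depends on dataset size, so
  threshold-based selection does not transfer across datasets; use ranks.
- Docking adapters only build job specifications and parse output; no
  receptor preparation, heme parameterization or pose analysis.
- The exact McNemar test is conservative (discrete); with very few
  discordant pairs it has little power, which is the honest answer on small
  test sets.
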