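# Methods

This note documents the models and procedures implemented in `tastekit`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Problem setting

Four-class classification of compounds into bitter / sweet / umami / other
from 2D structure. The chemical space is heterogeneous (small organics,
natural products, peptides); the umami class is strongly under-represented
in available data, which drives two design elements: fold-internal
oversampling and recall-heavy objective weights.

## Curation

* Identity key: canonical SMILES of the standardized **parent** structure.
  Standardization = rdkit `MolStandardize` cleanup → largest-fragment
  parent (salt/solvate stripping) → uncharging. The operation is
  idempotent; findings are accumulated as issue flags, and an unparseable
  input receives a fatal flag instead of crashing the batch.
* Duplicates collapse to one record; a structure observed with *different*
  taste labels is removed entirely — a single-label classifier cannot learn
  from contradictory assignments, and keeping either label would inject
  noise at a rate the model cannot detect.
* Peptides (FASTA one-letter codes) become linear L-peptides with free
  termini. Stereochemistry is fixed to L because natural tastant peptides
  are L-configured; D-enantiomers are out of scope.
* PubChem-style name resolution is an optional callback; the core is
  network-free and treats an unresolved name as fatal.

## Descriptor catalogue (width 1613)

The catalogue covers the standard 2D families computable from the
hydrogen-suppressed molecular graph:

| family | width | notes |
|---|---:|---|
| autocorrelation ATS/AATS/ATSC/AATSC (lags 0–8), MATS/GATS (lags 1–8) | 624 | 12 atomic weightings: Gasteiger charge, valence degree, degree, intrinsic state, Z, mass, vdW volume, Sanderson/Pauling/Allred-Rochow electronegativity, polarizability, ionization energy |
| graph-matrix eigenspectra (SpAbs, SpMax, SpDiam, SpAD, SpMAD, LogEE, VE1–3, VR1–3) | 132 | adjacency, Laplacian, distance, and Barysz weighted-distance matrices under 8 weightings |
| rdkit physicochemical / topological / fragment set | 210 | `Descriptors.descList`, including BCUT2D |
| E-state atom types (count, sum, max, min × 79 types) | 316 | absent types give missing max/min — the dominant, structural source of missingness |
| CATS2D pharmacophore pair counts | 210 | 6 point types, topological lags 0–9 |
| Galvez charge indices GGI/JGI 1–10 + JGT10 | 21 | |
| ring counts (sizes 3–12 × any/aromatic/hetero/saturated/fused) | 50 | SSSR-based |
| distance-matrix indices (diameter, radius, Petitjean, ECCEN, Wiener, polarity, …) | 8 | |
| molecular quantum numbers | 42 | |

Conventions worth noting: descriptors operate on heavy atoms only (Gasteiger
hydrogen charges are folded into the bonded heavy atom); element constants
missing from the property tables propagate as NaN (missing), never 0;
`SpDiam` is the eigenvalue range, so a single-heavy-atom molecule has
`SpDiam_A = 0`; Moreau–Broto lag 0 is the sum of squared weights over atoms.

**Preprocessing.** Features with missing fraction strictly > 0.30 are
dropped (the strict inequality is deliberate: exactly 30% is kept).
Remaining gaps are imputed with kNN (k = 20, NaN-aware Euclidean distance
on mutually observed features, k capped at the available rows). Min–max
normalization to [0, 1] is fitted on the training table only; at apply time
out-of-range values are clipped and constant training features map to 0. A
query compound whose descriptor fails entirely maps to mid-range (0.5)
rather than aborting a batch prediction.

## Statistical screening

Kruskal–Wallis (tie-corrected, chi-square reference) across the four
classes per feature; Benjamini–Hochberg step-up q-values; selection at
q < 0.05. Shapiro–Wilk is computed as a diagnostic only — it motivates the
non-parametric route (the log-normal-like descriptor distributions fail it)
but never gates a feature. One-vs-rest Mann–Whitney p-values are reported
unadjusted because they feed a ranked top-5 report, not selection. PCA is
centered (not re-scaled: inputs are already on [0, 1]).

## Class balancing

Boosting-flavoured oversampling by *duplication* (no interpolation): each
minority class is topped up to the majority count by drawing members with
probability proportional to per-sample weights; a drawn sample's weight is
halved so copies spread across the class. Balancing happens inside each CV
fold on the training portion only; validation folds contain only original
samples (asserted by the test suite). No additional class weighting is
applied in the classifiers.

## Metrics

ACC plus support-weighted one-vs-rest F1, F2, precision, recall and
ROC-AUC; per-class tables accompany every aggregate. Weighted (not macro)
averaging was chosen because it makes aggregate recall coincide with
accuracy in the multi-class case, matching how this family of models is
conventionally reported. AUC on a single-class truth is undefined and
flagged, not silently 0 or 1.

## Evolutionary model construction

Genome = feature bit-mask ‖ family bit ‖ three real genes (tree-count
fraction, log10 C, log10 gamma). Defaults follow the published protocol of
this model family: population 100, 200 generations, two-point crossover
p = 0.9, arithmetic crossover p = 0, per-gene mutation p = 0.01, 10
independent runs, stratified 10-fold CV per evaluation, objective weights
1/10/10/1/1/10/1/1/1 (maximum scalar fitness 36).

Open points resolved here:

* **Selection operator** (unspecified): size-2 tournament on scalar
  fitness. **Elitism**: the current Pareto front survives unchanged
  (truncated to population size by fitness if needed), which makes best
  fitness non-decreasing.
* **Minimization objectives** are rescaled to [0, 1] maximizations:
  1 − n_selected/m for features, 1 − complexity/max for model size
  (max = tree-range upper bound for forests, training-set size for support
  vectors).
* **"Manhattan distance" objective** (named in the protocol but never
  defined): implemented as 1 − (mean L1 distance between out-of-fold
  class-probability vectors and the one-hot truth)/2 — the only
  distance-flavoured quantity computable per candidate from CV output that
  lies in [0, 1]. It is isolated in a single replaceable function
  (`evoselect.manhattan_score`).
* **Convergence** (mean within 5% of best) is recorded per generation as a
  diagnostic; stopping is always at `max_generations`.
* Evaluations are memoized by genome and seeded from the run
  configuration, so a candidate's score is a pure function of its genome —
  this also makes runs bit-reproducible.
* An empty feature mask is repaired (one random bit) and logged rather
  than rejected, so crossover cannot strand the search.

Final-model choice: maximum scalar fitness on the front ("knee"),
ties broken towards fewer features; `fewest_features`, `max_accuracy` and
explicit index are available for manual choice.

## Explanation

Exact path-dependent Tree-Shapley (polynomial recursion over decision
paths, cover-weighted conditional expectations) per class probability,
averaged over forest members; local accuracy (base + Σφ = predicted
probability) holds to ~1e-15 and is asserted. Non-tree models fall back to
seeded permutation-sampling Shapley and are flagged. Global importance =
mean over classes of mean |φ|, ties alphabetical. Feature correlation is
Pearson (the conventional choice for descriptor panels); attributions are
computed on the training table.

## Applicability domain

Morgan fingerprints (1024 bits, radius 2); query score = mean Tanimoto to
the 5 nearest training compounds ("10 quartiles" in the source protocol is
read as 10 equal-frequency deciles — a count of 10 cannot be quartiles).
When a training compound is scored against its own set, one
identity-fingerprint match is excluded. Degenerate binning (many identical
scores) merges bins and flags the report.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
log-normal base features (σ = 0.5 — skewed enough that Shapiro–Wilk rejects
normality in ≥95% of features at n ≥ 200, as with real descriptor tables);
correlated blocks of 5 features sharing a latent factor (ρ = 0.6); planted
informative features shifted per class in pooled-SD units; missing cells at
5% with two uninformative features pushed above the 30% threshold; class
sizes defaulting to the curated training set's imbalance (360/360/227/360).
Over-sparse columns are drawn from the uninformative pool so the planted
signal survives the sparsity filter — the generator states a world in which
recovery is possible, and the tests measure whether the pipeline achieves
it.

What a green synthetic test does **not** establish: real descriptor tables
have heavier inter-feature dependence, label noise from curation, and
chemistry-specific missingness patterns; absolute accuracies on synthetic
data say nothing about accuracy on curated taste data.

## Numerical and scale choices

* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical tables, splits, folds, populations and fronts.
* The planted-recovery acceptance test runs the search at its stated scale
  (population 30, 40 generations, 5 seeds, n = 60/class, 50 features) but
  uses 5-fold CV inside the evaluation instead of 10-fold to keep a desk
  run within minutes; the acceptance script similarly runs a reduced
  population/generation budget. Protocol-scale runs (pop 100 × 200
  generations × 10-fold × 10 runs) are a library call away but take hours
  on one CPU.
* SVM probabilities use pairwise-coupling calibration; random-forest and
  SVM complexity are measured as tree count and total support vectors.

## Known limitations

* The descriptor catalogue is an independent implementation of the
  standard 2D families at the published width; individual values are not
  numerically interchangeable with other descriptor engines (property
  tables, hashing and conventions differ), so models should always be
  applied to tables produced by this package.
* Published headline accuracies for this model family depend on a curated
  ~4700-compound dataset that is not redistributed here; nothing in this
  package asserts them.
* No 3D descriptors, no gradient-boosting/neural baselines, no web
  service; name resolution requires a user-supplied resolver.
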