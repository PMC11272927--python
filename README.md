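# tastekit

Machine-learning prediction of the taste of small molecules and peptides —
**bitter / sweet / umami / other** — from structure alone.

Taste perception drives food formulation, drug palatability and the search
for new sweeteners and umami compounds, but experimental tasting panels are
slow and expensive. `tastekit` implements a complete in-silico pipeline for
multi-class taste prediction from 2D molecular structure: compound curation,
descriptor computation, statistical feature screening, evolutionary
multi-objective model construction, Shapley-value explanation, and
applicability-domain scoring. It is aimed at cheminformaticians and
food-science researchers who want a tested, reproducible, scriptable
version of this class of taste predictor.

## The pipeline

1. **Curation** (`tastekit.chemio`) — compounds arrive as SMILES, InChI,
   SMARTS or peptide FASTA (auto-detected). Structures are cleaned,
   salt/solvate-stripped to the parent molecule and neutralized; duplicates
   collapse on canonical SMILES, and structures carrying conflicting taste
   labels are removed entirely. Training subsets are drawn per class
   (e.g. 360 sweet / 360 bitter / 227 umami / 360 other), the remainder
   forming an external test set.
2. **Descriptors** (`tastekit.descriptors`) — a 1613-wide catalogue of 2D
   descriptors per compound (topological autocorrelations ATS/ATSC/AATS/
   AATSC/MATS/GATS under 12 atomic weightings, graph-matrix eigenspectra
   including `SpDiam_A` and Barysz variants, E-state atom types, CATS2D
   pharmacophore pairs, Galvez charge indices, ring counts, MQNs, and the
   rdkit physicochemical set). Failed computations are *missing*, never
   zero. Features >30% missing are dropped, the rest kNN-imputed (k = 20)
   and min–max normalized to [0, 1] with parameters frozen on the training
   set.
3. **Screening** (`tastekit.statfilter`) — descriptor distributions are
   non-normal (Shapiro–Wilk diagnostic), so features are screened with the
   Kruskal–Wallis rank test across the four classes; Benjamini–Hochberg
   q < 0.05 selects the significant set. One-vs-rest Mann–Whitney tests
   rank the most class-discriminating features and PCA gives the
   3-component projection.
4. **Model construction** (`tastekit.evoselect` + `tastekit.modelkit`) — a
   Pareto-based genetic algorithm jointly picks the feature subset, the
   classifier family (random forest vs RBF-SVM) and its hyperparameters,
   scoring each candidate by stratified 10-fold cross-validation on nine
   objectives with weights

   | objective | w | objective | w | objective | w |
   |---|---|---|---|---|---|
   | fewer features | 1 | ACC | 10 | F1 | 10 |
   | F2 | 1 | precision | 1 | recall | 10 |
   | ROC-AUC | 1 | smaller model | 1 | Manhattan distance | 1 |

   The under-represented umami class is balanced inside each CV training
   fold by boosting-style weighted *copies* (e.g. 227 umami + 133 copies
   = 360); copies never reach a validation fold. The final model is chosen
   from the Pareto front (default: maximum weighted fitness, ties to fewer
   features).
5. **Explanation** (`tastekit.explain`) — exact path-dependent tree-Shapley
   attributions per class probability; features ranked by the mean over
   classes of mean |SHAP|; Pearson correlation of the selected features.
6. **Applicability domain** (`tastekit.applicability`) — a query's score is
   the mean Tanimoto similarity of its Morgan fingerprint (1024 bits,
   radius 2) to its 5 nearest training compounds; model performance is
   profiled across 10 similarity deciles.

## Worked example

Train a 95-tree random forest on the built-in labelled fixture set and
predict three compounds (one input is deliberately broken):

```python
import numpy as np
from tastekit import chemio
from tastekit.descriptors import compute_descriptors
from tastekit.modelkit import (ClassifierSpec, TastePredictor,
                               preprocess_raw_table, train)
from tastekit.synthetic import fixture_molecules

curated = chemio.deduplicate([chemio.standardize(r) for r in fixture_molecules()])
table = compute_descriptors(curated)                  # 26 x 1613
norm, params = preprocess_raw_table(table)
spec = ClassifierSpec("random_forest", {"n_trees": 95}, seed=0)
model = train(spec, norm.values, np.array([r.label for r in curated]))
predictor = TastePredictor(selected_features=norm.feature_names,
                           normalization=params, spec=spec, model=model,
                           metadata={"train_smiles": [r.canonical_smiles
                                                      for r in curated]})
predictor.save("fixture_model.joblib")
```

```bash
printf 'CCO\nCN1C=NC2=C1C(=O)N(C)C(=O)N2C\nNC(CCC(=O)O)C(=O)O\nC1CC\n' > query.txt
tastekit predict --input query.txt --model fixture_model.joblib --out pred.csv
# 3/4 compounds predicted -> pred.csv
```

`pred.csv` (abridged):

| id | canonical_smiles | predicted | p_bitter | p_other | p_sweet | p_umami | avg_top5 |
|----|------------------|-----------|---------:|--------:|--------:|--------:|---------:|
| cpd0 | CCO | other | 0.116 | 0.642 | 0.179 | 0.063 | 0.222 |
| cpd1 | Cn1c(=O)c2c(ncn2C)n(C)c1=O | bitter | 0.832 | 0.116 | 0.053 | 0.000 | 0.190 |
| cpd2 | NC(CCC(=O)O)C(=O)O | umami | 0.011 | 0.137 | 0.042 | 0.811 | 0.326 |
| cpd3 | *(unparseable — row flagged, run continues)* | | | | | | |

Ethanol lands in *other*, caffeine in *bitter* and glutamic acid in
*umami*; per-row probabilities sum to 1 and `avg_top5` is the
applicability-domain similarity to the training set.

The evolutionary search is available both as a library call
(`tastekit.evoselect.evolve`) and as `tastekit evolve ...`, which writes a
per-generation history, the Pareto front (feature names, family,
hyperparameters, nine objectives) and the selected model bundle. A
synthetic four-class dataset generator (`tastekit simulate`, with the
curated training set's class imbalance, log-normal features, correlated
blocks, missing values and a planted informative subset) makes every stage
testable without any external download.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch: fixture curation, full-width
descriptor computation, synthetic-data generation, preprocessing,
statistical screening, a (scaled-down) evolutionary model construction,
final-model training, Shapley feature ranking and applicability scoring,
then writes its results manifest to `--out`. All randomness derives from
`--seed`.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
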