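# qsprkit

A QSAR/QSPR model-training pipeline for drug-discovery data: from a raw
table of SMILES strings with experimental potencies (IC50/EC50-type values)
to a self-contained serialized predictor that maps a SMILES string to a
predicted molecular property or activity class.

## Who it is for

Computational and medicinal chemists who have a compound/potency table
(e.g. a ChEMBL extract) and want a reproducible, leakage-free
structure–activity model without hand-wiring RDKit, scikit-learn and a
hyperparameter optimizer for every project.

## What it does

The pipeline runs six stages end to end:

1. **Curation.** SMILES are canonicalized (stereo preserved) so all
   spellings of one structure share a key. Replicate measurements of one
   compound are checked for consistency: a group whose sample standard
   deviation on the nM scale exceeds a threshold (default 100 nM) is
   removed; the survivors are aggregated (mean/median/min/max) to one
   endpoint per compound. All removals are audited.
2. **Featurization.** Each molecule is described by physico-chemical
   descriptors (default panel: SLogP, SMR, naRing, nHBAcc, nHBDon, nRot,
   MW, TopoPSA), binary drug-likeness flags (Lipinski rule-of-five and
   Ghose filter), and a molecular fingerprint (Morgan, MACCS, atom-pair,
   topological-torsion or path-based).
3. **Scaling + PCA.** Columns are standardized on the training rows; the
   fingerprint block is compressed to its leading principal components.
   The reference recipe — 8 descriptors + 2 flags + 50 components of a
   1024-bit Morgan fingerprint — gives a 60-dimensional feature vector.
4. **Target transform.** Regression models are trained on
   pIC50/pEC50 = −log10(potency in molar); classification binarizes at a
   configured nM threshold, with ACTIVE (potency ≤ threshold) as the
   positive class.
5. **Model training.** Six model families (XGBoost, multilayer
   perceptron, SVM, random forest, ridge, bagging of trees) with
   declarative hyperparameter spaces; a budgeted sequential search
   (tree-structured Parzen estimator by default, pure random search as an
   alternative) minimizes the k-fold cross-validated MSE (regression) or
   1 − accuracy (classification). Scaling and PCA are refitted inside
   every fold, so no held-out information leaks into the transform. The
   winner is refit on the full training split (default 90% of the data).
6. **Evaluation + serialization.** Held-out metrics (accuracy, precision,
   recall/sensitivity, specificity, F1, ROC AUC, average precision,
   Matthews coefficient for classifiers; MSE in log units and the
   within-1-log-unit fraction for regressors), ROC curves and gain-based
   feature importances for tree models, and a single-file model artifact
   from which prediction needs nothing but a SMILES string.

A seeded synthetic-data module (`qsprkit.fixtures`) generates compound
tables with known ground truth — activities are an affine function of real
descriptors plus noise, with engineered replicate spread — so the whole
pipeline builds and tests without any external download.

## Worked example

```python
from qsprkit import QSPRModel, TrainingConfig, PipelineConfig
from qsprkit.fixtures import FixtureConfig, generate

raw, _ = generate(FixtureConfig(n_compounds=300, seed=11))
raw.to_csv("example.csv", index=False)

tcfg = TrainingConfig(task="regression", model_family="ridge",
                      hpo_max_evals=25, seed=11)
res = QSPRModel.from_csv("example.csv", tcfg, PipelineConfig()).fit()
print(res.summary())
```

prints

```
QSPR model fit
==========================================================
task:               regression
model family:       ridge
compounds curated:  282 (inconsistent removed: 18, invalid: 0)
train / test:       253 / 29
features:           60
search trials:      25 (best CV objective: 0.0472)
winning hyperparameters:
                 alpha = 0.3599915457652051
held-out performance:
                       MSE = 0.0546
  Fraction within 1 log unit = 1.0000
```

The 475 raw rows collapse to 282 curated compounds (18 replicate groups
were too inconsistent to keep); each molecule becomes a 60-number vector;
the best of 25 searched ridge models reaches a cross-validated MSE of
0.047 log² units and a held-out MSE of 0.055, with every test compound
predicted within one log unit. Prediction from structure alone:

```python
for p in res.predict(["CC(=O)Oc1ccccc1C(=O)O", "c1ccc2[nH]ccc2c1"]):
    print(p.input_smiles, "->", round(p.value, 3))
# CC(=O)Oc1ccccc1C(=O)O -> 3.907
# c1ccc2[nH]ccc2c1 -> 5.659
```

`res.save("model.qspr")` writes the self-contained artifact;
`ModelArtifact.load("model.qspr").predict_from_smiles([...])` runs
anywhere, with no access to the training data or configs.

The same pipeline is scriptable from the shell:

```sh
qspr fixtures --out raw.csv --truth truth.csv --seed 11
qspr curate   --in raw.csv --out curated.csv --audit audit.json
qspr train    --in raw.csv --training train.json --pipeline pipe.json \
              --out model.qspr --trials trials.csv
qspr predict  --model model.qspr --smiles-file probe.smi --out preds.csv
qspr evaluate --model model.qspr --test held_out.csv --out report.json --plots plots/
```

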