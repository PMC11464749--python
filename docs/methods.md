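# Methods

## The modelling problem

Given a table of molecules (SMILES) with experimental potency endpoints
(IC50/EC50-type concentrations, internally normalized to nM), the package
fits either a regression model of pIC50/pEC50 = −log10(concentration in
molar) or a binary activity classifier, and packages the entire fitted
data-processing chain into one artifact so that prediction requires only a
SMILES string.

## Curation model

Public bioactivity data typically contain several measurements per
compound from qualitatively different assays. Compound identity is the
RDKit canonical SMILES with stereochemistry preserved; salts are **not**
stripped by default (a `desalt` toggle keeps the largest fragment), and
multi-fragment structures are counted in the log. Replicate groups are
tested on the untransformed nM scale — the inconsistency threshold
(default 100 nM) is a concentration, so applying it after a log transform
would change its meaning. The spread statistic is the **sample** standard
deviation (n − 1 denominator), the usual estimator for replicate
measurements, and removal is **strict** (`SD > threshold`); both are
explicit knobs (`sd_kind`, `sd_strict`) since other conventions are
defensible. Singleton groups always pass. Surviving groups are aggregated
by mean (default), median, min or max. Curated output is sorted by
canonical SMILES and each group is summed in sorted order, making the
result bit-identical under any permutation of the input rows.

## Feature recipe

A molecule's feature vector is, in fixed order: the configured descriptors,
the drug-likeness flags, then the fingerprint block (principal components
`pc1..pck`, or raw bits when PCA is off).

* **Descriptors** (RDKit): SLogP and SMR (Crippen logP / molar
  refractivity), naRing, nHBAcc and nHBDon (Lipinski definitions), nRot,
  MW, TopoPSA. The registry is extensible at run time.
* **Drug-likeness flags** are zero-violation booleans, not violation
  counts: Lipinski = 1 iff MW ≤ 500, logP ≤ 5, HBD ≤ 5 and HBA ≤ 10;
  Ghose = 1 iff 160 ≤ MW ≤ 480, −0.4 ≤ logP ≤ 5.6, 40 ≤ MR ≤ 130 and the
  total atom count **including hydrogens** lies in 20–70 (the standard
  literature bounds; benzene, with 12 atoms counting hydrogens, fails).
* **Fingerprints**: Morgan (default radius 2 — the common ECFP4-like
  setting), MACCS keys (fixed 167-bit key set), atom-pair, topological
  torsion, or a hashed path-based fingerprint (paths of 1–7 bonds).
  Hashed families honor the configured bit length (default 1024).
* **Scaling** standardizes every column to zero mean and unit variance on
  the training rows; constant columns keep scale 1 and therefore map to
  exactly zero. Scaling of the fingerprint block before PCA is on by
  default and toggleable, since either convention is seen in practice.
* **PCA** is fitted on the (scaled) fingerprint block only — descriptors
  and flags pass through scaled but unprojected; this is the only
  composition consistent with a 60-wide reference vector (8 + 2 + 50).
  Loading signs are fixed by forcing each component's largest-magnitude
  loading positive, so serialized transforms reproduce across runs and
  BLAS builds. Fitting requires at least `pca_components + 1` rows.

## Targets

`to_plog` maps nM to −log10(molar): 1000 nM → 6.0, 1 nM → 9.0. For
classification, a compound is ACTIVE iff its endpoint is **at or below**
the threshold (ties are ACTIVE; the two representations agree:
endpoint ≤ t ⇔ plog ≥ plog(t)). ACTIVE is the positive class for every
reported measure.

## Model families and hyperparameter search

Registered families (regression / classification variants): XGBoost,
multilayer perceptron (one hidden layer, size searched), RBF-kernel SVM,
random forest, ridge (RidgeClassifier for classification) and bagging over
decision trees. Each family declares a conventional search space in
`modeling.HYPERPARAMETER_SPACES` (e.g. ridge α ∈ [1e-4, 1e3] log-uniform;
XGBoost depth 2–8, learning rate 1e-3–0.3 log-uniform); the spaces are
deliberately ordinary, not tuned to any dataset.

The search objective is the arithmetic mean over k folds (default k = 5)
of MSE (regression) or 1 − accuracy (classification), so both tasks share
a minimization contract. Classification folds are stratified, and every
fold's class proportions deviate from the global proportion by at most one
compound. Cross-validation inside the search refits the scaling/PCA
transform on each fold's training rows only, so fold-validation data never
influence the transform.

Two pluggable samplers share one interface: a pure random search and the
default **tree-structured Parzen estimator** (implemented in
`qsprkit.search`): after `n_startup = 10` random trials, finished trials
are split at the best γ = 25% by objective; each dimension's "good" and
"bad" observations are modelled as Parzen mixtures (Gaussian kernels with
bandwidth (range)/√(m+1) plus one uniform prior component; log-scaled
dimensions are modelled in log space; categoricals use +1-smoothed
frequencies); 24 candidates are drawn from the good density and the one
maximizing the summed log density ratio good/bad is evaluated next. The
budget (`hpo_max_evals`, default 100) is exact — exactly that many trials
are logged, failed fits included (recorded with an infinite objective; if
*all* trials fail the first underlying error is raised).

The holdout split (default 10% test) is made **once, before** the search —
stratified for classification, uniform for regression — and the final
model is refit on the full training split with the winning point.

Reproducibility: one master seed drives everything; stage seeds are
derived as `(seed · 1000003 + crc32(tag)) mod 2³¹` with tags `split`,
`cv`, `hpo`, `fold{k}`, `final`, so runs are bit-reproducible end to end.

## Evaluation

Classification measures are computed from the confusion counts with ACTIVE
positive; MCC uses the standard four-factor formula and returns 0 when any
denominator factor is zero (the common convention for degenerate
predictors). ROC AUC equals the Mann–Whitney pair statistic with ties
credited ½ (verified against trapezoidal curve area); average precision is
the step-wise precision–recall integral. The regression report gives MSE
in log units and the fraction of compounds within 1.0 log unit
(boundary inclusive). Predicted labels use the estimator's native
operating point (0.5 posterior for probabilistic models, 0 margin
otherwise); inference also returns the raw score so users can pick their
own cut. Feature importance is the tree ensemble's native gain-based
importance (averaged over members for bagging), normalized to sum to 1 and
reported as a descending list with a top-40 default view.

## Artifact format

One zip archive: `meta.json` (format version, both config snapshots,
resolved feature names, target transform, model family and winning
hyperparameters, creation metadata), `arrays.npz` (the fitted transform's
numeric state as explicit little-endian float64 blobs) and `model.joblib`
(the fitted estimator). The version integer is checked on load, and a
round-tripped artifact predicts bit-for-bit identically. Inference
canonicalizes each input, featurizes with the stored state and predicts;
invalid SMILES produce per-row failure markers, never a batch failure.

## Synthetic data generator

`qsprkit.fixtures` stands in for a real bioactivity extract. It draws
molecules from a packaged library of 1400 valid, chemically diverse SMILES
(enumerated substituted scaffolds — benzenes, azines, fused bicyclics,
saturated heterocycles, amides/sulfonamides — with frozen SLogP, TopoPSA
and MW columns so generation needs no chemistry toolkit), assigns true
activities

    pIC50 = 4.0 + 0.9·SLogP − 0.02·TopoPSA + N(0, σ),   σ = 0.2 by default,

(giving a realistic pIC50 spread of roughly 3–8 over the library) and
converts to nM endpoints. A configurable fraction of compounds (default
30%) receives 2–4 replicate rows whose *sample SD in nM is engineered
exactly*: consistent groups get an SD drawn below the curation threshold
(and small relative to the value, like assay noise); a chosen fraction
(default 20% of replicated compounds) gets an SD of 1.5–5× the threshold
and is recorded as `removed_inconsistent` in the ground truth. Because
activities are affine in descriptors the featurizer actually computes, the
signal is recoverable by construction and parameter-recovery tests are
meaningful.

What it does **not** emulate: assay heterogeneity beyond replicate spread,
censored/qualified values ("> 10000 nM"), activity cliffs, scaffold bias
between train and test, or the size and chemical diversity of a real
ChEMBL extract. Passing tests therefore demonstrate pipeline correctness
and signal recovery under controlled conditions, not expected performance
on real screening data.

## Problem sizes used in the test and acceptance runs

Unit and property tests run on toy matrices (≤ 20×10), ≤ 50-row curation
tables and 80–150-compound fixtures with reduced PCA (10–20 components)
and small search budgets (2–8 trials). The recovery benchmark is a
500-compound, σ = 0.2 fixture with the full 60-feature reference recipe
and a 20-trial ridge search; the budget-exactness check uses the default
100 trials on a 200-compound set; the split check uses 1000 compounds.

## Known limitations

* No applicability-domain estimation; predictions for molecules far from
  the training chemistry are silently extrapolated.
* No tautomer standardization and no assay-quality scoring; curation is
  purely the SD filter plus the audit trail.
* Qualified endpoint values are rejected at parse time rather than
  treated as censored observations.
* MLP training can hit its iteration cap on hard settings; such trials
  simply score poorly rather than being restarted.
* The TPE sampler models dimensions independently (no conditional or
  joint structure), which is adequate for the registered spaces.
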