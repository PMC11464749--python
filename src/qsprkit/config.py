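"""Configuration documents and compound-table ingestion.

Two JSON documents drive a run:

* the **training configuration** — endpoint curation thresholds, the
  aggregation strategy, the model family, cross-validation and
  hyperparameter-search budgets, the train/test split and the master seed;
* the **pipeline configuration** — which molecular descriptors and
  drug-likeness flags to compute, the fingerprint family and length, and
  the scaling / PCA settings.

Unspecified fields take the documented reference defaults (8 descriptors,
2 drug-like flags, 50 principal components of a 1024-bit Morgan
fingerprint, 100 nM inconsistency threshold, 5-fold CV, 100 search
evaluations, 90/10 split).

Compound tables are plain CSV with a SMILES column and a numeric endpoint
column (IC50/EC50-type potency). Endpoints are converted to nM on read.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from ._log import log_counts, stage_logger
from .errors import ConfigError, ValidationError

logger = stage_logger("config")

TASKS = ("regression", "classification")
AGGREGATIONS = ("mean", "median", "min", "max")
UNITS_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}
MODEL_FAMILIES = ("xgboost", "mlp", "svm", "random_forest", "ridge", "bagging")
FINGERPRINT_FAMILIES = (
    "morgan",
    "maccs",
    "atom_pair",
    "topological_torsion",
    "path_based",
)

#: Reference descriptor panel: computed logP and molar refractivity,
#: aromatic-ring / H-bond donor-acceptor / rotatable-bond counts,
#: molecular weight, topological polar surface area.
DEFAULT_DESCRIPTORS = (
    "SLogP",
    "SMR",
    "naRing",
    "nHBAcc",
    "nHBDon",
    "nRot",
    "MW",
    "TopoPSA",
)


@dataclass
class TrainingConfig:
    """Scalars governing curation, splitting, model choice and search budget."""

    task: str = "regression"
    inconsistency_sd_threshold: float = 100.0  # nM, on the untransformed scale
    aggregation: str = "mean"
    class_threshold: Optional[float] = None  # nM; required iff classification
    input_unit: str = "nM"
    model_family: str = "xgboost"
    cv_folds: int = 5
    hpo_max_evals: int = 100
    test_fraction: float = 0.10
    seed: int = 0
    # Column-name knobs for the compound CSV (matched case-insensitively).
    smiles_column: str = "smiles"
    value_column: str = "value"
    # Curation knobs left open by convention: sample SD with strict ">"
    # removal, no salt stripping.
    sd_kind: str = "sample"  # "sample" (n-1) or "population" (n)
    sd_strict: bool = True
    desalt: bool = False

    def validate(self) -> "TrainingConfig":
        v = []
        if self.task not in TASKS:
            v.append(f"task must be one of {TASKS}, got {self.task!r}")
        if self.aggregation not in AGGREGATIONS:
            v.append(f"aggregation must be one of {AGGREGATIONS}, got {self.aggregation!r}")
        if self.input_unit not in UNITS_TO_NM:
            v.append(f"input_unit must be one of {tuple(UNITS_TO_NM)}, got {self.input_unit!r}")
        if self.model_family not in MODEL_FAMILIES:
            v.append(f"model_family must be one of {MODEL_FAMILIES}, got {self.model_family!r}")
        if self.cv_folds < 2:
            v.append(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.hpo_max_evals < 1:
            v.append(f"hpo_max_evals must be >= 1, got {self.hpo_max_evals}")
        if not (0.0 < self.test_fraction < 1.0):
            v.append(f"test_fraction must lie in (0, 1), got {self.test_fraction}")
        if self.inconsistency_sd_threshold <= 0:
            v.append("inconsistency_sd_threshold must be positive")
        if self.task == "classification" and self.class_threshold is None:
            v.append("class_threshold is required when task=classification")
        if self.class_threshold is not None and self.class_threshold <= 0:
            v.append("class_threshold must be positive")
        if self.sd_kind not in ("sample", "population"):
            v.append(f"sd_kind must be 'sample' or 'population', got {self.sd_kind!r}")
        if v:
            raise ValidationError(v)
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class PipelineConfig:
    """Feature recipe: descriptors, drug-likeness flags, fingerprint, PCA."""

    descriptors: tuple = DEFAULT_DESCRIPTORS
    druglike_filters: tuple = ("lipinski", "ghose")
    fingerprint_family: str = "morgan"
    fingerprint_bits: int = 1024
    morgan_radius: int = 2
    scale: bool = True
    scale_fingerprint_before_pca: bool = True
    pca_components: int = 50

    def __post_init__(self):
        self.descriptors = tuple(self.descriptors)
        self.druglike_filters = tuple(self.druglike_filters)

    def validate(self) -> "PipelineConfig":
        from .featurize import DESCRIPTOR_REGISTRY, FILTER_NAMES

        v = []
        unknown = [d for d in self.descriptors if d not in DESCRIPTOR_REGISTRY]
        if unknown:
            v.append(f"unknown descriptors {unknown}; supported: {sorted(DESCRIPTOR_REGISTRY)}")
        bad = [f for f in self.druglike_filters if f not in FILTER_NAMES]
        if bad:
            v.append(f"unknown drug-like filters {bad}; supported: {sorted(FILTER_NAMES)}")
        if self.fingerprint_family not in FINGERPRINT_FAMILIES:
            v.append(
                f"fingerprint_family must be one of {FINGERPRINT_FAMILIES}, "
                f"got {self.fingerprint_family!r}"
            )
        if self.fingerprint_bits < 1:
            v.append("fingerprint_bits must be positive")
        if self.morgan_radius < 0:
            v.append("morgan_radius must be non-negative")
        if self.pca_components < 0:
            v.append("pca_components must be non-negative (0 disables PCA)")
        if self.pca_components > self.fingerprint_bits:
            v.append("pca_components must not exceed fingerprint_bits")
        if v:
            raise ValidationError(v)
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["descriptors"] = list(self.descriptors)
        d["druglike_filters"] = list(self.druglike_filters)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _load_document(path, cls, name):
    try:
        raw = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read {name} at {path}: {exc}") from exc
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{name} at {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{name} must be a JSON object, got {type(doc).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(f"{name} contains unrecognized key(s): {', '.join(unknown)}")
    return cls(**doc).validate()


def load_training_config(path) -> TrainingConfig:
    """Read and validate a training configuration JSON document.

    Missing fields take the reference defaults; an empty object ``{}`` is a
    fully defaulted configuration.
    """
    return _load_document(path, TrainingConfig, "training configuration")


def load_pipeline_config(path) -> PipelineConfig:
    """Read and validate a pipeline (feature recipe) JSON document."""
    return _load_document(path, PipelineConfig, "pipeline configuration")


@dataclass
class CompoundRecord:
    """One raw compound-table row: SMILES plus a positive endpoint in nM."""

    smiles_raw: str
    endpoint_nM: float
    assay_id: Optional[str] = None
    smiles_canonical: Optional[str] = None


@dataclass
class ReadAudit:
    """Row-level accounting for a compound-table read."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_nonnumeric: int = 0
    n_dropped_nonpositive: int = 0


def read_compound_table(path, training_config: TrainingConfig,
                        assay_column: str = "assay_id"):
    """Read a compound CSV into records, converting endpoints to nM.

    Returns ``(records, audit)``. Rows whose endpoint is missing,
    non-numeric or non-positive are dropped and counted in the audit; a
    missing mandatory column is fatal.
    """
    df = pd.read_csv(path)
    colmap = {c.lower(): c for c in df.columns}
    s_col = colmap.get(training_config.smiles_column.lower())
    v_col = colmap.get(training_config.value_column.lower())
    missing = []
    if s_col is None:
        missing.append(training_config.smiles_column)
    if v_col is None:
        missing.append(training_config.value_column)
    if missing:
        raise ConfigError(
            f"compound table {path} lacks required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    a_col = colmap.get(assay_column.lower())

    factor = UNITS_TO_NM[training_config.input_unit]
    audit = ReadAudit(n_rows=len(df))
    records = []
    values = pd.to_numeric(df[v_col], errors="coerce")
    for i, row in df.iterrows():
        val = values.loc[i]
        if pd.isna(val):
            audit.n_dropped_nonnumeric += 1
            continue
        if val <= 0:
            audit.n_dropped_nonpositive += 1
            continue
        records.append(
            CompoundRecord(
                smiles_raw=str(row[s_col]),
                endpoint_nM=float(val) * factor,
                assay_id=None if a_col is None else str(row[a_col]),
            )
        )
    audit.n_kept = len(records)
    log_counts(
        logger,
        "read compound table",
        rows=audit.n_rows,
        kept=audit.n_kept,
        dropped_nonnumeric=audit.n_dropped_nonnumeric,
        dropped_nonpositive=audit.n_dropped_nonpositive,
    )
    return records, audit
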