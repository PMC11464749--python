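"""High-level modelling interface: ``QSPRModel`` and ``QSPRResults``.

``QSPRModel`` is built from a raw compound table plus the two
configuration documents; ``fit()`` runs the full pipeline — curation,
featurization, a single up-front train/test split, budgeted
hyperparameter search under k-fold cross-validation (with scaling/PCA
refitted inside every fold), final training — and returns a
``QSPRResults`` carrying the winning hyperparameters, the trial log, the
held-out evaluation report and a self-contained prediction artifact.

    >>> model = QSPRModel.from_csv("table.csv", training_cfg, pipeline_cfg)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict(["CCO"])
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._log import stage_logger
from .artifact import ModelArtifact, build_metadata
from .config import (
    CompoundRecord,
    PipelineConfig,
    TrainingConfig,
    read_compound_table,
)
from .curation import CuratedDataset, curate
from .errors import ValidationError
from .evaluate import (
    ClassificationReport,
    FeatureImportanceReport,
    RegressionReport,
    ROCCurve,
    classification_metrics,
    feature_importance,
    regression_metrics,
    roc_and_ap,
)
from .featurize import FeatureSpec, build_blocks, fit_transform, subset_blocks
from .modeling import (
    TREE_FAMILIES,
    TrialRecord,
    get_space,
    optimize,
    split_train_test,
    train_final,
)
from .targets import TargetTransform
from .search import validate_point

logger = stage_logger("model")


class QSPRModel:
    """A SMILES→property model specification bound to training data."""

    def __init__(
        self,
        records: Sequence[CompoundRecord],
        training_config: TrainingConfig,
        pipeline_config: Optional[PipelineConfig] = None,
    ):
        self.records = list(records)
        self.training_config = training_config.validate()
        self.pipeline_config = (pipeline_config or PipelineConfig()).validate()

    @classmethod
    def from_csv(cls, path, training_config: TrainingConfig,
                 pipeline_config: Optional[PipelineConfig] = None) -> "QSPRModel":
        records, _ = read_compound_table(path, training_config)
        return cls(records, training_config, pipeline_config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, training_config: TrainingConfig,
                       pipeline_config: Optional[PipelineConfig] = None) -> "QSPRModel":
        """Build from a DataFrame with the configured SMILES/value columns
        (values in the configured input unit)."""
        from .config import UNITS_TO_NM

        factor = UNITS_TO_NM[training_config.input_unit]
        s_col = training_config.smiles_column
        v_col = training_config.value_column
        records = [
            CompoundRecord(smiles_raw=str(r[s_col]), endpoint_nM=float(r[v_col]) * factor)
            for _, r in df.iterrows()
            if pd.notna(r[v_col]) and float(r[v_col]) > 0
        ]
        return cls(records, training_config, pipeline_config)

    # ------------------------------------------------------------------

    def fit(self, search_strategy: str = "tpe") -> "QSPRResults":
        """Run the full training pipeline and return the results object."""
        tcfg, pcfg = self.training_config, self.pipeline_config
        curated = curate(self.records, tcfg)
        if not curated.records:
            raise ValidationError("no compounds survived curation")

        spec = FeatureSpec.from_config(pcfg)
        blocks = build_blocks(curated.smiles, pcfg)
        endpoint_by_smiles = dict(curated.records)
        endpoints = [endpoint_by_smiles[s] for s in blocks.smiles]

        target_transform = TargetTransform(
            task=tcfg.task, class_threshold_nM=tcfg.class_threshold
        )
        y = target_transform.apply(endpoints)

        train_idx, test_idx = split_train_test(
            y, tcfg.test_fraction, tcfg.seed, tcfg.task
        )
        train_blocks = subset_blocks(blocks, train_idx)
        test_blocks = subset_blocks(blocks, test_idx)
        y_train, y_test = y[train_idx], y[test_idx]

        def preprocess(tr, va):
            fold_train = subset_blocks(train_blocks, tr)
            t = fit_transform(fold_train, pcfg)
            return t.transform(fold_train), t.transform(subset_blocks(train_blocks, va))

        space = get_space(tcfg.model_family, tcfg.task)
        best, trials = optimize(
            space, None, y_train, tcfg, strategy=search_strategy,
            preprocess=preprocess,
        )

        fitted = fit_transform(train_blocks, pcfg)
        X_train = fitted.transform(train_blocks)
        trained = train_final(
            tcfg.model_family, best, X_train, y_train, tcfg.seed,
            spec.feature_names, tcfg.task,
        )

        artifact = ModelArtifact(
            training_config=tcfg,
            pipeline_config=pcfg,
            feature_spec=spec,
            fitted_transform=fitted,
            target_transform=target_transform,
            trained_model=trained,
            metadata=build_metadata(
                tcfg.seed, len(curated.records), len(train_idx), len(test_idx)
            ),
        )

        # Held-out evaluation.
        X_test = fitted.transform(test_blocks)
        roc = None
        importances = None
        if tcfg.task == "regression":
            pred = trained.predict(X_test, spec.feature_names)
            report = regression_metrics(y_test, pred)
        else:
            pred = trained.predict(X_test, spec.feature_names)
            scores = trained.predict_score(X_test, spec.feature_names)
            report = classification_metrics(y_test, pred, scores)
            roc, _ = roc_and_ap(y_test, scores)
        if tcfg.model_family in TREE_FAMILIES:
            importances = feature_importance(trained, spec.feature_names)

        return QSPRResults(
            model=self,
            curated=curated,
            artifact=artifact,
            params=dict(best),
            trials=trials,
            report=report,
            roc_curve=roc,
            importances=importances,
            train_index=train_idx,
            test_index=test_idx,
        )


@dataclass
class QSPRResults:
    """Fit outcome: estimates, trial log, held-out diagnostics, artifact."""

    model: QSPRModel
    curated: CuratedDataset
    artifact: ModelArtifact
    params: dict                      # winning hyperparameters
    trials: List[TrialRecord]
    report: object                    # RegressionReport | ClassificationReport
    roc_curve: Optional[ROCCurve] = None
    importances: Optional[FeatureImportanceReport] = None
    train_index: Optional[np.ndarray] = None
    test_index: Optional[np.ndarray] = None

    @property
    def best_objective(self) -> float:
        return min(t.mean_objective for t in self.trials)

    def predict(self, smiles_list: Sequence[str]):
        return self.artifact.predict_from_smiles(smiles_list)

    def save(self, path) -> None:
        self.artifact.save(path)

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {"trial": t.index, "mean_objective": t.mean_objective,
                   "error": t.error}
            row.update({f"hp_{k}": v for k, v in t.hyperparameters.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tcfg = self.model.training_config
        lines = [
            "QSPR model fit",
            "=" * 58,
            f"task:               {tcfg.task}",
            f"model family:       {tcfg.model_family}",
            f"compounds curated:  {len(self.curated.records)} "
            f"(inconsistent removed: {len(self.curated.removed_inconsistent)}, "
            f"invalid: {self.curated.removed_invalid})",
            f"train / test:       {len(self.train_index)} / {len(self.test_index)}",
            f"features:           {self.artifact.feature_spec.n_features}",
            f"search trials:      {len(self.trials)} "
            f"(best CV objective: {self.best_objective:.4f})",
            "winning hyperparameters:",
        ]
        for k, v in sorted(self.params.items()):
            lines.append(f"  {k:>20s} = {v}")
        lines.append("held-out performance:")
        for k, v in self.report.to_dict().items():
            if isinstance(v, float):
                lines.append(f"  {k:>24s} = {v:.4f}")
            else:
                lines.append(f"  {k:>24s} = {v}")
        return "\n".join(lines)
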