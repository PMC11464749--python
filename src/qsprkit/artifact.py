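"""Self-contained model artifacts: serialization and standalone inference.

An artifact bundles everything needed to go from a SMILES string to a
prediction: both configuration snapshots, the resolved feature spec, the
fitted scaling/PCA state, the target transform, the trained estimator and
creation metadata. It is a single zip archive holding

* ``meta.json`` — format version, configs, feature names, target
  transform, model family / winning hyperparameters, metadata;
* ``arrays.npz`` — the fitted transform's numeric state (``.npy`` blobs,
  endianness-tagged by the format itself);
* ``model.joblib`` — the fitted estimator.

The format version is checked on load, and a round-tripped artifact
predicts bit-for-bit identically to the original.
"""
from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np

from .config import PipelineConfig, TrainingConfig
from .curation import canonicalize
from .errors import ArtifactError, ContractError
from .featurize import FeatureSpec, FittedTransform, assemble
from .modeling import TrainedModel
from .targets import ACTIVE, INACTIVE, TargetTransform

FORMAT_VERSION = 1

_TRANSFORM_ARRAYS = (
    "desc_center", "desc_scale", "flag_center", "flag_scale",
    "fp_center", "fp_scale", "pca_mean", "pca_components",
    "pca_explained_variance",
)


@dataclass
class Prediction:
    """Per-SMILES inference outcome; ``status`` is 'ok' or an error note."""

    input_smiles: str
    canonical_smiles: Optional[str]
    value: Optional[float]  # plog (regression) or ACTIVE-class score
    label: Optional[str] = None  # classification only
    status: str = "ok"


@dataclass
class ModelArtifact:
    """The serialized-predictor bundle; sufficient for SMILES-only inference."""

    training_config: TrainingConfig
    pipeline_config: PipelineConfig
    feature_spec: FeatureSpec
    fitted_transform: FittedTransform
    target_transform: TargetTransform
    trained_model: TrainedModel
    metadata: dict

    def _require_complete(self):
        if not self.fitted_transform.fitted:
            raise ContractError("artifact transform is not fitted")
        if self.trained_model is None or self.trained_model.estimator is None:
            raise ContractError("artifact has no trained model")

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write the artifact archive; the in-memory object is untouched."""
        self._require_complete()
        meta = {
            "format_version": FORMAT_VERSION,
            "byte_order": "little",
            "training_config": self.training_config.to_dict(),
            "pipeline_config": self.pipeline_config.to_dict(),
            "feature_names": list(self.feature_spec.feature_names),
            "target_transform": self.target_transform.to_dict(),
            "model_family": self.trained_model.family,
            "task": self.trained_model.task,
            "hyperparameters": self.trained_model.hyperparameters,
            "n_train": self.trained_model.n_train,
            "metadata": self.metadata,
        }
        arrays = {}
        for name in _TRANSFORM_ARRAYS:
            val = getattr(self.fitted_transform, name)
            if val is not None:
                # Explicit little-endian float64 blobs.
                arrays[name] = np.ascontiguousarray(val, dtype="<f8")
        buf_npz = io.BytesIO()
        np.savez(buf_npz, **arrays)
        buf_model = io.BytesIO()
        joblib.dump(self.trained_model.estimator, buf_model)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            zf.writestr("arrays.npz", buf_npz.getvalue())
            zf.writestr("model.joblib", buf_model.getvalue())

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        """Read an artifact archive, checking the format version."""
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("meta.json"))
                version = meta.get("format_version")
                if version != FORMAT_VERSION:
                    raise ArtifactError(
                        f"artifact format version {version!r} is not the "
                        f"expected version {FORMAT_VERSION}"
                    )
                npz = np.load(io.BytesIO(zf.read("arrays.npz")))
                estimator = joblib.load(io.BytesIO(zf.read("model.joblib")))
        except ArtifactError:
            raise
        except (OSError, KeyError, zipfile.BadZipFile, json.JSONDecodeError) as exc:
            raise ArtifactError(f"cannot read artifact at {path}: {exc}") from exc

        tcfg = TrainingConfig(**meta["training_config"])
        pcfg = PipelineConfig(**meta["pipeline_config"])
        spec = FeatureSpec.from_config(pcfg)
        if tuple(meta["feature_names"]) != spec.feature_names:
            raise ArtifactError("stored feature names disagree with the recipe")
        transform = FittedTransform(config=pcfg)
        for name in _TRANSFORM_ARRAYS:
            if name in npz.files:
                setattr(transform, name, npz[name])
        transform.fitted = True
        model = TrainedModel(
            family=meta["model_family"],
            task=meta["task"],
            estimator=estimator,
            hyperparameters=meta["hyperparameters"],
            feature_names=spec.feature_names,
            n_train=meta["n_train"],
        )
        return cls(
            training_config=tcfg,
            pipeline_config=pcfg,
            feature_spec=spec,
            fitted_transform=transform,
            target_transform=TargetTransform.from_dict(meta["target_transform"]),
            trained_model=model,
            metadata=meta["metadata"],
        )

    # -- inference -----------------------------------------------------------

    def predict_from_smiles(self, smiles_list: Sequence[str]) -> List[Prediction]:
        """Canonicalize → featurize → predict, row-isolated.

        Regression yields plog values; classification yields a label plus
        the ACTIVE-class score. A bad SMILES produces a per-row failure
        marker, never a batch failure.
        """
        self._require_complete()
        out: List[Prediction] = [None] * len(smiles_list)
        canon, keep_idx = [], []
        for i, smi in enumerate(smiles_list):
            can = canonicalize(str(smi), desalt=self.training_config.desalt)
            if can is None:
                out[i] = Prediction(smi, None, None, status="invalid SMILES")
            else:
                canon.append(can)
                keep_idx.append(i)
        if not canon:
            return [p for p in out if p is not None]
        X, row_smiles, failed = assemble(canon, self.feature_spec, self.fitted_transform)
        failed_set = set(failed)
        ok_rows = [
            (i, c) for i, c in zip(keep_idx, canon) if c not in failed_set
        ]
        for i, c in zip(keep_idx, canon):
            if c in failed_set:
                out[i] = Prediction(smiles_list[i], c, None,
                                    status="featurization failed")
        if ok_rows:
            names = self.feature_spec.feature_names
            if self.target_transform.task == "regression":
                preds = self.trained_model.predict(X, names)
                for (i, c), p in zip(ok_rows, preds):
                    out[i] = Prediction(smiles_list[i], c, float(p))
            else:
                labels = self.trained_model.predict(X, names)
                scores = self.trained_model.predict_score(X, names)
                for (i, c), lab, sc in zip(ok_rows, labels, scores):
                    out[i] = Prediction(
                        smiles_list[i], c, float(sc),
                        label=ACTIVE if int(lab) == 1 else INACTIVE,
                    )
        return out


def build_metadata(seed: int, n_curated: int, n_train: int, n_test: int) -> dict:
    return {
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "n_curated": n_curated,
        "n_train": n_train,
        "n_test": n_test,
    }
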