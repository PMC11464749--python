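"""Model registry, cross-validated objective, and budgeted hyperparameter
optimization.

Six model families are registered, each in a regression and a
classification variant: gradient-boosted trees (XGBoost), multilayer
perceptrons, support vector machines, random forests, ridge models and
bagging ensembles of decision trees. For each family a conventional
default hyperparameter space is declared in ``HYPERPARAMETER_SPACES``.

The search objective is the k-fold cross-validated mean of MSE
(regression) or 1 − accuracy (classification), so both tasks minimize.
Classification folds are stratified. When a ``preprocess`` callback is
supplied, the feature transform (scaling/PCA) is refitted inside every
fold on that fold's training rows only, so no held-out information leaks
into the transform.

One master seed drives the split, the folds, the sampler and model
initialization through a documented derivation (seed + stage tag).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import (
    BaggingClassifier,
    BaggingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from xgboost import XGBClassifier, XGBRegressor

from ._log import log_counts, stage_logger
from .config import MODEL_FAMILIES, TrainingConfig
from .errors import ContractError, ValidationError
from .search import Categorical, Integer, Real, get_strategy, validate_point

logger = stage_logger("modeling")

TREE_FAMILIES = ("xgboost", "random_forest", "bagging")

HYPERPARAMETER_SPACES = {
    "ridge": {"alpha": Real(1e-4, 1e3, log=True)},
    "svm": {
        "C": Real(1e-2, 1e3, log=True),
        "gamma": Real(1e-4, 1e1, log=True),
    },
    "random_forest": {
        "n_estimators": Integer(50, 300),
        "max_depth": Integer(2, 16),
        "min_samples_leaf": Integer(1, 8),
        "max_features": Real(0.2, 1.0),
    },
    "xgboost": {
        "n_estimators": Integer(50, 300),
        "max_depth": Integer(2, 8),
        "learning_rate": Real(1e-3, 0.3, log=True),
        "subsample": Real(0.5, 1.0),
        "colsample_bytree": Real(0.5, 1.0),
        "reg_lambda": Real(1e-3, 10.0, log=True),
    },
    "mlp": {
        "hidden_layer_size": Integer(16, 128),
        "alpha": Real(1e-5, 1e-1, log=True),
        "learning_rate_init": Real(1e-4, 1e-2, log=True),
    },
    "bagging": {
        "n_estimators": Integer(10, 100),
        "max_samples": Real(0.5, 1.0),
    },
}


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage seed: mix the master seed with a stage tag."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def get_space(family: str, task: str) -> dict:
    if family not in HYPERPARAMETER_SPACES:
        raise ValidationError(
            f"unknown model family {family!r}; registered: {MODEL_FAMILIES}"
        )
    space = dict(HYPERPARAMETER_SPACES[family])
    if family == "svm" and task == "regression":
        space["epsilon"] = Real(1e-2, 1.0, log=True)
    return space


def make_model(family: str, hyperparameters: dict, seed: int,
               task: str = "regression"):
    """Instantiate an unfitted estimator for the family at the given point.

    The point is validated against the family's declared space.
    """
    space = get_space(family, task)
    validate_point(space, hyperparameters)
    hp = dict(hyperparameters)
    reg = task == "regression"
    if family == "ridge":
        return Ridge(**hp) if reg else RidgeClassifier(**hp)
    if family == "svm":
        return SVR(kernel="rbf", **hp) if reg else SVC(kernel="rbf", **hp)
    if family == "random_forest":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        return cls(random_state=seed, n_jobs=1, **hp)
    if family == "xgboost":
        cls = XGBRegressor if reg else XGBClassifier
        return cls(random_state=seed, n_jobs=1, verbosity=0, **hp)
    if family == "mlp":
        size = hp.pop("hidden_layer_size")
        cls = MLPRegressor if reg else MLPClassifier
        return cls(
            hidden_layer_sizes=(size,), random_state=seed, max_iter=500, **hp
        )
    if family == "bagging":
        base = DecisionTreeRegressor(random_state=seed) if reg else DecisionTreeClassifier(random_state=seed)
        cls = BaggingRegressor if reg else BaggingClassifier
        return cls(estimator=base, random_state=seed, n_jobs=1, **hp)
    raise ValidationError(f"unknown model family {family!r}")


def default_point(family: str, task: str, seed: int = 0) -> dict:
    """Mid-range point of the family's space (log-midpoint for log domains)."""
    point = {}
    for name, dom in get_space(family, task).items():
        if isinstance(dom, Real):
            if dom.log:
                point[name] = float(np.sqrt(dom.low * dom.high))
            else:
                point[name] = (dom.low + dom.high) / 2.0
        elif isinstance(dom, Integer):
            point[name] = (dom.low + dom.high) // 2
        else:
            point[name] = dom.choices[0]
    return point


def _folds(y: np.ndarray, cv_folds: int, task: str, seed: int):
    n = len(y)
    if n < cv_folds:
        raise ValidationError(f"need at least cv_folds={cv_folds} rows, got {n}")
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < cv_folds:
            raise ValidationError(
                f"smallest class has {counts.min()} members < cv_folds="
                f"{cv_folds}; use fewer folds"
            )
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(n), y)


def cross_validate(
    estimator_factory: Callable[[int], object],
    X: Optional[np.ndarray],
    y: np.ndarray,
    cv_folds: int,
    task: str,
    seed: int,
    preprocess: Optional[Callable] = None,
) -> np.ndarray:
    """Per-fold objective values: MSE (regression) or 1 − accuracy.

    ``estimator_factory(fold_seed)`` builds an unfitted estimator;
    ``preprocess(train_idx, valid_idx)``, when given, returns the fold's
    design matrices with any transform refitted on the fold-train rows.
    """
    y = np.asarray(y)
    objectives = []
    for k, (tr, va) in enumerate(_folds(y, cv_folds, task, seed)):
        if preprocess is not None:
            X_tr, X_va = preprocess(tr, va)
        else:
            X_tr, X_va = X[tr], X[va]
        est = estimator_factory(derive_seed(seed, f"fold{k}"))
        est.fit(X_tr, y[tr])
        pred = est.predict(X_va)
        if task == "regression":
            objectives.append(float(np.mean((pred - y[va]) ** 2)))
        else:
            objectives.append(float(np.mean(pred != y[va])))
    return np.array(objectives)


@dataclass
class TrialRecord:
    """One hyperparameter-search evaluation."""

    index: int
    hyperparameters: dict
    fold_objectives: List[float]
    mean_objective: float
    error: Optional[str] = None


def optimize(
    space: dict,
    X: Optional[np.ndarray],
    y: np.ndarray,
    training_config: TrainingConfig,
    strategy: str = "tpe",
    preprocess: Optional[Callable] = None,
) -> Tuple[dict, List[TrialRecord]]:
    """Budgeted sequential search over ``space``.

    Runs exactly ``hpo_max_evals`` trials; each trial's objective is the
    mean over ``cv_folds`` folds. Returns the minimizing point and the
    complete trial log. A trial whose fit fails is recorded with an
    infinite objective; if every trial fails the first failure is raised.
    """
    cfg = training_config
    sampler = get_strategy(strategy)
    rng = np.random.default_rng(derive_seed(cfg.seed, "hpo"))
    trials: List[TrialRecord] = []
    history: List[Tuple[dict, float]] = []
    first_failure = None
    for i in range(cfg.hpo_max_evals):
        params = sampler.suggest(rng, space, history)
        try:
            folds = cross_validate(
                lambda s: make_model(cfg.model_family, params, s, cfg.task),
                X, y, cfg.cv_folds, cfg.task, derive_seed(cfg.seed, "cv"),
                preprocess=preprocess,
            )
            rec = TrialRecord(i, params, list(folds), float(np.mean(folds)))
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - trial isolation
            if first_failure is None:
                first_failure = exc
            rec = TrialRecord(i, params, [], float("inf"), error=str(exc))
        trials.append(rec)
        history.append((params, rec.mean_objective))
    finite = [t for t in trials if np.isfinite(t.mean_objective)]
    if not finite:
        raise ContractError(
            f"all {len(trials)} trials failed to fit: {first_failure}"
        ) from first_failure
    best = min(finite, key=lambda t: t.mean_objective)
    log_counts(
        logger, "optimization finished",
        trials=len(trials), failed=len(trials) - len(finite),
    )
    logger.info("best mean objective %.6g at trial %d", best.mean_objective, best.index)
    return best.hyperparameters, trials


@dataclass
class TrainedModel:
    """A fitted estimator bound to its feature-name contract."""

    family: str
    task: str
    estimator: object
    hyperparameters: dict
    feature_names: Tuple[str, ...]
    n_train: int = 0

    def _check(self, feature_names: Sequence[str]):
        if tuple(feature_names) != tuple(self.feature_names):
            raise ContractError(
                "feature-name mismatch: model was trained on "
                f"{list(self.feature_names)[:5]}... ({len(self.feature_names)} "
                f"features), got {list(feature_names)[:5]}... "
                f"({len(feature_names)})"
            )

    def predict(self, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        self._check(feature_names)
        return np.asarray(self.estimator.predict(X))

    def predict_score(self, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        """Positive-class score: probability when available, otherwise the
        decision-function margin."""
        self._check(feature_names)
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(X))[:, 1]
        return np.asarray(self.estimator.decision_function(X))


def train_final(
    family: str,
    best_hyperparameters: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    feature_names: Sequence[str],
    task: str = "regression",
) -> TrainedModel:
    """Fit the winning point on the full training split."""
    est = make_model(family, best_hyperparameters, derive_seed(seed, "final"), task)
    est.fit(X, np.asarray(y))
    return TrainedModel(
        family=family,
        task=task,
        estimator=est,
        hyperparameters=dict(best_hyperparameters),
        feature_names=tuple(feature_names),
        n_train=len(y),
    )


def split_train_test(y: np.ndarray, test_fraction: float, seed: int,
                     task: str) -> Tuple[np.ndarray, np.ndarray]:
    """One up-front holdout split; stratified for classification."""
    idx = np.arange(len(y))
    stratify = y if task == "classification" else None
    tr, te = train_test_split(
        idx, test_size=test_fraction,
        random_state=derive_seed(seed, "split"), stratify=stratify,
    )
    return np.sort(tr), np.sort(te)
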