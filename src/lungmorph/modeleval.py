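"""Model families, hyperparameter search, and the metric suite.

Required families are the four tree ensembles — LightGBM, XGBoost, random
forest, AdaBoost — and a feedforward network (MLP); tabular-attention
("tabnet") and 1-D convolutional ("cnn1d") families are optional adapter slots
behind the same interface and are reported as skipped when no adapter is
registered.

Tuning maximises validation accuracy over the declared search space
(exhaustive grid or seeded random sampling).  Evaluation reports accuracy,
precision, recall, F1 and AUC on the test partition, the confusion matrix,
ROC points, and the wall-clock fit duration (logged only; hardware-dependent).
Binary metrics treat the larger class label as positive; multiclass metrics
are macro one-vs-rest, with classes absent from the truth excluded from the
macro mean and logged.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelEncoder

from .assemble import AssembledDataset

__all__ = [
    "SearchSpace",
    "Metrics",
    "RocResult",
    "TuneResult",
    "ModelReport",
    "EvalReport",
    "REQUIRED_FAMILIES",
    "OPTIONAL_FAMILIES",
    "default_spaces",
    "make_model",
    "tune",
    "classification_metrics",
    "roc_auc",
    "run_experiment",
]

logger = logging.getLogger(__name__)

REQUIRED_FAMILIES = ("lightgbm", "xgboost", "random_forest", "adaboost", "mlp")
OPTIONAL_FAMILIES = ("tabnet", "cnn1d")

#: registry for optional family adapters: family -> callable(params, seed) -> estimator
ADAPTERS: dict[str, object] = {}


@dataclass
class SearchSpace:
    """A declared hyperparameter space for one model family."""

    family: str
    grid: dict[str, list]
    strategy: str = "grid"  # "grid" (exhaustive) or "random" (seeded sampling)
    budget: int | None = None  # max trials; None = all configurations
    seed: int = 0

    def configurations(self) -> list[dict]:
        keys = sorted(self.grid)
        all_cfgs = [dict(zip(keys, vals))
                    for vals in itertools.product(*(self.grid[k] for k in keys))]
        if self.strategy == "grid":
            cfgs = all_cfgs
            if self.budget is not None:
                cfgs = cfgs[:self.budget]
        elif self.strategy == "random":
            rng = np.random.default_rng(self.seed)
            budget = min(self.budget or len(all_cfgs), len(all_cfgs))
            idx = rng.choice(len(all_cfgs), size=budget, replace=False)
            cfgs = [all_cfgs[i] for i in sorted(idx)]
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not cfgs:
            raise ValueError("empty search space")
        return cfgs


def default_spaces(strategy: str = "random", budget: int | None = 8,
                   seed: int = 0) -> dict[str, SearchSpace]:
    """The published candidate grids for the five required families.

    The AdaBoost boosting-variant axis is omitted: current scikit-learn
    implements only the discrete SAMME algorithm.
    """
    grids = {
        "lightgbm": {
            "num_leaves": [31, 64, 128, 256],
            "learning_rate": [0.01, 0.02, 0.04, 0.08, 0.1],
            "num_iterations": [100, 120, 140, 160, 180, 200],
            "max_bin": [255, 265, 275, 285, 300],
            "boosting_type": ["gbdt", "dart", "goss"],
        },
        "xgboost": {
            "eta": [0.01, 0.05, 0.1, 0.3],
            "max_depth": [3, 6, 10],
            "min_child_weight": [1, 3, 5, 10],
            "gamma": [0, 0.1, 0.5, 1],
            "subsample": [0.5, 0.7, 1],
            "colsample_bytree": [0.5, 0.7, 1],
            "lambda": [0, 0.1, 0.5, 1],
            "alpha": [0, 0.01, 0.1, 1],
        },
        "random_forest": {
            "n_estimators": [100, 150, 200],
            "max_depth": [5, 10, 20, 30, 50],
            "min_samples_split": [2, 5, 10, 20],
            "min_samples_leaf": [1, 2, 5, 10],
        },
        "adaboost": {
            "n_estimators": [50, 75, 100, 125, 150, 175, 200],
            "learning_rate": [0.01, 0.025, 0.05, 0.075, 0.1],
        },
        "mlp": {
            "hidden_layer_sizes": [(50, 50), (100, 100)],
            "max_iter": [100, 200, 300],
            "activation": ["relu", "tanh", "logistic"],
            "solver": ["adam", "sgd", "lbfgs"],
            "alpha": [0.0001, 0.001, 0.01, 0.1],
            "learning_rate_init": [0.01, 0.05, 0.1],
        },
    }
    return {fam: SearchSpace(family=fam, grid=g, strategy=strategy,
                             budget=budget, seed=seed)
            for fam, g in grids.items()}


class _LabelEncodedModel:
    """Wraps an estimator so fit/predict speak the task's own class labels."""

    def __init__(self, est):
        self.est = est
        self.le = LabelEncoder()

    def fit(self, X, y):
        self.est.fit(X, self.le.fit_transform(y))
        return self

    @property
    def classes_(self):
        return self.le.classes_

    def predict(self, X):
        return self.le.inverse_transform(np.asarray(self.est.predict(X)))

    def predict_proba(self, X):
        return self.est.predict_proba(X)


def make_model(family: str, params: dict, seed: int = 0):
    """Instantiate a classifier for a family with the given hyperparameters."""
    params = dict(params)
    if family == "lightgbm":
        import lightgbm as lgb

        n_iter = params.pop("num_iterations", 100)
        return _LabelEncodedModel(lgb.LGBMClassifier(
            n_estimators=n_iter, random_state=seed, n_jobs=1, verbose=-1,
            **params))
    if family == "xgboost":
        import xgboost as xgb

        eta = params.pop("eta", 0.3)
        lam = params.pop("lambda", 1)
        alpha = params.pop("alpha", 0)
        return _LabelEncodedModel(xgb.XGBClassifier(
            learning_rate=eta, reg_lambda=lam, reg_alpha=alpha,
            n_estimators=100, random_state=seed, n_jobs=1, **params))
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(random_state=seed, **params)
    if family in ADAPTERS:
        return ADAPTERS[family](params, seed)
    raise KeyError(f"no adapter registered for family {family!r}")


@dataclass
class TuneResult:
    family: str
    best_params: dict
    best_score: float
    trials: list[tuple[dict, float]]


def tune(space: SearchSpace, X_train, y_train, X_val, y_val,
         seed: int = 0) -> TuneResult:
    """Pick the configuration maximising validation accuracy.

    Deterministic given the space's strategy and seeds; ties go to the first
    configuration in enumeration order.  The full trial log is returned.
    """
    trials = []
    best, best_score = None, -np.inf
    for cfg in space.configurations():
        model = make_model(space.family, cfg, seed=seed)
        model.fit(X_train, y_train)
        score = float(np.mean(model.predict(X_val) == y_val))
        trials.append((cfg, score))
        if score > best_score:
            best, best_score = cfg, score
    return TuneResult(family=space.family, best_params=best,
                      best_score=best_score, trials=trials)


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: pd.DataFrame
    per_class: dict = field(default_factory=dict)


def classification_metrics(y_true, y_pred, classes=None) -> Metrics:
    """Accuracy, precision, recall and F1 from the confusion matrix.

    Binary tasks use the larger class label as positive.  Multiclass tasks
    report macro one-vs-rest averages; a class absent from ``y_true`` has
    undefined metrics, is excluded from the macro mean, and is logged.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(sorted(classes))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    accuracy = float(np.trace(cm) / cm.sum())
    per_class = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if cm[i, :].sum() == 0:
            logger.info("class %r absent from y_true; excluded from macro mean", c)
            per_class[c] = None
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1}
    if k == 2:
        pos = classes[-1]
        stats = per_class[pos]
        precision, recall, f1 = stats["precision"], stats["recall"], stats["f1"]
    else:
        defined = [v for v in per_class.values() if v is not None]
        precision = float(np.mean([v["precision"] for v in defined]))
        recall = float(np.mean([v["recall"] for v in defined]))
        f1 = float(np.mean([v["f1"] for v in defined]))
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    return Metrics(accuracy=accuracy, precision=float(precision),
                   recall=float(recall), f1=float(f1), confusion=confusion,
                   per_class=per_class)


@dataclass
class RocResult:
    auc: float
    curves: dict  # class label -> (fpr, tpr) arrays; "binary" for 2-class
    per_class_auc: dict = field(default_factory=dict)


def roc_auc(y_true, scores, classes=None) -> RocResult:
    """ROC points and trapezoidal AUC; macro one-vs-rest for multiclass.

    ``scores`` is the positive-class probability (binary, 1-D) or an
    (n, n_classes) probability matrix.  The trapezoidal AUC equals the rank
    statistic (probability that a random positive outscores a random negative,
    ties counted half).  Raises on a single-class truth vector.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(y_true)
    if uniq.size < 2:
        raise ValueError("AUC undefined for single-class y_true")
    if scores.ndim == 1:
        pos = uniq[-1] if classes is None else np.asarray(sorted(classes))[-1]
        fpr, tpr, _ = roc_curve(y_true == pos, scores)
        return RocResult(auc=float(np.trapezoid(tpr, fpr)),
                         curves={"binary": (fpr, tpr)})
    classes = np.asarray(sorted(classes if classes is not None else uniq))
    curves, aucs = {}, {}
    for i, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            logger.info("class %r one-sided in y_true; excluded from macro AUC", c)
            continue
        fpr, tpr, _ = roc_curve(mask, scores[:, i])
        curves[c] = (fpr, tpr)
        aucs[c] = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=float(np.mean(list(aucs.values()))), curves=curves,
                     per_class_auc=aucs)


@dataclass
class ModelReport:
    family: str
    chosen_params: dict | None
    metrics: Metrics | None
    roc: RocResult | None
    learning_duration_seconds: float | None
    skipped: bool = False
    reason: str = ""


@dataclass
class EvalReport:
    task: str
    models: dict[str, ModelReport]
    test_access_log: list[str] = field(default_factory=list)


def run_experiment(dataset: AssembledDataset, families=REQUIRED_FAMILIES,
                   spaces: dict[str, SearchSpace] | None = None,
                   feature_subset: list[str] | None = None,
                   seed: int = 0) -> EvalReport:
    """Tune, refit and evaluate each family once on the test partition.

    Per family: tune on train/validation, refit on train with the chosen
    configuration (the recorded learning duration is this fit only), then
    evaluate exactly once on test.  The test partition is touched once per
    family, recorded in ``test_access_log``.  Families without an adapter are
    reported as skipped.
    """
    if spaces is None:
        spaces = default_spaces(seed=seed)
    cols = feature_subset or dataset.feature_columns
    sub_cols = [c for c in cols if c in dataset.feature_columns]

    def design(part):
        s = dataset.subset(part)
        return s[sub_cols].to_numpy(float), s[dataset.label_column].to_numpy()

    X_tr, y_tr = design("train")
    X_val, y_val = design("validation")
    report = EvalReport(task=dataset.task, models={})
    X_te = y_te = None
    for fam in families:
        if fam not in spaces:
            if fam in OPTIONAL_FAMILIES and fam not in ADAPTERS:
                report.models[fam] = ModelReport(
                    family=fam, chosen_params=None, metrics=None, roc=None,
                    learning_duration_seconds=None, skipped=True,
                    reason="no adapter registered")
                continue
            raise KeyError(f"no search space declared for {fam!r}")
        try:
            make_model(fam, next(iter(spaces[fam].configurations()[:1]), {}),
                       seed=seed)
        except KeyError as exc:
            report.models[fam] = ModelReport(
                family=fam, chosen_params=None, metrics=None, roc=None,
                learning_duration_seconds=None, skipped=True, reason=str(exc))
            continue
        tuned = tune(spaces[fam], X_tr, y_tr, X_val, y_val, seed=seed)
        model = make_model(fam, tuned.best_params, seed=seed)
        t0 = time.perf_counter()
        model.fit(X_tr, y_tr)
        duration = time.perf_counter() - t0
        if X_te is None:
            X_te, y_te = design("test")
        report.test_access_log.append(fam)
        y_pred = model.predict(X_te)
        classes = np.unique(np.concatenate([y_tr, y_val]))
        metrics = classification_metrics(y_te, y_pred, classes=classes)
        proba = model.predict_proba(X_te)
        if proba.shape[1] == 2:
            roc = roc_auc(y_te, proba[:, 1], classes=classes)
        else:
            roc = roc_auc(y_te, proba, classes=classes)
        report.models[fam] = ModelReport(
            family=fam, chosen_params=tuned.best_params, metrics=metrics,
            roc=roc, learning_duration_seconds=duration)
    return report
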