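"""Level-1 models: per-endpoint random-forest classifiers with calibrated
decision thresholds, Cmax regressors, and the cross-endpoint predictivity
matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.experimental import enable_halving_search_cv  # noqa: F401
from sklearn.model_selection import (
    HalvingRandomSearchCV,
    StratifiedKFold,
    cross_val_predict,
)

from ._util import endpoint_seed, keyset_digest
from .data_model import EndpointDataset, Panel
from .evaluation import binary_report
from .featurization import FeatureBlock


@dataclass
class SearchSpace:
    """Hyperparameter ranges for the halving random search."""

    n_estimators: list[int] = field(default_factory=lambda: [100, 300, 500, 1000])
    max_depth: list[int | None] = field(default_factory=lambda: [None, 8, 16, 32])
    min_samples_leaf: list[int] = field(default_factory=lambda: [1, 3, 5, 10])
    max_features: list = field(default_factory=lambda: ["sqrt", 0.3, 0.5])
    class_weight: list = field(default_factory=lambda: [None, "balanced"])
    n_candidates: int = 16
    halving_factor: int = 2
    min_resources_divisor: int = 8  # initial budget = n_rows / this

    def __post_init__(self) -> None:
        for name in ("n_estimators", "max_depth", "min_samples_leaf", "max_features"):
            if not getattr(self, name):
                raise ValueError(f"empty range for {name}")

    def grid(self, classifier: bool) -> dict:
        g = {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "max_features": self.max_features,
        }
        if classifier:
            g["class_weight"] = self.class_weight
        return g

    @classmethod
    def fast(cls) -> "SearchSpace":
        """Small space for tests and smoke runs."""
        return cls(
            n_estimators=[100],
            max_depth=[None, 8],
            min_samples_leaf=[1, 3],
            max_features=["sqrt"],
            class_weight=[None],
            n_candidates=4,
        )


@dataclass
class EndpointModel:
    endpoint: str
    estimator: RandomForestClassifier | RandomForestRegressor
    threshold: float | None
    cv_config: dict
    training_digest: str
    training_keys: frozenset[str]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        is_clf = isinstance(self.estimator, RandomForestClassifier)
        if is_clf != (self.threshold is not None):
            raise ValueError("threshold must be present iff the model is a classifier")

    @property
    def is_classifier(self) -> bool:
        return isinstance(self.estimator, RandomForestClassifier)


def youden_threshold(probs, labels) -> float:
    """Probability cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive sorted unique
    probabilities, plus 0 and 1; a call is positive when prob >= threshold.
    Ties resolve to the smallest threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must align")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probs must be in [0, 1]")
    classes = set(np.unique(labels))
    if classes != {0, 1}:
        raise ValueError("labels must contain both classes")
    uniq = np.unique(probs)
    if len(uniq) == 1:
        warnings.warn("all probabilities identical; returning default threshold 0.5")
        return 0.5
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in candidates:
        calls = probs >= t
        tp = np.sum(calls & (labels == 1))
        tn = np.sum(~calls & (labels == 0))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    if best_j <= 1e-12:
        warnings.warn("no threshold improves over chance (J <= 0)")
    return best_t


def _search(
    base, space: SearchSpace, X: np.ndarray, y: np.ndarray, seed: int,
    scoring: str, stratified: bool
):
    n = len(y)
    min_res = max(space.min_resources_divisor * 2, n // space.min_resources_divisor)
    min_res = min(min_res, n)
    grid = space.grid(classifier=stratified)
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    if n_combos == 1:
        params = {k: v[0] for k, v in grid.items()}
        est = base.set_params(**params)
        est.fit(X, y)
        return est, params
    cv = (
        StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        if stratified
        else 5
    )
    search = HalvingRandomSearchCV(
        base,
        grid,
        n_candidates=min(space.n_candidates, n_combos),
        factor=space.halving_factor,
        resource="n_samples",
        min_resources=min_res,
        cv=cv,
        scoring=scoring,
        random_state=seed,
        refit=True,
        error_score=0.0,  # a failed tiny-fold fit scores worst, not fatal
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    return search.best_estimator_, search.best_params_


def train_endpoint_classifier(
    dataset: EndpointDataset,
    features: FeatureBlock,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> EndpointModel:
    """Halving random search with 5-fold stratified CV scored by AUC-ROC;
    the best configuration is refit on all rows.  The decision threshold is
    NOT set here (see :func:`youden_threshold` / caller protocols)."""
    if dataset.kind != "binary":
        raise ValueError("classifier requires a binary dataset")
    X = features.matrix
    y = dataset.labels()
    if X.shape[0] != len(y):
        raise ValueError("features must be row-aligned to the dataset")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        raise ValueError("each class needs at least as many members as CV folds")
    space = space or SearchSpace()
    sd = endpoint_seed(seed, dataset.name)
    base = RandomForestClassifier(random_state=sd, n_jobs=1)
    est, params = _search(base, space, X, y, sd, "roc_auc", stratified=True)
    est.random_state = sd
    est.fit(X, y)
    # threshold from 5-fold out-of-fold probabilities on the training data
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=sd)
    oof = cross_val_predict(est, X, y, cv=cv, method="predict_proba")[:, 1]
    thr = youden_threshold(oof, y)
    return EndpointModel(
        endpoint=dataset.name,
        estimator=est,
        threshold=thr,
        cv_config={"folds": 5, "seed": sd, "params": {k: str(v) for k, v in params.items()}},
        training_digest=keyset_digest(dataset.keys()),
        training_keys=frozenset(dataset.keys()),
        feature_names=list(features.feature_names),
    )


def train_cmax_regressor(
    dataset: EndpointDataset,
    features: FeatureBlock,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> EndpointModel:
    """Same search protocol with R^2 scoring; refit on all rows."""
    if dataset.kind != "numeric":
        raise ValueError("regressor requires a numeric dataset")
    y = dataset.labels()
    if len(y) < 20:
        raise ValueError("need at least 20 training rows for a Cmax regressor")
    if np.allclose(y, y[0]):
        warnings.warn("constant regression target; R^2 is undefined")
    X = features.matrix
    space = space or SearchSpace()
    sd = endpoint_seed(seed, dataset.name)
    base = RandomForestRegressor(random_state=sd, n_jobs=1)
    est, params = _search(base, space, X, y, sd, "r2", stratified=False)
    est.random_state = sd
    est.fit(X, y)
    return EndpointModel(
        endpoint=dataset.name,
        estimator=est,
        threshold=None,
        cv_config={"folds": 5, "seed": sd, "params": {k: str(v) for k, v in params.items()}},
        training_digest=keyset_digest(dataset.keys()),
        training_keys=frozenset(dataset.keys()),
        feature_names=list(features.feature_names),
    )


def predict_endpoint(
    model: EndpointModel, features: FeatureBlock
) -> tuple[np.ndarray, np.ndarray | None]:
    """Probabilities (or numeric predictions) plus binary calls at the
    model threshold.  A probability exactly at the threshold is positive."""
    if not hasattr(model.estimator, "estimators_"):
        raise ValueError("model is not fitted")
    if features.matrix.shape[0] == 0:
        return np.zeros(0), (np.zeros(0, dtype=int) if model.is_classifier else None)
    if features.feature_names != model.feature_names:
        raise ValueError("feature block does not match the model's features")
    if model.is_classifier:
        probs = model.estimator.predict_proba(features.matrix)[:, 1]
        calls = (probs >= model.threshold).astype(int)
        return probs, calls
    return model.estimator.predict(features.matrix), None


def train_panel_models(
    panel: Panel,
    featurize,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> dict[str, EndpointModel]:
    """Train one classifier per proxy endpoint and one regressor per PK
    target.  ``featurize(dataset) -> FeatureBlock`` supplies row-aligned
    features."""
    models: dict[str, EndpointModel] = {}
    for ds in panel.proxies:
        models[ds.name] = train_endpoint_classifier(ds, featurize(ds), space, seed)
    for ds in panel.pk:
        models[ds.name] = train_cmax_regressor(ds, featurize(ds), space, seed)
    return models


def cross_predict_matrix(
    models: dict[str, EndpointModel],
    panel: Panel,
    featurize,
) -> dict[str, dict[str, dict]]:
    """Endpoint-by-endpoint predictivity: model i predicts dataset j.

    Off-diagonal thresholds are re-derived against dataset j's labels (the
    best-case protocol); the diagonal reports 5-fold out-of-fold self-CV.
    """
    out: dict[str, dict[str, dict]] = {}
    datasets = {ds.name: ds for ds in panel.proxies}
    for name_i, model in models.items():
        if not model.is_classifier:
            continue
        out[name_i] = {}
        for name_j, ds_j in datasets.items():
            feats = featurize(ds_j)
            y = ds_j.labels()
            if name_i == name_j:
                cv = StratifiedKFold(5, shuffle=True, random_state=model.cv_config["seed"])
                probs = cross_val_predict(
                    model.estimator, feats.matrix, y, cv=cv, method="predict_proba"
                )[:, 1]
            else:
                if feats.feature_names != model.feature_names:
                    raise ValueError(
                        f"feature mismatch between model {name_i!r} and dataset {name_j!r}"
                    )
                probs = model.estimator.predict_proba(feats.matrix)[:, 1]
            thr = youden_threshold(probs, y)
            calls = (probs >= thr).astype(int)
            rep = binary_report(y, calls, probs)
            out[name_i][name_j] = {
                "auc_roc": rep.auc_roc,
                "f1": rep.f1,
                "lr_plus": rep.lr_plus,
                "lr_plus_infinite": rep.lr_plus_infinite,
                "threshold": thr,
            }
    return out


__all__ = [
    "SearchSpace",
    "EndpointModel",
    "youden_threshold",
    "train_endpoint_classifier",
    "train_cmax_regressor",
    "predict_endpoint",
    "train_panel_models",
    "cross_predict_matrix",
]
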