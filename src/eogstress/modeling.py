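"""Classifier harness: the five supervised models, their tuned defaults,
and a validation-split grid search.

The defaults are the tuned optima for each class scheme (two-class and
three-class); grid ranges used by the search bracket those optima. The
classifiers themselves are scikit-learn estimators — the contribution here
is the leakage-free harness: per-training-split standardization, Lasso
feature selection, and deterministic seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, LassoSelection, lasso_select

CLASSIFIERS = ("rf", "lr", "svm", "dt", "knn")

# Tuned hyperparameter optima per class scheme.
DEFAULT_HYPERPARAMETERS: dict[tuple[str, str], dict[str, Any]] = {
    ("rf", "two"): {"max_depth": 12, "n_estimators": 8, "criterion": "gini"},
    ("rf", "three"): {"max_depth": 14, "n_estimators": 6, "criterion": "gini"},
    ("lr", "two"): {"solver": "newton-cg", "max_iter": 75, "C": 0.05},
    ("lr", "three"): {"solver": "newton-cg", "max_iter": 65, "C": 0.03},
    ("svm", "two"): {"kernel": "linear", "max_iter": 80, "C": 0.1,
                     "decision_function_shape": "ovo"},
    ("svm", "three"): {"kernel": "linear", "max_iter": 70, "C": 0.5,
                       "decision_function_shape": "ovo"},
    ("dt", "two"): {"max_depth": 15, "criterion": "gini"},
    ("dt", "three"): {"max_depth": 20, "criterion": "gini"},
    ("knn", "two"): {"n_neighbors": 7, "metric": "minkowski", "weights": "distance"},
    ("knn", "three"): {"n_neighbors": 9, "metric": "minkowski", "weights": "distance"},
}

# Grid-search ranges bracketing the tuned optima. The iteration caps of the
# linear models extend to converged settings: a cap tuned on one dataset can
# leave the solver far from the optimum on another.
DEFAULT_GRIDS: dict[str, list[dict[str, Any]]] = {
    "rf": [
        {"max_depth": d, "n_estimators": n, "criterion": "gini"}
        for d in (8, 12, 16)
        for n in (6, 8, 16)
    ],
    "lr": [
        {"solver": "newton-cg", "max_iter": m, "C": c}
        for m in (75, 500)
        for c in (0.03, 0.05, 1.0)
    ],
    "svm": [
        {"kernel": "linear", "max_iter": m, "C": c, "decision_function_shape": "ovo"}
        for m in (80, 100_000)
        for c in (0.1, 0.5)
    ],
    "dt": [
        {"max_depth": d, "criterion": "gini"} for d in (5, 10, 15, 20, 25)
    ],
    "knn": [
        {"n_neighbors": k, "metric": "minkowski", "weights": "distance"}
        for k in (5, 7, 9, 11)
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """Classifier identity + hyperparameters + class scheme."""

    classifier: str  # rf | lr | svm | dt | knn
    class_scheme: str = "two"  # two | three
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.class_scheme not in ("two", "three"):
            raise ValueError("class_scheme must be 'two' or 'three'")

    @property
    def label_column(self) -> str:
        return "label2" if self.class_scheme == "two" else "label3"

    def resolved_hyperparameters(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS[(self.classifier, self.class_scheme)])
        params.update(self.hyperparameters)
        return params


def default_model_spec(classifier: str, class_scheme: str = "two",
                       random_seed: int = 0) -> ModelSpec:
    return ModelSpec(classifier=classifier, class_scheme=class_scheme,
                     random_seed=random_seed)


def build_estimator(classifier: str, params: dict[str, Any], seed: int = 0):
    """Instantiate the scikit-learn estimator for one grid point."""
    if classifier == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if classifier == "lr":
        return LogisticRegression(**params)
    if classifier == "svm":
        return SVC(random_state=seed, **params)
    if classifier == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if classifier == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown classifier {classifier!r}")


@dataclass
class TrainedModel:
    """Fitted classifier + the training-split preprocessing it depends on."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    selection: LassoSelection
    classes: list[str]
    metadata: dict = field(default_factory=dict)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from input: {missing}")
        Z = (X[self.feature_names].to_numpy(dtype=float) - self.scaler_mean) / self.scaler_sd
        return Z[:, self.selection.mask]


def identity_selection(feature_names: list[str]) -> LassoSelection:
    """A no-op selection keeping every feature."""
    k = len(feature_names)
    return LassoSelection(
        mask=np.ones(k, dtype=bool),
        coefficients=np.zeros(k),
        alpha=0.0,
        dropped_constant=[],
        feature_names=list(feature_names),
    )


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns pass through centred
    return mean, sd


def train(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    selection: LassoSelection | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit standardization, Lasso selection and the classifier on training rows only.

    Standardization statistics and the Lasso support are computed from the
    training split alone, so no test-set information can leak into the model.
    """
    feature_names = feature_names or FEATURE_NAMES
    y = np.asarray(y)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    Xv = X[feature_names].to_numpy(dtype=float)
    mean, sd = _fit_scaler(Xv)
    Z = (Xv - mean) / sd

    if selection is None:
        selection = lasso_select(
            pd.DataFrame(Xv, columns=feature_names), y, seed=spec.random_seed
        )
    mask = selection.mask
    if not mask.any():
        # empty Lasso support: fall back to all features so the model is usable
        mask = np.ones(len(feature_names), dtype=bool)
        selection = LassoSelection(
            mask=mask,
            coefficients=selection.coefficients,
            alpha=selection.alpha,
            dropped_constant=selection.dropped_constant,
            feature_names=feature_names,
        )

    est = build_estimator(
        spec.classifier, spec.resolved_hyperparameters(), seed=spec.random_seed
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # capped max_iter raises convergence noise
        est.fit(Z[:, mask], y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=feature_names,
        scaler_mean=mean,
        scaler_sd=sd,
        selection=selection,
        classes=classes,
        metadata={"seed": spec.random_seed, "n_train": len(y)},
    )


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict class labels; selection and standardization applied internally."""
    return model.estimator.predict(model.transform(X))


def grid_search(
    classifier: str,
    grid: list[dict[str, Any]] | None,
    X: pd.DataFrame,
    y: np.ndarray,
    class_scheme: str = "two",
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> dict[str, Any]:
    """Pick the grid point with the best held-out validation accuracy.

    10% of the training rows form the validation split (stratified); ties
    are broken by first occurrence in grid order.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[classifier]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y)
    idx_train, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=validation_fraction,
        random_state=seed,
        stratify=y,
    )
    names = list(X.columns)
    # tune on the full feature set: selection is a property of the final
    # model fit, and letting it vary across grid points would conflate the
    # two choices
    selection = identity_selection(names)
    best_params, best_acc = None, -1.0
    for params in grid:
        spec = ModelSpec(classifier=classifier, class_scheme=class_scheme,
                         hyperparameters=params, random_seed=seed)
        model = train(spec, X.iloc[idx_train], y[idx_train], selection=selection,
                      feature_names=names)
        acc = float(np.mean(predict(model, X.iloc[idx_val]) == y[idx_val]))
        if acc > best_acc:
            best_params, best_acc = params, acc
    assert best_params is not None
    return dict(best_params)
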