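"""Uniform fit/predict contract over the eight model families.

Families: k-nearest neighbours, linear models, decision tree, random
forest, gradient-boosted trees, the associative-graph lazy learner (MAGN),
and two convolutional-recurrent nets (LSTM and GRU cells).  Tabular
families consume the EMA feature table; the sequence families consume
lagged sequence samples.  Every family supports both tasks: regression on
the raw concentration and classification on the clinical classes
(regression output can additionally be post-categorized).

Hyperparameter defaults are this package's own desk-scale choices,
documented on :class:`ModelSpec`.
"""

from __future__ import annotations

import time
import tracemalloc
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from xgboost import XGBClassifier, XGBRegressor

from . import magn as magn_mod
from .features import SequenceDataset
from .metrics import CategoryScheme, categorize
from .nets import ConvRecurrentNet

__all__ = [
    "TABULAR_FAMILIES",
    "SEQUENCE_FAMILIES",
    "ALL_FAMILIES",
    "ModelSpec",
    "FittedModel",
    "make_model",
    "fit_predict",
    "split_xy",
]

TABULAR_FAMILIES = ("knn", "linear", "decision_tree", "random_forest", "boosted_trees", "magn")
SEQUENCE_FAMILIES = ("conv_lstm", "conv_gru")
ALL_FAMILIES = TABULAR_FAMILIES + SEQUENCE_FAMILIES

#: desk-scale hyperparameter defaults per family
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "knn": {"k": 5},
    "linear": {},
    "decision_tree": {"max_depth": None},
    "random_forest": {"n_estimators": 300, "max_depth": None},
    "boosted_trees": {"n_estimators": 200, "max_depth": 6, "learning_rate": 0.1},
    "magn": {"k": 5},
    "conv_lstm": {"conv_channels": 16, "hidden_units": 32, "epochs": 30, "lr": 3e-3},
    "conv_gru": {"conv_channels": 16, "hidden_units": 32, "epochs": 30, "lr": 3e-3},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: family, task, input mode, hyperparameters."""

    family: str
    task: str = "classification"  # or "regression"
    input_mode: str | None = None  # derived from family when None
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        mode = "sequence" if self.family in SEQUENCE_FAMILIES else "tabular"
        if self.input_mode is None:
            object.__setattr__(self, "input_mode", mode)
        elif self.input_mode != mode:
            raise ValueError(f"{self.family} requires {mode} input, got {self.input_mode}")

    @property
    def effective_hyperparams(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMS[self.family])
        hp.update(self.hyperparams)
        return hp


@dataclass
class FittedModel:
    """A trained handle: spec, opaque fitted state, importances, resources."""

    spec: ModelSpec
    state: object
    feature_names: list[str] | None = None
    fit_seconds: float = 0.0
    peak_memory_bytes: int = 0

    @property
    def feature_importances(self) -> pd.Series | None:
        """Impurity-based importances for the tree families, else None."""
        est = self.state
        if hasattr(est, "steps"):  # pipeline
            est = est.steps[-1][1]
        imp = getattr(est, "feature_importances_", None)
        if imp is None or self.feature_names is None:
            return None
        return pd.Series(np.asarray(imp, dtype=float), index=self.feature_names)


class _EncodedClassifier:
    """Label-encodes string classes for estimators that require integers."""

    def __init__(self, base):
        self.base = base
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        self.classes_, codes = np.unique(np.asarray(y, dtype=object), return_inverse=True)
        self.base.fit(X, codes)
        return self

    def predict(self, X):
        return self.classes_[np.asarray(self.base.predict(X), dtype=int)]

    @property
    def feature_importances_(self):
        return getattr(self.base, "feature_importances_", None)


class _MagnEstimator:
    """Adapter giving the associative graph the sklearn-style surface."""

    def __init__(self, task: str, k: int):
        self.task = task
        self.k = k
        self.graph = None
        self.columns: list[str] = []

    def fit(self, X: pd.DataFrame, y):
        rows = X.copy()
        rows["target"] = np.asarray(y)
        self.columns = list(X.columns)
        self.graph = magn_mod.magn_build(rows, target="target")
        return self

    def predict(self, X: pd.DataFrame):
        mode = "regression" if self.task == "regression" else "classification"
        out = [
            magn_mod.magn_predict(self.graph, dict(zip(self.columns, row)), k=self.k, mode=mode)
            for row in X[self.columns].itertuples(index=False, name=None)
        ]
        return np.asarray(out, dtype=float if mode == "regression" else object)


def make_model(spec: ModelSpec):
    """Instantiate an untrained estimator for a model spec."""
    hp = spec.effective_hyperparams
    reg = spec.task == "regression"
    if spec.family == "knn":
        est = (KNeighborsRegressor if reg else KNeighborsClassifier)(n_neighbors=hp["k"])
        return make_pipeline(StandardScaler(), est)
    if spec.family == "linear":
        if reg:
            return LinearRegression()
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=spec.seed)
        )
    if spec.family == "decision_tree":
        cls = DecisionTreeRegressor if reg else DecisionTreeClassifier
        return cls(max_depth=hp["max_depth"], random_state=spec.seed)
    if spec.family == "random_forest":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        return cls(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"], random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "boosted_trees":
        cls = XGBRegressor if reg else XGBClassifier
        est = cls(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        )
        return est if reg else _EncodedClassifier(est)
    if spec.family == "magn":
        return _MagnEstimator(task=spec.task, k=hp["k"])
    if spec.family in SEQUENCE_FAMILIES:
        return ConvRecurrentNet(
            cell="lstm" if spec.family == "conv_lstm" else "gru",
            task=spec.task,
            conv_channels=hp["conv_channels"],
            hidden_units=hp["hidden_units"],
            epochs=hp["epochs"],
            lr=hp["lr"],
            seed=spec.seed,
        )
    raise AssertionError(spec.family)


def split_xy(table: pd.DataFrame, task: str):
    """Feature matrix and target vector from an EMA feature table."""
    meta = [c for c in ("date", "year", "target", "target_class") if c in table.columns]
    X = table.drop(columns=meta)
    y = table["target"].to_numpy() if task == "regression" else table["target_class"].to_numpy()
    return X, y


def _sequence_xy(ds: SequenceDataset, task: str):
    # pollen lags become one channel aligned at the sequence end (zero-padded
    # over the embargoed last n days), meteo the other ten channels.
    n_samples, T = len(ds), ds.meteo.shape[1]
    pol = np.zeros((n_samples, T, 1))
    w = ds.pollen.shape[1]
    pol[:, 1 : 1 + w, 0] = ds.pollen  # days n+w-1 .. n before target
    X = np.concatenate([pol, ds.meteo], axis=2)
    y = ds.target if task == "regression" else ds.target_class
    return X, y


def _label_encode(y):
    return np.asarray(y, dtype=object)


def fit_predict(
    spec: ModelSpec,
    train,
    test,
    scheme: CategoryScheme | None = None,
) -> tuple[FittedModel, dict[str, np.ndarray]]:
    """Fit a model on the training split and predict the test split.

    ``train``/``test`` are feature tables (tabular families) or
    :class:`SequenceDataset` objects (sequence families).  Returns the
    fitted handle and a dict with ``prediction`` (task-native output) and,
    for regression with a scheme, ``class_prediction`` = categorized
    clipped concentrations.
    """
    if spec.input_mode == "tabular":
        if len(train) == 0:
            raise ValueError("empty training set")
        Xtr, ytr = split_xy(train, spec.task)
        Xte, _ = split_xy(test, spec.task)
        if list(Xtr.columns) != list(Xte.columns):
            raise ValueError("train/test schema mismatch")
        feature_names = list(Xtr.columns)
    else:
        if len(train) == 0:
            raise ValueError("empty training set")
        Xtr, ytr = _sequence_xy(train, spec.task)
        Xte, _ = _sequence_xy(test, spec.task)
        if Xtr.shape[1:] != Xte.shape[1:]:
            raise ValueError("train/test schema mismatch")
        feature_names = None

    model = make_model(spec)
    tracemalloc.start()
    t0 = time.perf_counter()
    model.fit(Xtr, ytr if spec.task == "regression" else _label_encode(ytr))
    fit_s = time.perf_counter() - t0
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()

    pred = model.predict(Xte)
    out: dict[str, np.ndarray] = {"prediction": pred}
    if spec.task == "regression":
        out["prediction"] = np.asarray(pred, dtype=float)
        if scheme is not None:
            out["class_prediction"] = categorize(np.clip(out["prediction"], 0, None), scheme)
    fitted = FittedModel(
        spec=spec,
        state=model,
        feature_names=feature_names,
        fit_seconds=fit_s,
        peak_memory_bytes=int(peak),
    )
    return fitted, out
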