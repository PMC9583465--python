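"""Uniform fit/score adapters for every classifier family in the benchmark.

Eight off-the-shelf learners (KNN, SVM, AdaBoost, RF, LGBM, XGB, LR, DT —
scikit-learn / lightgbm / xgboost) and the two bespoke evolutionary engines
(GP, GE) share one contract: ``fit(train, labels)`` then
``scores(test) -> continuous class-1 scores``.  Adapters never see test
labels.  Each family carries its hyperparameter grid for the nested-CV grid
search; SVM contributes raw decision values (no probability calibration),
the others class-1 probabilities.

The LGBM/XGB grids appear in the benchmark source with the estimator-count
and depth option lists swapped relative to the other ensembles; the default
grids here use the corrected orientation (estimators 10-400, depth 1-60),
with ``printed_grid`` preserving the original rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, export_text

from .gp_engine import EvolutionConfig, evolve
from .ge_engine import GEConfig, evolve_ge

__all__ = ["ClassifierSpec", "REGISTRY", "make_model", "fit_score",
           "DEFAULT_ALGORITHMS", "ALL_ALGORITHMS"]

#: Default experiment roster: nine score-producing families (the eight
#: standard learners plus GP as the evolutionary representative; GE is
#: registered and selectable in its place or in addition).
DEFAULT_ALGORITHMS = ["KNN", "SVM", "ADAB", "RF", "LGBM", "XGB", "LR", "DT", "GP"]
ALL_ALGORITHMS = DEFAULT_ALGORITHMS + ["GE"]

_ENSEMBLE_N = [10, 30, 60, 100, 200, 400]
_ENSEMBLE_DEPTH = [1, 2, 3, 4, 5, 10, 15, 30, 60]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family: its registry name and hyperparameter grid."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)

    def param_sets(self) -> list[dict]:
        """Cartesian product of the grid, in option-list order."""
        sets = [dict()]
        for key, options in self.grid.items():
            sets = [{**s, key: opt} for s in sets for opt in options]
        return sets

    def with_grid(self, grid: dict[str, list]) -> "ClassifierSpec":
        return ClassifierSpec(name=self.name, grid=grid)


REGISTRY: dict[str, ClassifierSpec] = {
    "KNN": ClassifierSpec("KNN", {"n_neighbors": [1, 3, 5, 7, 9, 11, 13]}),
    "SVM": ClassifierSpec("SVM", {"C": [1, 2, 5, 7, 10, 50, 100, 200, 400],
                                  "gamma": [0.001, 0.01, 0.05, 0.1, 1]}),
    "ADAB": ClassifierSpec("ADAB", {"n_estimators": _ENSEMBLE_N,
                                    "base_max_depth": _ENSEMBLE_DEPTH}),
    "RF": ClassifierSpec("RF", {"n_estimators": _ENSEMBLE_N,
                                "max_depth": _ENSEMBLE_DEPTH}),
    "LGBM": ClassifierSpec("LGBM", {"n_estimators": _ENSEMBLE_N,
                                    "max_depth": _ENSEMBLE_DEPTH}),
    "XGB": ClassifierSpec("XGB", {"n_estimators": _ENSEMBLE_N,
                                  "max_depth": _ENSEMBLE_DEPTH}),
    "LR": ClassifierSpec("LR", {"C": [0.001, 0.01, 0.1, 1, 10, 100, 1000]}),
    "DT": ClassifierSpec("DT", {"max_depth": [2, 3, 4, 5, 10, 50],
                                "criterion": ["gini", "entropy", "log_loss"],
                                "splitter": ["best", "random"]}),
    "GP": ClassifierSpec("GP", {"population_size": [100, 300, 500, 1000, 3000],
                                "generations": [20, 50, 100, 200],
                                "init_depth": [(2, 2), (2, 6)],
                                "tournament_size": [2, 7, 20]}),
    "GE": ClassifierSpec("GE", {"population_size": [100, 300, 500, 1000, 3000],
                                "generations": [50, 100, 200]}),
}


def printed_grid(name: str) -> dict[str, list]:
    """LGBM/XGB grids exactly as originally printed (rows swapped)."""
    if name not in ("LGBM", "XGB"):
        return dict(REGISTRY[name].grid)
    return {"n_estimators": list(_ENSEMBLE_DEPTH), "max_depth": list(_ENSEMBLE_N)}


class _SkModel:
    """Wrap a scikit-learn-style estimator under the uniform contract."""

    def __init__(self, est, use_decision: bool = False):
        self.est = est
        self.use_decision = use_decision
        self.expression: str | None = None
        self.importances: pd.Series | None = None
        self.weights: pd.Series | None = None

    def fit(self, train: pd.DataFrame, labels) -> "_SkModel":
        self.est.fit(train.to_numpy(dtype=float), np.asarray(labels))
        cols = list(train.columns)
        if isinstance(self.est, DecisionTreeClassifier):
            self.expression = export_text(self.est, feature_names=cols)
        if hasattr(self.est, "feature_importances_"):
            self.importances = pd.Series(self.est.feature_importances_, index=cols)
        if isinstance(self.est, LogisticRegression):
            self.weights = pd.Series(self.est.coef_[0], index=cols)
            self.importances = self.weights.abs()
        return self

    def scores(self, test: pd.DataFrame) -> np.ndarray:
        X = test.to_numpy(dtype=float)
        if self.use_decision:
            return np.asarray(self.est.decision_function(X), dtype=float)
        return np.asarray(self.est.predict_proba(X)[:, 1], dtype=float)


class _EvoModel:
    """GP/GE engines under the uniform contract."""

    def __init__(self, engine: str, params: dict, seed: int, dialect: str):
        self.engine = engine
        self.params = params
        self.seed = seed
        self.dialect = dialect
        self.model = None
        self.expression: str | None = None
        self.importances: pd.Series | None = None
        self.weights = None

    def fit(self, train: pd.DataFrame, labels) -> "_EvoModel":
        if self.engine == "GP":
            cfg = EvolutionConfig(seed=self.seed, **self.params)
            self.model = evolve(train, labels, cfg, dialect=self.dialect)
        else:
            cfg = GEConfig(seed=self.seed, **self.params)
            self.model = evolve_ge(train, labels, cfg, dialect=self.dialect)
        self.expression = self.model.expression
        used = self.model.tree.root.terminals()
        self.importances = pd.Series(
            [1.0 if c in used else 0.0 for c in train.columns], index=train.columns)
        return self

    def scores(self, test: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.model.score(test), dtype=float)


def make_model(name: str, params: dict | None = None, seed: int = 0,
               dialect: str = "arithmetic"):
    """Instantiate an unfitted model of a registered family.

    ``params`` must use the family's grid keys; ``dialect`` selects the
    expression family for GP/GE (arithmetic on normalized data, fuzzy on
    fuzzified data).
    """
    if name not in REGISTRY:
        raise ValueError(f"unknown algorithm {name!r}; known: {sorted(REGISTRY)}")
    params = dict(params or {})
    grid_keys = set(REGISTRY[name].grid)
    bad = set(params) - grid_keys
    if bad:
        raise ValueError(f"unknown hyperparameters for {name}: {sorted(bad)}")
    if name == "KNN":
        return _SkModel(KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 5)))
    if name == "SVM":
        return _SkModel(SVC(C=params.get("C", 1.0), gamma=params.get("gamma", "scale"),
                            kernel="rbf", random_state=seed), use_decision=True)
    if name == "ADAB":
        base = DecisionTreeClassifier(max_depth=params.get("base_max_depth", 1),
                                      random_state=seed)
        return _SkModel(AdaBoostClassifier(estimator=base,
                                           n_estimators=params.get("n_estimators", 50),
                                           random_state=seed))
    if name == "RF":
        return _SkModel(RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth"), random_state=seed))
    if name == "LGBM":
        from lightgbm import LGBMClassifier
        return _SkModel(LGBMClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", -1),
            random_state=seed, verbose=-1, min_child_samples=5))
    if name == "XGB":
        from xgboost import XGBClassifier
        return _SkModel(XGBClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 6),
            random_state=seed, verbosity=0, eval_metric="logloss"))
    if name == "LR":
        return _SkModel(LogisticRegression(C=params.get("C", 1.0), max_iter=2000,
                                           random_state=seed))
    if name == "DT":
        return _SkModel(DecisionTreeClassifier(
            max_depth=params.get("max_depth"),
            criterion=params.get("criterion", "gini"),
            splitter=params.get("splitter", "best"), random_state=seed))
    if name in ("GP", "GE"):
        return _EvoModel(name, params, seed, dialect)
    raise AssertionError(name)


def fit_score(spec: ClassifierSpec | str, train: pd.DataFrame, labels,
              test: pd.DataFrame, params: dict | None = None, seed: int = 0,
              dialect: str = "arithmetic") -> np.ndarray:
    """Fit one configuration on the training rows and score the test rows.

    Returns class-1 probabilities (or raw decision values for SVM) per test
    row; deterministic given ``seed``.
    """
    name = spec if isinstance(spec, str) else spec.name
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if list(train.columns) != list(test.columns):
        raise ValueError("train and test tables must share the same columns")
    model = make_model(name, params, seed=seed, dialect=dialect)
    model.fit(train, labels)
    return model.scores(test)
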