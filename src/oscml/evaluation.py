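"""Evaluation harness: univariate AUC, nested cross-validation, RFE, statistics.

Three experiments are supported, each run for two analyses (control vs.
sarcoidosis with normal spirometry; control vs. sarcoidosis with altered
spirometry) and two data representations (z-score-normalized crisp features;
fuzzified features):

1. univariate AUC of each of the 16 features;
2. nested cross-validation of every classifier family with exhaustive inner
   grid search — stratified 10-fold outer splits, per-fold train-only
   normalization/fuzzification, stratified 5-fold inner search by AUC, and a
   single pooled ROC/AUC over the concatenated outer test folds;
3. experiment 2 with recursive feature elimination, the number of surviving
   features treated as one more grid hyperparameter.

Feature selections are aggregated into a per-analysis selection-frequency
table (denominator: algorithms x outer folds), and absolute LR weights are
averaged across folds for the importance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .baselines import DEFAULT_ALGORITHMS, REGISTRY, ClassifierSpec, make_model
from .eric_fit import FEATURE_COLUMNS
from .eric_model import GROUP_ALTERED, GROUP_CONTROL, GROUP_NORMAL
from .fuzzify import fit_scheme, transform

__all__ = [
    "ANALYSES", "FoldResult", "NestedCVResult", "univariate_auc", "nested_cv",
    "rfe_path", "rfe_select", "default_rfe_options", "group_compare",
    "plan_experiment", "run_experiment1", "run_experiment", "selection_frequency",
    "lr_weight_average", "analysis_subset",
]

#: analysis id -> disease group compared against the control group
ANALYSES = {"normal": GROUP_NORMAL, "altered": GROUP_ALTERED}

N_OUTER_FOLDS = 10
N_INNER_FOLDS = 5


def analysis_subset(table: pd.DataFrame, analysis: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Rows and binary labels of one analysis from a table with a group column."""
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; known: {sorted(ANALYSES)}")
    groups = (GROUP_CONTROL, ANALYSES[analysis])
    sub = table[table["group"].isin(groups)]
    labels = (sub["group"] != GROUP_CONTROL).astype(int).to_numpy()
    return sub.drop(columns=["group"]), labels


def univariate_auc(values, labels) -> float:
    """Orientation-corrected rank AUC of a raw feature used as a score.

    Equals the normalized Mann-Whitney U statistic; orientation correction
    returns max(AUC, 1 - AUC) since a feature may separate in either
    direction.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    auc = roc_auc_score(labels, np.asarray(values, dtype=float))
    return float(max(auc, 1.0 - auc))


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Bookkeeping of one outer fold."""

    fold: int
    params: dict
    selected_features: list[str]
    test_index: np.ndarray
    test_labels: np.ndarray
    test_scores: np.ndarray
    inner_auc: float
    expression: str | None = None
    weights: pd.Series | None = None


@dataclass
class NestedCVResult:
    """Pooled outcome of a nested cross-validation run."""

    algorithm: str
    representation: str
    analysis: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([f.test_labels for f in self.folds])

    @property
    def pooled_scores(self) -> np.ndarray:
        return np.concatenate([f.test_scores for f in self.folds])

    @property
    def auc(self) -> float:
        """Single AUC over the concatenated outer test folds."""
        return float(roc_auc_score(self.pooled_labels, self.pooled_scores))

    def roc_points(self) -> pd.DataFrame:
        fpr, tpr, thr = roc_curve(self.pooled_labels, self.pooled_scores)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _transformers(representation: str):
    """(fit, apply) pair for a representation, fitted on training rows only."""
    if representation == "normalized":
        def fit(train: pd.DataFrame):
            return StandardScaler().fit(train.to_numpy(dtype=float)), list(train.columns)

        def apply(state, table: pd.DataFrame) -> pd.DataFrame:
            scaler, cols = state
            return pd.DataFrame(scaler.transform(table.to_numpy(dtype=float)),
                                index=table.index, columns=cols)
        return fit, apply
    if representation == "fuzzy":
        def fit(train: pd.DataFrame):
            return fit_scheme(train)

        def apply(scheme, table: pd.DataFrame) -> pd.DataFrame:
            return transform(scheme, table)
        return fit, apply
    raise ValueError(f"unknown representation {representation!r}")


def _dialect(representation: str) -> str:
    return "arithmetic" if representation == "normalized" else "fuzzy"


def _safe_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    if not np.all(np.isfinite(scores)) or np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(labels, scores))


def _inner_cv_auc(name: str, table: pd.DataFrame, labels: np.ndarray, params: dict,
                  seed: int, dialect: str, n_splits: int = N_INNER_FOLDS) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(table, labels):
        model = make_model(name, params, seed=seed, dialect=dialect)
        model.fit(table.iloc[tr], labels[tr])
        aucs.append(_safe_auc(labels[te], model.scores(table.iloc[te])))
    return float(np.mean(aucs))


def rfe_path(table: pd.DataFrame, labels: np.ndarray, name: str, params: dict,
             seed: int, dialect: str = "arithmetic",
             inner_folds: int = N_INNER_FOLDS) -> list[str]:
    """Backward-elimination order: first-removed feature first.

    At each round the feature whose removal least degrades the inner-CV AUC
    is dropped (ties resolved toward the later column).  The returned list
    has length ``n_columns - 1``; the last surviving feature is the one not
    listed.
    """
    cols = list(table.columns)
    order: list[str] = []
    while len(cols) > 1:
        best_auc = -np.inf
        victim = None
        for c in cols:  # later columns win ties via >=
            remaining = [x for x in cols if x != c]
            auc = _inner_cv_auc(name, table[remaining], labels, params, seed,
                                dialect, inner_folds)
            if auc >= best_auc:
                best_auc = auc
                victim = c
        order.append(victim)
        cols.remove(victim)
    return order


def rfe_select(table: pd.DataFrame, labels: np.ndarray, spec: ClassifierSpec | str,
               n_features: int, params: dict | None = None, seed: int = 0,
               dialect: str = "arithmetic") -> list[str]:
    """Backward elimination down to ``n_features`` surviving features."""
    total = table.shape[1]
    if not (1 <= n_features < total):
        raise ValueError(f"n_features must lie in [1, {total - 1}], got {n_features}")
    name = spec if isinstance(spec, str) else spec.name
    order = rfe_path(table, labels, name, params or {}, seed, dialect)
    eliminated = set(order[: total - n_features])
    return [c for c in table.columns if c not in eliminated]


def default_rfe_options(name: str, representation: str) -> list[int]:
    """Numbers of surviving features offered to the grid search.

    1-15 (crisp) / 1-47 (fuzzy) for the standard learners; the evolutionary
    engines get three options each for run-time reasons: {4, 8, 12} crisp,
    {12, 24, 36} fuzzy.
    """
    if name in ("GP", "GE"):
        return [4, 8, 12] if representation == "normalized" else [12, 24, 36]
    return list(range(1, 16)) if representation == "normalized" else list(range(1, 48))


def nested_cv(table: pd.DataFrame, labels, spec: ClassifierSpec | str,
              seed: int = 7, representation: str = "normalized",
              analysis: str = "", rfe_options: list[int] | None = None,
              n_outer: int = N_OUTER_FOLDS, inner_folds: int = N_INNER_FOLDS
              ) -> NestedCVResult:
    """Nested cross-validation of one classifier family.

    Stratified ``n_outer``-fold outer split; per outer fold the
    normalization (or fuzzification) is fitted on the outer-training rows
    only, hyperparameters are chosen by exhaustive stratified inner-CV grid
    search on AUC (ties to the first option in grid order), the model is
    refitted on the full outer-training fold and scored on the outer test
    fold.  With ``rfe_options`` a backward-elimination path is computed at
    the chosen hyperparameters and the surviving-feature count is selected
    along that path by inner-CV AUC.  The pooled ROC/AUC is computed once
    over all outer test folds.  All randomness derives from ``seed``.
    """
    spec = REGISTRY[spec] if isinstance(spec, str) else spec
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need two classes for nested cross-validation")
    dialect = _dialect(representation)
    fit_t, apply_t = _transformers(representation)
    result = NestedCVResult(algorithm=spec.name, representation=representation,
                            analysis=analysis)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(outer.split(table, labels)):
        y_tr, y_te = labels[tr], labels[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(f"outer fold {k} contains a single class; "
                             "cohort too small or too unbalanced for 10-fold CV")
        state = fit_t(table.iloc[tr])
        train = apply_t(state, table.iloc[tr])
        test = apply_t(state, table.iloc[te])

        param_sets = spec.param_sets()
        if len(param_sets) == 1:
            best_params, best_auc = param_sets[0], float("nan")
        else:
            best_params, best_auc = None, -np.inf
            for ps in param_sets:  # first option wins ties via strict >
                auc = _inner_cv_auc(spec.name, train, y_tr, ps, seed, dialect, inner_folds)
                if auc > best_auc:
                    best_auc, best_params = auc, ps

        selected = list(train.columns)
        if rfe_options:
            order = rfe_path(train, y_tr, spec.name, best_params, seed, dialect,
                             inner_folds)
            options = [n for n in rfe_options if 1 <= n <= train.shape[1]]
            best_n, best_n_auc = None, -np.inf
            for n in options:
                elim = set(order[: train.shape[1] - n]) if n < train.shape[1] else set()
                subset = [c for c in train.columns if c not in elim]
                auc = _inner_cv_auc(spec.name, train[subset], y_tr, best_params,
                                    seed, dialect, inner_folds)
                if auc > best_n_auc:
                    best_n_auc, best_n = auc, n
            elim = set(order[: train.shape[1] - best_n]) if best_n < train.shape[1] else set()
            selected = [c for c in train.columns if c not in elim]

        model = make_model(spec.name, best_params, seed=seed, dialect=dialect)
        model.fit(train[selected], y_tr)
        scores = model.scores(test[selected])
        result.folds.append(FoldResult(
            fold=k, params=best_params, selected_features=selected,
            test_index=np.asarray(te), test_labels=y_te, test_scores=scores,
            inner_auc=best_auc, expression=getattr(model, "expression", None),
            weights=getattr(model, "weights", None),
        ))
    return result


# ---------------------------------------------------------------------------
# Group-comparison statistics
# ---------------------------------------------------------------------------

def group_compare(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Shapiro-Wilk normality and two-sided Mann-Whitney tests per feature.

    Returns one row per feature with the per-group Shapiro p-values, the
    Mann-Whitney p-value and a significance flag at p <= 0.05.  A
    zero-variance feature is reported with p = 1 and flagged (no test is
    defined).  No multiple-testing correction is applied.
    """
    labels = np.asarray(labels)
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name in table.columns:
        a = table[name].to_numpy(dtype=float)[labels == 0]
        b = table[name].to_numpy(dtype=float)[labels == 1]
        degenerate = np.ptp(np.concatenate([a, b])) == 0
        if degenerate:
            rows.append({"feature": name, "shapiro_p_group0": np.nan,
                         "shapiro_p_group1": np.nan, "mannwhitney_p": 1.0,
                         "significant": False, "degenerate": True})
            continue
        sh0 = stats.shapiro(a).pvalue if np.ptp(a) > 0 else np.nan
        sh1 = stats.shapiro(b).pvalue if np.ptp(b) > 0 else np.nan
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": name, "shapiro_p_group0": float(sh0) if sh0 == sh0 else np.nan,
                     "shapiro_p_group1": float(sh1) if sh1 == sh1 else np.nan,
                     "mannwhitney_p": p, "significant": p <= 0.05,
                     "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------

def plan_experiment(experiment: int, representation: str,
                    algorithms: list[str] | None = None,
                    n_outer: int = N_OUTER_FOLDS) -> list[dict]:
    """Enumerate the sub-experiments of one experiment/representation.

    Experiment 1 has one entry per (analysis, feature); experiments 2 and 3
    one per (analysis, algorithm, outer fold) — 180 with the default
    nine-family roster.
    """
    if experiment == 1:
        return [{"experiment": 1, "analysis": a, "feature": f}
                for a in ANALYSES for f in FEATURE_COLUMNS]
    algorithms = algorithms if algorithms is not None else list(DEFAULT_ALGORITHMS)
    return [{"experiment": experiment, "analysis": a, "algorithm": alg,
             "fold": k, "representation": representation}
            for a in ANALYSES for alg in algorithms for k in range(n_outer)]


def run_experiment1(features: pd.DataFrame) -> pd.DataFrame:
    """Univariate AUC of every crisp feature, per analysis.

    ``features`` must carry the 16 feature columns plus ``group``.  Raw
    feature values are used directly as scores (no CV: a lone feature has
    no fitted parameters); orientation is corrected.
    """
    rows = []
    for analysis in ANALYSES:
        sub, labels = analysis_subset(features, analysis)
        for name in [c for c in sub.columns if c in FEATURE_COLUMNS]:
            rows.append({"analysis": analysis, "feature": name,
                         "auc": univariate_auc(sub[name], labels)})
    return pd.DataFrame(rows)


def run_experiment(features: pd.DataFrame, experiment: int = 2,
                   representation: str = "normalized",
                   algorithms: list[str] | None = None,
                   grids: dict[str, dict] | None = None,
                   rfe_options: dict[str, list[int]] | None = None,
                   seed: int = 7, n_outer: int = N_OUTER_FOLDS,
                   inner_folds: int = N_INNER_FOLDS) -> dict[str, dict[str, NestedCVResult]]:
    """Run experiment 2 (or 3, with feature selection) on a feature table.

    Parameters
    ----------
    features : DataFrame with the 16 crisp columns + ``group``.
    experiment : 2 or 3 (3 adds recursive feature elimination).
    algorithms : families to run; defaults to the nine-family roster.
    grids : per-family grid overrides (family -> grid dict).
    rfe_options : per-family overrides of the surviving-feature options.
    seed : global seed for folds and stochastic learners.

    Returns
    -------
    dict analysis -> algorithm -> NestedCVResult
    """
    if experiment not in (2, 3):
        raise ValueError("experiment must be 2 or 3")
    algorithms = algorithms if algorithms is not None else list(DEFAULT_ALGORITHMS)
    unknown = [a for a in algorithms if a not in REGISTRY]
    if unknown:
        raise ValueError(f"unknown algorithms {unknown}; known: {sorted(REGISTRY)}")
    results: dict[str, dict[str, NestedCVResult]] = {}
    for analysis in ANALYSES:
        sub, labels = analysis_subset(features, analysis)
        sub = sub[FEATURE_COLUMNS]
        results[analysis] = {}
        for name in algorithms:
            spec = REGISTRY[name]
            if grids and name in grids:
                spec = spec.with_grid(grids[name])
            opts = None
            if experiment == 3:
                opts = (rfe_options or {}).get(name,
                                               default_rfe_options(name, representation))
            results[analysis][name] = nested_cv(
                sub, labels, spec, seed=seed, representation=representation,
                analysis=analysis, rfe_options=opts, n_outer=n_outer,
                inner_folds=inner_folds)
    return results


def selection_frequency(results: dict[str, NestedCVResult],
                        feature_names: list[str]) -> pd.Series:
    """Percentage of sub-experiments (algorithm x fold) selecting each feature."""
    n = sum(len(r.folds) for r in results.values())
    counts = pd.Series(0.0, index=feature_names)
    for r in results.values():
        for f in r.folds:
            for c in f.selected_features:
                counts[c] += 1
    return 100.0 * counts / n


def lr_weight_average(result: NestedCVResult) -> pd.Series:
    """Across-fold average of absolute LR feature weights."""
    weights = [f.weights.abs() for f in result.folds if f.weights is not None]
    if not weights:
        raise ValueError("result has no stored weights (not an LR run?)")
    return pd.concat(weights, axis=1).mean(axis=1)
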