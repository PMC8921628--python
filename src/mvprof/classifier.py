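"""Training protocol: 60:20:20 split, random-search tuning, model choice.

Two tree-ensemble algorithms are supported — gradient boosting (xgboost)
and random forests (sklearn) — over three feature sets (all / functional /
computational).  Hyperparameters are tuned by random search scored by mean
10-fold cross-validated AUC on the training split; the best algorithm ×
feature-set combination is chosen by mean validation AUC over repeated
tuned runs; the chosen model is refit on train+validation (80%) and
evaluated exactly once on the sealed 20% test split.

The positive class is "D" (deleterious / functionally abnormal);
``predict`` returns D when the predicted probability reaches the decision
threshold (default 0.5, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from mvprof.metrics import ValidationReport, auc as rank_auc, confusion

Algorithm = Literal["gbm", "rf"]
ALGORITHM_ORDER = ("gbm", "rf")  # tie-break preference


@dataclass(frozen=True)
class SplitSpec:
    """The 60:20:20 train/validation/test design."""

    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class TuningConfig:
    """Random-search setup for one algorithm."""

    algorithm: Algorithm = "gbm"
    n_candidates: int = 50
    cv_folds: int = 10
    search: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.search != "random":
            raise ValueError("only random search is supported")
        if self.algorithm not in ALGORITHM_ORDER:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def split_data(
    labels: pd.Series, spec: SplitSpec
) -> tuple[list[str], list[str], list[str]]:
    """Partition labeled variant keys into train/validation/test.

    Validation and test each get floor(fraction·n) members; the remainder
    goes to training (1294 labeled variants → 778/258/258).  Stratification
    by label is on by default to stabilize the smaller class.
    """
    n = len(labels)
    if n < 10:
        raise ValueError("need at least 10 labeled variants to split")
    keys = np.asarray(labels.index)
    y = np.asarray(labels.values)
    n_test = int(np.floor(spec.test * n))
    n_val = int(np.floor(spec.validation * n))
    strat = y if spec.stratified else None
    rest_keys, test_keys, rest_y, _ = train_test_split(
        keys, y, test_size=n_test, stratify=strat, random_state=spec.seed
    )
    strat_rest = rest_y if spec.stratified else None
    train_keys, val_keys = train_test_split(
        rest_keys, test_size=n_val, stratify=strat_rest,
        random_state=spec.seed + 1,
    )
    return list(train_keys), list(val_keys), list(test_keys)


def _gbm_space() -> dict:
    # documented config default, not a claim about any published grid
    return {
        "max_depth": randint(2, 9),
        "learning_rate": loguniform(0.01, 0.3),
        "n_estimators": randint(100, 1001),
        "subsample": uniform(0.5, 0.5),
    }


def _rf_space() -> dict:
    return {
        "n_estimators": randint(100, 1001),
        "max_features": uniform(0.1, 0.8),
        "min_samples_leaf": randint(1, 11),
    }


class FunctionalityClassifier(BaseEstimator, ClassifierMixin):
    """Tuned tree-ensemble classifier of variant functionality.

    Parameters
    ----------
    algorithm : {"gbm", "rf"}
        Gradient boosting (xgboost) or random forest (sklearn).
    feature_set : str
        Identifier recorded for provenance ("all"/"functional"/
        "computational").
    n_candidates : int
        Random-search draws (each scored by ``cv_folds``-fold CV AUC).
    cv_folds : int
        Cross-validation folds during tuning.
    threshold : float
        Decision threshold on P(D); class D iff probability >= threshold.
    random_state : int
        Seed for the search, CV shuffling and the ensembles.

    Fitted attributes end with an underscore: ``best_params_``,
    ``cv_auc_``, ``model_``, ``classes_``, ``feature_names_in_``,
    ``importances_``.
    """

    def __init__(
        self,
        algorithm: Algorithm = "gbm",
        feature_set: str = "all",
        n_candidates: int = 50,
        cv_folds: int = 10,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.feature_set = feature_set
        self.n_candidates = n_candidates
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------
    def _base_estimator(self):
        if self.algorithm == "gbm":
            return XGBClassifier(
                tree_method="hist",
                eval_metric="logloss",
                n_jobs=1,
                random_state=self.random_state,
            )
        if self.algorithm == "rf":
            return RandomForestClassifier(
                n_jobs=1, random_state=self.random_state
            )
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @staticmethod
    def _encode(y: Sequence) -> np.ndarray:
        arr = np.asarray(y)
        enc = np.asarray([1 if v in ("D", 1, True) else 0 for v in arr])
        return enc

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: Sequence) -> "FunctionalityClassifier":
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        X = pd.DataFrame(X)
        yv = self._encode(y)
        if len(np.unique(yv)) < 2:
            raise ValueError("training labels contain a single class")
        space = _gbm_space() if self.algorithm == "gbm" else _rf_space()
        cv = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
        )
        search = RandomizedSearchCV(
            self._base_estimator(),
            space,
            n_iter=self.n_candidates,
            scoring="roc_auc",
            cv=cv,
            random_state=self.random_state,
            n_jobs=1,
            refit=True,
        )
        search.fit(X.to_numpy(), yv)
        self.model_ = search.best_estimator_
        self.best_params_ = dict(search.best_params_)
        self.cv_auc_ = float(search.best_score_)
        self.classes_ = np.asarray(["ND", "D"])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        raw = np.asarray(self.model_.feature_importances_, dtype=float)
        total = raw.sum()
        self.importances_ = pd.Series(
            raw / total if total > 0 else raw, index=list(X.columns)
        )
        return self

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return X[list(self.feature_names_in_)]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._check_columns(X)
        return self.model_.predict_proba(X.to_numpy())

    def decision_scores(self, X) -> np.ndarray:
        """P(deleterious) for each row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.where(p >= self.threshold, "D", "ND")

    def tune_threshold(self, X_val, y_val) -> float:
        """Pick the probability cutoff maximizing validation accuracy.

        Candidate cutoffs are midpoints between adjacent distinct
        validation scores; ties keep the cutoff closest to 0.5.
        """
        p = self.decision_scores(X_val)
        yv = self._encode(y_val)
        uniq = np.unique(p)
        cands = np.concatenate([[0.5], (uniq[1:] + uniq[:-1]) / 2.0])
        accs = [( (p >= c).astype(int) == yv).mean() for c in cands]
        best = max(zip(accs, -np.abs(cands - 0.5), cands))
        self.threshold = float(best[2])
        return self.threshold


def tune_and_train(
    X: pd.DataFrame, y: Sequence, cfg: TuningConfig, feature_set: str = "all"
) -> FunctionalityClassifier:
    """Random-search tuning + refit on all of the given training data."""
    clf = FunctionalityClassifier(
        algorithm=cfg.algorithm,
        feature_set=feature_set,
        n_candidates=cfg.n_candidates,
        cv_folds=cfg.cv_folds,
        random_state=cfg.seed,
    )
    return clf.fit(X, y)


@dataclass
class ModelComparison:
    """Validation metrics of repeated tuned runs per candidate model."""

    runs: list[dict] = field(default_factory=list)

    def add(self, algorithm: str, feature_set: str,
            auc_value: float, accuracy: float) -> None:
        self.runs.append(
            {"algorithm": algorithm, "feature_set": feature_set,
             "auc": auc_value, "accuracy": accuracy}
        )

    def mean_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs)
        return (
            df.groupby(["algorithm", "feature_set"])[["auc", "accuracy"]]
            .mean()
            .reset_index()
        )


def select_model(runs: ModelComparison) -> tuple[str, str]:
    """Argmax of mean validation AUC; ties by mean accuracy, then by
    algorithm preference order (gbm before rf)."""
    if not runs.runs:
        raise ValueError("no runs to select from")
    table = runs.mean_table()
    table["alg_rank"] = table["algorithm"].map(
        {a: i for i, a in enumerate(ALGORITHM_ORDER)}
    )
    table = table.sort_values(
        by=["auc", "accuracy", "alg_rank"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = table.iloc[0]
    return str(best["algorithm"]), str(best["feature_set"])


def compare_models(
    X: pd.DataFrame,
    y: pd.Series,
    train_keys: Sequence[str],
    val_keys: Sequence[str],
    candidates: Sequence[tuple[str, str]],
    n_runs: int = 10,
    n_candidates: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
    feature_groups: dict[str, list[str]] | None = None,
) -> ModelComparison:
    """Repeated tuned runs per (algorithm, feature_set), scored on the
    validation split."""
    comparison = ModelComparison()
    for algorithm, feature_set in candidates:
        cols = feature_groups[feature_set] if feature_groups else list(X.columns)
        for run in range(n_runs):
            cfg = TuningConfig(
                algorithm=algorithm, n_candidates=n_candidates,
                cv_folds=cv_folds, seed=seed + run,
            )
            clf = tune_and_train(
                X.loc[list(train_keys), cols], y.loc[list(train_keys)],
                cfg, feature_set,
            )
            scores = clf.decision_scores(X.loc[list(val_keys), cols])
            preds = clf.predict(X.loc[list(val_keys), cols])
            yv = y.loc[list(val_keys)]
            comparison.add(
                algorithm, feature_set,
                rank_auc(scores, list(yv)),
                float((preds == np.asarray(yv)).mean()),
            )
    return comparison


def finalize_and_test(
    X: pd.DataFrame,
    y: pd.Series,
    train_keys: Sequence[str],
    val_keys: Sequence[str],
    test_keys: Sequence[str],
    choice: tuple[str, str],
    n_candidates: int = 50,
    cv_folds: int = 10,
    seed: int = 0,
    feature_groups: dict[str, list[str]] | None = None,
) -> tuple[FunctionalityClassifier, ValidationReport]:
    """Refit the chosen model on train+validation, test once on the
    sealed test split."""
    algorithm, feature_set = choice
    cols = feature_groups[feature_set] if feature_groups else list(X.columns)
    fit_keys = list(train_keys) + list(val_keys)
    if set(fit_keys) & set(test_keys):
        raise ValueError("test keys leak into the fitting split")
    cfg = TuningConfig(
        algorithm=algorithm, n_candidates=n_candidates,
        cv_folds=cv_folds, seed=seed,
    )
    clf = tune_and_train(X.loc[fit_keys, cols], y.loc[fit_keys], cfg, feature_set)
    X_test = X.loc[list(test_keys), cols]
    y_test = y.loc[list(test_keys)]
    preds = clf.predict(X_test)
    scores = clf.decision_scores(X_test)
    cm = confusion(list(y_test), list(preds))
    report = ValidationReport.from_confusion(
        cm,
        auc_value=rank_auc(scores, list(y_test)),
        algorithm=algorithm,
        feature_set=feature_set,
        n_test=len(test_keys),
        best_params=clf.best_params_,
    )
    return clf, report


def predict_space(
    model: FunctionalityClassifier, X: pd.DataFrame
) -> pd.DataFrame:
    """Score every variant of a feature table.

    Returns a frame indexed by variant with columns probability (P(D)),
    class, feature_set and algorithm.
    """
    p = model.decision_scores(X)
    return pd.DataFrame(
        {
            "probability": p,
            "class": np.where(p >= model.threshold, "D", "ND"),
            "feature_set": model.feature_set,
            "algorithm": model.algorithm,
        },
        index=pd.DataFrame(X).index,
    )


def variable_importance(
    model: FunctionalityClassifier,
    groups: dict[str, list[str]] | None = None,
) -> pd.Series:
    """Normalized (sum-1) importances, optionally aggregated by source."""
    check_is_fitted(model, "importances_")
    imp = model.importances_
    if groups is None:
        return imp
    out = {
        name: float(imp.reindex(cols).fillna(0.0).sum())
        for name, cols in groups.items()
    }
    return pd.Series(out)
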