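"""Random-forest screening models and PCA quality control.

Two supervised tasks, both on TIC-normalized bucket matrices:

* classification of pure vs. syrup-adulterated honey, with case
  weights that equalize the contribution of the two classes (a cohort
  with five mixture levels per honey has five adulterated samples for
  every pure one);
* regression of the syrup volume fraction (percent v/v).

Forest configuration follows common ranger defaults: 5000 trees,
``mtry`` = rounded square root of the feature count, minimal node size
1 for classification and 5 for regression. Tree induction itself is
scikit-learn's; this module owns configuration, weighting, evaluation
and reporting. Classification performance is summarized the way
screening studies report it: out-of-bag (OOB) error on the training
cohort plus a per-proportion-level tally of correct test predictions.

Unsupervised structure is examined with column-centered (unscaled) PCA
of the first two components — on multi-device cohorts this is the plot
in which instrument identity, not adulteration, dominates the variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RfConfig",
    "ModelReport",
    "default_mtry",
    "class_weights",
    "CaseWeightedForest",
    "train_classifier",
    "predict_classes",
    "train_regressor",
    "evaluate_regression",
    "pca_scores",
    "PURE",
    "ADULTERATED",
]

#: Class codes; pure precedes adulterated so prediction ties resolve to pure.
PURE, ADULTERATED = 0, 1
CLASS_NAMES = {PURE: "pure", ADULTERATED: "adulterated"}


def default_mtry(p: int) -> int:
    """Default number of candidate features per split: round-half-up sqrt(p)."""
    if p < 1:
        raise ValueError("feature count must be >= 1")
    return int(math.floor(math.sqrt(p) + 0.5))


@dataclass
class RfConfig:
    """Random-forest settings.

    ``mtry`` and ``min_node_size`` default to None, meaning the task's
    standard defaults (sqrt(p); 1 for classification, 5 for regression).
    """

    num_trees: int = 5000
    mtry: int | None = None
    min_node_size: int | None = None
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = default_mtry(p) if self.mtry is None else self.mtry
        if not (1 <= m <= p):
            raise ValueError(f"mtry {m} outside [1, {p}]")
        return m


@dataclass
class ModelReport:
    """Evaluation summary of a fitted model (fields unused by a task stay None)."""

    oob_error: float | None = None  # percent
    test_accuracy: float | None = None  # percent
    per_level_confusion: dict[float, tuple[int, int]] | None = None  # level -> (correct, total)
    r_squared: float | None = None  # squared Pearson correlation (headline)
    r_squared_ss: float | None = None  # 1 - SS_res/SS_tot variant
    rmse: float | None = None  # percent v/v
    per_level_mae: dict[float, float] | None = None

    def confusion_table(self) -> str:
        """Human-readable tally: true proportion level vs correct/total."""
        if not self.per_level_confusion:
            return "(no test predictions)"
        lines = ["True proportion [%]\tCorrect predictions"]
        for level in sorted(self.per_level_confusion):
            c, t = self.per_level_confusion[level]
            lines.append(f"{level:g}\t{c}/{t}")
        return "\n".join(lines)


def class_weights(y: Sequence[int]) -> np.ndarray:
    """Per-sample case weights balancing the pure and adulterated classes.

    A sample of class k gets ``n_total / (2 * n_k)``, so the summed
    weight of each class is ``n_total / 2`` regardless of composition.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to balance them")
    n = y.size
    weights = np.empty(n, dtype=float)
    for k in classes:
        mask = y == k
        weights[mask] = n / (2.0 * mask.sum())
    return weights


def _as_array(X) -> np.ndarray:
    return X.values if hasattr(X, "values") else np.asarray(X)


class CaseWeightedForest:
    """Bagged classification trees with case-weighted bootstrap sampling.

    Case weights act on the bootstrap, not on the impurity: each tree is
    grown on a multinomial bootstrap whose per-sample inclusion
    probability is proportional to the sample's weight (the classic
    remedy for class imbalance — every tree sees roughly balanced
    classes). Samples drawn zero times by a tree are that tree's
    out-of-bag set; OOB class probabilities are averaged over the trees
    that did not see the sample. Tree induction is scikit-learn's;
    prediction ties resolve to the lowest class code (pure).
    """

    def __init__(self, n_estimators: int, max_features: int, min_samples_split: int, seed: int):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_split = min_samples_split
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray, case_weights: np.ndarray) -> "CaseWeightedForest":
        n = X.shape[0]
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        prob = np.asarray(case_weights, dtype=float)
        if np.any(prob < 0) or prob.sum() <= 0:
            raise ValueError("case weights must be nonnegative with positive sum")
        prob = prob / prob.sum()
        rng = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 7]))
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_estimators)
        self.estimators_ = []
        oob_votes = np.zeros((n, self.classes_.size))
        oob_counts = np.zeros(n)
        for ts in tree_seeds:
            counts = rng.multinomial(n, prob)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                min_samples_split=self.min_samples_split,
                random_state=int(ts),
            )
            tree.fit(X, y, sample_weight=counts.astype(float))
            self.estimators_.append(tree)
            oob = counts == 0
            if np.any(oob):
                oob_votes[oob] += tree.predict_proba(X[oob])
                oob_counts[oob] += 1
        with np.errstate(invalid="ignore"):
            self.oob_decision_function_ = oob_votes / oob_counts[:, None]
        self.oob_decision_function_[oob_counts == 0] = np.nan
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.estimators_:
            proba += tree.predict_proba(X)
        return proba / len(self.estimators_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(
    X, y: Sequence[int], cfg: RfConfig = RfConfig(), case_weights: np.ndarray | None = None
) -> tuple[CaseWeightedForest, ModelReport]:
    """Fit the pure-vs-adulterated forest and report its OOB error.

    ``y`` holds the class codes :data:`PURE` / :data:`ADULTERATED`. If
    ``case_weights`` is None, balancing weights from
    :func:`class_weights` are used. The reported OOB error is the
    unweighted fraction of misclassified out-of-bag votes, in percent.
    """
    Xa, ya = _as_array(X), np.asarray(y)
    if np.unique(ya).size < 2:
        raise ValueError("training data contains a single class")
    if case_weights is None:
        case_weights = class_weights(ya)
    model = CaseWeightedForest(
        n_estimators=cfg.num_trees,
        max_features=cfg.resolve_mtry(Xa.shape[1]),
        min_samples_split=(cfg.min_node_size or 1) + 1,
        seed=cfg.seed,
    ).fit(Xa, ya, np.asarray(case_weights, dtype=float))
    valid = ~np.isnan(model.oob_decision_function_).any(axis=1)
    oob_pred = model.classes_[
        np.argmax(np.nan_to_num(model.oob_decision_function_), axis=1)
    ]
    report = ModelReport(
        oob_error=100.0 * float(np.mean(oob_pred[valid] != ya[valid]))
    )
    return model, report


def predict_classes(
    model: CaseWeightedForest, X_test, proportions: Sequence[float]
) -> tuple[np.ndarray, dict[float, tuple[int, int]]]:
    """Predict test samples and tally correctness per true proportion level.

    ``proportions`` are the true percent-v/v levels of the test samples
    (0 = pure); the true class is derived from them. Returns the
    predicted class codes and a ``level -> (n correct, n total)`` map
    whose totals sum to the test-set size.
    """
    Xa = _as_array(X_test)
    if Xa.shape[1] != model.n_features_in_:
        raise ValueError(
            f"test matrix has {Xa.shape[1]} columns, model expects {model.n_features_in_}"
        )
    y_pred = model.predict(Xa)
    tally: dict[float, tuple[int, int]] = {}
    for level in sorted(set(float(p) for p in proportions)):
        mask = np.asarray(proportions, dtype=float) == level
        truth = PURE if level == 0 else ADULTERATED
        correct = int(np.sum(y_pred[mask] == truth))
        tally[level] = (correct, int(mask.sum()))
    return y_pred, tally


def train_regressor(X, y: Sequence[float], cfg: RfConfig = RfConfig()) -> RandomForestRegressor:
    """Fit the syrup-proportion forest (min node size 5 by default)."""
    Xa, ya = _as_array(X), np.asarray(y, dtype=float)
    if np.unique(ya).size < 2:
        raise ValueError("regression target is constant")
    model = RandomForestRegressor(
        n_estimators=cfg.num_trees,
        max_features=cfg.resolve_mtry(Xa.shape[1]),
        min_samples_split=max(cfg.min_node_size or 5, 2),
        bootstrap=True,
        oob_score=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(Xa, ya)
    return model


def evaluate_regression(
    model: RandomForestRegressor, X_test, y_test: Sequence[float]
) -> ModelReport:
    """Evaluate proportion predictions on held-out samples.

    The headline coefficient of determination is the squared Pearson
    correlation between predicted and true proportions (invariant to an
    affine miscalibration); the ``1 - SS_res/SS_tot`` variant is also
    reported. RMSE and the mean absolute error at each true level are
    in percent v/v. Zero-variance predictions make the correlation
    undefined; it is reported as 0 with a warning.
    """
    import warnings

    y_true = np.asarray(y_test, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(_as_array(X_test))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        warnings.warn("degenerate predictions or targets; Pearson R^2 reported as 0")
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y_pred, y_true)[0, 1] ** 2)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum((y_pred - y_true) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    per_level = {
        float(lv): float(np.mean(np.abs(y_pred[y_true == lv] - lv)))
        for lv in np.unique(y_true)
    }
    return ModelReport(r_squared=r2, r_squared_ss=r2_ss, rmse=rmse, per_level_mae=per_level)


def pca_scores(X, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered (unscaled) PCA scores and explained-variance fractions.

    Returns a frame of per-sample scores (columns ``PC1..PCk``) and the
    explained-variance fractions, ordered nonincreasing.
    """
    Xa = _as_array(X)
    if Xa.shape[0] < n_components:
        raise ValueError("need at least as many samples as components")
    pca = PCA(n_components=n_components, random_state=0)
    scores = pca.fit_transform(Xa - Xa.mean(axis=0))
    index = X.index if hasattr(X, "index") else pd.RangeIndex(Xa.shape[0])
    frame = pd.DataFrame(scores, index=index, columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, pca.explained_variance_ratio_
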