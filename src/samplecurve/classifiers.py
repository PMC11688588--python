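"""Fixed-configuration classifier adapters and the CV-AUC machinery.

Four algorithms are supported, each at a frozen configuration so that
learning-curve results are a function of the data and the sample size only:

``lr``
    Plain multivariable logistic regression fitted by maximum likelihood,
    no selection or regularization.  On separable subsamples the iteration
    cap is the safeguard; rank-based AUC is insensitive to the direction of
    coefficient blow-up.
``rf`` / ``xgb``
    Random forest and gradient-boosted trees at their implementations'
    documented defaults (recorded in the config echo, since defaults differ
    across ecosystems and versions).
``nn``
    A multilayer perceptron with one hidden layer of 20 rectified-linear
    units trained for 10 epochs — an architectural contract, not a
    bit-for-bit reproduction of any particular backend.

Discrimination is measured by the area under the ROC curve in its
Mann-Whitney form, estimated out-of-sample by outcome-stratified k-fold
cross-validation and macro-averaged over folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from samplecurve.tabular import TabularDataset

__all__ = [
    "ALGORITHMS",
    "AlgorithmSpec",
    "CVResult",
    "auc",
    "stratified_folds",
    "cv_auc",
    "full_dataset_auc",
]

ALGORITHMS = ("xgb", "rf", "lr", "nn")


@dataclass(frozen=True)
class AlgorithmSpec:
    """One of the four supported algorithms at its fixed configuration."""

    name: str
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; expected one of {ALGORITHMS}")

    def make_estimator(self, seed: int):
        """Build a fresh, seeded scikit-learn style estimator."""
        if self.name == "lr":
            # C=inf: unpenalized maximum-likelihood fit; iteration cap guards
            # against separable subsamples
            return LogisticRegression(C=np.inf, max_iter=200, solver="lbfgs")
        if self.name == "rf":
            return RandomForestClassifier(random_state=seed)
        if self.name == "xgb":
            return XGBClassifier(random_state=seed, eval_metric="logloss")
        # nn: 1 hidden layer x 20 rectifier units, 10 training epochs;
        # features standardized inside the fold (MLPs are scale-sensitive)
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(20,),
                activation="relu",
                max_iter=10,
                random_state=seed,
            ),
        )

    def describe(self, seed: int | None = None) -> dict[str, Any]:
        """Config echo for run manifests: the estimator's effective params."""
        est = self.make_estimator(seed if seed is not None else 0)
        params = est.get_params() if hasattr(est, "get_params") else {}
        return {
            "name": self.name,
            "params": {k: v for k, v in params.items() if not callable(v)},
        }


@dataclass(frozen=True)
class CVResult:
    """Per-fold AUCs from one stratified cross-validation run."""

    fold_aucs: tuple[float, ...]
    k: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form).

    The fraction of (positive, negative) pairs where the positive scores
    higher, ties counting one half.  Invariant to any strictly increasing
    transform of ``scores``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Outcome-stratified fold assignment vector in {0..k-1}.

    Each fold's class proportion is within one sample of the overall
    proportion; the assignment is deterministic given ``seed``.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs at least k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def cv_auc(
    dataset: TabularDataset,
    algo: AlgorithmSpec,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """k-fold outcome-stratified cross-validated AUC, macro-averaged.

    Trains on k-1 folds, scores held-out probabilities, computes one AUC per
    fold and averages over folds (not over pooled predictions).
    """
    if dataset.has_missing:
        raise ValueError("dataset has missing values; impute before cross-validation")
    assignment = stratified_folds(dataset.y, k, seed)
    fold_aucs = []
    for fold in range(k):
        test = assignment == fold
        est = algo.make_estimator(seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(dataset.X[~test], dataset.y[~test])
            scores = est.predict_proba(dataset.X[test])[:, 1]
        except Exception as exc:  # noqa: BLE001 - annotate with fold index
            raise RuntimeError(f"training failed on fold {fold}: {exc}") from exc
        fold_aucs.append(auc(dataset.y[test], scores))
    return CVResult(fold_aucs=tuple(fold_aucs), k=k, seed=seed)


def full_dataset_auc(dataset: TabularDataset, algo: AlgorithmSpec, seed: int = 0) -> float:
    """Full-dataset AUC (*separability*): 5-fold stratified CV on all rows."""
    return cv_auc(dataset, algo, k=5, seed=seed).mean_auc
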