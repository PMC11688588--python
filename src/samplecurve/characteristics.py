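"""The six dataset-level characteristics driving sample-size prediction.

* **minority class proportion** — percentage of samples in the rarer outcome
  class, at most 50 (50 = perfectly balanced);
* **separability** — the full-dataset 5-fold CV-AUC of an algorithm, stored
  multiplied by 100 for interpretability;
* **number of features**;
* **percentage of continuous features** (>= 10 unique values);
* **percentage of core linear features** — features whose coefficients
  survive an L1 (LASSO) penalty in a full-data logistic model;
* **nonlinearity** — 100 x (XGB full-data AUC − LR full-data AUC), i.e. the
  AUC points a flexible learner gains over a plain linear model, dichotomized
  at 5.0 into high/low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from samplecurve.classifiers import AlgorithmSpec, full_dataset_auc
from samplecurve.tabular import FeatureKind, TabularDataset

__all__ = [
    "NONLINEARITY_THRESHOLD",
    "DatasetProfile",
    "minority_class_proportion",
    "core_linear_pct",
    "nonlinearity",
    "nonlinearity_class",
    "profile_dataset",
]

#: AUC-point gap (flexible minus linear) at and above which a dataset
#: counts as highly nonlinear
NONLINEARITY_THRESHOLD = 5.0


@dataclass
class DatasetProfile:
    """The six characteristics of one dataset (percentages on the 0-100 scale).

    ``separability`` maps algorithm name to 100 x full-dataset AUC; the XGB
    and LR entries are always present since nonlinearity is defined from
    them.
    """

    minority_pct: float
    n_features: int
    pct_continuous: float
    pct_core_linear: float
    separability: dict[str, float] = field(default_factory=dict)
    nonlinearity: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.minority_pct <= 50:
            raise ValueError("minority_pct must lie in (0, 50]")
        for name, value in (
            ("pct_continuous", self.pct_continuous),
            ("pct_core_linear", self.pct_core_linear),
        ):
            if not 0 <= value <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")

    @property
    def nonlinearity_high(self) -> bool:
        return self.nonlinearity >= NONLINEARITY_THRESHOLD

    def to_dict(self) -> dict:
        """One row in the characteristics-table column order."""
        return {
            "minority_pct": self.minority_pct,
            "n_features": self.n_features,
            "pct_core_linear": self.pct_core_linear,
            "pct_continuous": self.pct_continuous,
            "nonlinearity": self.nonlinearity,
            "nonlinearity_high": self.nonlinearity_high,
            **{f"separability_{k}": v for k, v in self.separability.items()},
        }


def minority_class_proportion(y: np.ndarray) -> float:
    """Percentage of samples in the rarer class; 50.0 means no imbalance."""
    y = np.asarray(y)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() == 0:
        raise ValueError("both outcome classes must be present")
    return float(100.0 * counts.min() / counts.sum())


def core_linear_pct(dataset: TabularDataset, seed: int = 0) -> float:
    """Percentage of features surviving an L1 penalty in a logistic model.

    Features are standardized, an L1 penalty path is scored by 5-fold
    cross-validated deviance, and the penalty is set by the one-standard-
    error rule: the strongest penalty whose mean CV deviance is within one
    standard error of the minimum.  (The deviance minimum itself sits at a
    near-vanishing penalty and lets most noise coefficients survive, which
    would defeat the point of a *core* feature count.)  Returns
    100 x (nonzero coefficients) / (total features) at the chosen penalty,
    refit on the full data.
    """
    if dataset.has_missing:
        raise ValueError("impute missing values before the LASSO scan")
    X = StandardScaler().fit_transform(dataset.X)
    if np.allclose(X, 0):
        raise ValueError("all features are constant; LASSO design is degenerate")
    y = dataset.y
    Cs = np.logspace(-3, 2, 30)  # ascending C = descending penalty
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    losses = np.empty((cv.get_n_splits(), len(Cs)))
    for f, (tr, te) in enumerate(cv.split(X, y)):
        for i, C in enumerate(Cs):
            model = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000
            )
            model.fit(X[tr], y[tr])
            p = np.clip(model.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
            losses[f, i] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(losses.shape[0])
    best = int(np.argmin(mean))
    within = np.flatnonzero(mean <= mean[best] + se[best])
    chosen = Cs[int(within.min())]  # smallest C = strongest penalty
    final = LogisticRegression(l1_ratio=1.0, C=chosen, solver="liblinear", max_iter=1000)
    final.fit(X, y)
    n_nonzero = int(np.sum(np.abs(final.coef_[0]) > 1e-10))
    return 100.0 * n_nonzero / dataset.n_features


def nonlinearity(auc_complex: float, auc_linear: float) -> float:
    """AUC-point gain of a flexible learner over plain logistic regression.

    ``100 x (auc_complex - auc_linear)``; e.g. AUCs of 0.95 vs 0.90 give 5.0.
    Antisymmetric under swapping its arguments.
    """
    for v in (auc_complex, auc_linear):
        if not 0.0 <= v <= 1.0:
            raise ValueError("AUC values must lie in [0, 1]")
    return 100.0 * (auc_complex - auc_linear)


def nonlinearity_class(value: float) -> str:
    """Dichotomize the nonlinearity value: 'high' iff >= 5.0, else 'low'."""
    return "high" if value >= NONLINEARITY_THRESHOLD else "low"


def profile_dataset(
    dataset: TabularDataset,
    seed: int = 0,
    algorithms: tuple[str, ...] = ("xgb", "lr"),
) -> DatasetProfile:
    """Compute all six characteristics of a preprocessed dataset.

    Runs the full-dataset CV-AUC for each requested algorithm (XGB and LR
    are always included — nonlinearity needs both).
    """
    algos = tuple(dict.fromkeys(algorithms + ("xgb", "lr")))
    separability = {
        name: 100.0 * full_dataset_auc(dataset, AlgorithmSpec(name), seed=seed)
        for name in algos
    }
    n_cont = sum(k is FeatureKind.CONTINUOUS for k in dataset.schema.kinds)
    return DatasetProfile(
        minority_pct=minority_class_proportion(dataset.y),
        n_features=dataset.n_features,
        pct_continuous=100.0 * n_cont / dataset.n_features,
        pct_core_linear=core_linear_pct(dataset, seed=seed),
        separability=separability,
        nonlinearity=nonlinearity(
            separability["xgb"] / 100.0, separability["lr"] / 100.0
        ),
    )
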