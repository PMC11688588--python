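"""The subsampling learning-curve engine.

The procedure traces cross-validated discrimination as a function of
training-set size:

1. choose a list of proposed training sizes (by default 10 evenly spaced
   points from 500 to 50,000; logistic regression stabilizes much earlier,
   so its default schedule ends at 10,000);
2. at each size n, draw 10 independent subsamples of the full dataset;
3. estimate the 5-fold outcome-stratified CV-AUC on each subsample;
4. average the 10 values into one point of the curve.

Per-(point, replicate) seeds are derived from the master seed with
``numpy.random.SeedSequence`` so any single point can be recomputed in
isolation and the whole curve is bit-reproducible for deterministic engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from samplecurve.classifiers import AlgorithmSpec, cv_auc, full_dataset_auc
from samplecurve.tabular import TabularDataset, subsample

__all__ = [
    "SampleSizeSchedule",
    "LearningCurvePoint",
    "LearningCurveData",
    "make_schedule",
    "compute_learning_curve",
    "extend_schedule",
    "replicate_seed",
    "DEFAULT_START",
    "DEFAULT_END",
    "DEFAULT_END_LR",
    "DEFAULT_N_POINTS",
    "DEFAULT_REPLICATES",
]

DEFAULT_START = 500
DEFAULT_END = 50_000
#: logistic regression stabilizes early; its default schedule ends lower
DEFAULT_END_LR = 10_000
DEFAULT_N_POINTS = 10
DEFAULT_REPLICATES = 10
MIN_SCHEDULE_N = 100


@dataclass(frozen=True)
class SampleSizeSchedule:
    """Strictly increasing list of proposed training-set sizes (each >= 100)."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) < 1:
            raise ValueError("schedule must contain at least one size")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("schedule sizes must be strictly increasing")
        if self.sizes[0] < MIN_SCHEDULE_N:
            raise ValueError(f"smallest schedule size must be >= {MIN_SCHEDULE_N}")

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class LearningCurvePoint:
    """Replicate CV-AUCs at one training size and their mean."""

    n: int
    replicate_aucs: tuple[float, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.replicate_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.replicate_aucs, ddof=1)) if len(self.replicate_aucs) > 1 else 0.0


@dataclass
class LearningCurveData:
    """A full learning curve plus the full-dataset AUC reference."""

    points: list[LearningCurvePoint]
    full_auc: float
    algo: AlgorithmSpec
    seed: int

    def __post_init__(self) -> None:
        ns = [p.n for p in self.points]
        if ns != sorted(ns):
            raise ValueError("points must be sorted by n")
        if not 0.0 <= self.full_auc <= 1.0:
            raise ValueError("full_auc must be in [0, 1]")

    @property
    def ns(self) -> np.ndarray:
        return np.array([p.n for p in self.points])

    @property
    def mean_aucs(self) -> np.ndarray:
        return np.array([p.mean_auc for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (n, replicate)."""
        rows = [
            {"n": p.n, "replicate": r, "cv_auc": v}
            for p in self.points
            for r, v in enumerate(p.replicate_aucs)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, full_auc: float, algo: AlgorithmSpec, seed: int = 0
    ) -> "LearningCurveData":
        points = [
            LearningCurvePoint(n=int(n), replicate_aucs=tuple(g.sort_values("replicate")["cv_auc"]))
            for n, g in df.groupby("n", sort=True)
        ]
        return cls(points=points, full_auc=full_auc, algo=algo, seed=seed)


def make_schedule(
    start: int = DEFAULT_START,
    end: int = DEFAULT_END,
    n_points: int = DEFAULT_N_POINTS,
) -> SampleSizeSchedule:
    """``n_points`` evenly spaced integers from ``start`` to ``end`` inclusive."""
    if start >= end:
        raise ValueError(f"start ({start}) must be below end ({end})")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    sizes = np.rint(np.linspace(start, end, n_points)).astype(int)
    return SampleSizeSchedule(sizes=tuple(int(s) for s in sizes))


def replicate_seed(master_seed: int, point_index: int, replicate: int) -> int:
    """Deterministic per-(point, replicate) seed, below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(point_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def compute_learning_curve(
    dataset: TabularDataset,
    algo: AlgorithmSpec,
    schedule: SampleSizeSchedule | None = None,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    k: int = 5,
    full_auc: float | None = None,
) -> LearningCurveData:
    """Trace the learning curve of ``algo`` on ``dataset`` over ``schedule``.

    Each schedule size is evaluated on ``replicates`` independent subsamples
    (drawn without replacement within a replicate; overlap across replicates
    is permitted), each scored by k-fold stratified CV-AUC.  A size whose
    subsamples repeatedly miss one class is skipped with a warning rather
    than failing the curve.  ``full_auc`` can be supplied to avoid
    recomputing the full-dataset reference.
    """
    if schedule is None:
        end = min(DEFAULT_END_LR if algo.name == "lr" else DEFAULT_END, dataset.n_samples)
        schedule = make_schedule(DEFAULT_START, end, DEFAULT_N_POINTS)
    if schedule.sizes[-1] > dataset.n_samples:
        raise ValueError(
            f"largest schedule size {schedule.sizes[-1]} exceeds dataset "
            f"size {dataset.n_samples}"
        )
    points: list[LearningCurvePoint] = []
    for i, n in enumerate(schedule):
        reps: list[float] = []
        for r in range(replicates):
            s = replicate_seed(seed, i, r)
            try:
                sub = subsample(dataset, n, seed=s)
                reps.append(cv_auc(sub, algo, k=k, seed=s).mean_auc)
            except ValueError as exc:
                warnings.warn(f"skipping replicate {r} at n={n}: {exc}")
        if reps:
            points.append(LearningCurvePoint(n=n, replicate_aucs=tuple(reps)))
        else:
            warnings.warn(f"skipping n={n}: no usable replicate")
    if full_auc is None:
        full_auc = full_dataset_auc(dataset, algo, seed=seed)
    return LearningCurveData(points=points, full_auc=full_auc, algo=algo, seed=seed)


def extend_schedule(
    data: LearningCurveData,
    dataset: TabularDataset,
    factor: float = 2.0,
    delta: float = 0.02,
    replicates: int = DEFAULT_REPLICATES,
    k: int = 5,
) -> LearningCurveData:
    """Extend a curve whose stability point lies beyond its last size.

    Appends evenly spaced sizes (at the curve's existing step) up to
    ``factor`` times the previous maximum, capped at the dataset size, and
    evaluates them.  If the fitted curve already reaches stability within
    the observed range this is a no-op with a warning.
    """
    from samplecurve.curve_fit import select_curve, solve_n_for_stability

    old_max = data.points[-1].n
    fit = select_curve(data)
    res = solve_n_for_stability(fit, data.full_auc, delta=delta)
    if res.n_stable is not None and res.n_stable <= old_max:
        warnings.warn("stability already reached within the observed range; no extension")
        return data
    if old_max >= dataset.n_samples:
        raise ValueError("schedule already spans the dataset; cannot extend")
    step = old_max - data.points[-2].n if len(data.points) >= 2 else old_max
    new_max = min(int(round(factor * old_max)), dataset.n_samples)
    new_sizes = list(range(old_max + step, new_max + 1, step))
    if not new_sizes or new_sizes[-1] != new_max:
        new_sizes.append(new_max)
    offset = len(data.points)
    points = list(data.points)
    for i, n in enumerate(new_sizes):
        reps = []
        for r in range(replicates):
            s = replicate_seed(data.seed, offset + i, r)
            try:
                sub = subsample(dataset, n, seed=s)
                reps.append(cv_auc(sub, data.algo, k=k, seed=s).mean_auc)
            except ValueError as exc:
                warnings.warn(f"skipping replicate {r} at n={n}: {exc}")
        if reps:
            points.append(LearningCurvePoint(n=n, replicate_aucs=tuple(reps)))
    return LearningCurveData(points=points, full_auc=data.full_auc, algo=data.algo, seed=data.seed)
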