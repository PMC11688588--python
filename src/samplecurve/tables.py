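"""Embedded reference tables and their printed summary statistics.

Four versioned fixtures ship with the package, describing a reference
meta-analysis of 16 large open clinical datasets (70,000-1,000,000 rows)
across the four supported algorithms:

* characteristics — the six dataset-level characteristics per dataset;
* full-dataset AUCs (separability) per dataset and algorithm;
* stability sample sizes per dataset and algorithm;
* published multivariable NB sample-size models per algorithm.

Every summary here is a pure function of the fixtures, so outputs are
byte-identical across runs.  Note two internal inconsistencies of the
reference source, reproduced as-is in the fixtures: its prose quotes an LR
range upper end of 6798 while the stored column maximum is 6768, and its NN
median appears both as 12,298 and 12,998; the recomputed summaries report
6768 and 12,298.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ALGO_COLUMNS",
    "ReferenceTables",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_table5",
    "load_all",
    "build_meta_frame",
    "summarize_sample_sizes",
    "characteristic_summaries",
    "epv_summary",
    "auc_gap_summary",
]

ALGO_COLUMNS = ("xgb", "rf", "lr", "nn")


def _read(name: str) -> pd.DataFrame:
    with resources.files("samplecurve.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Dataset-level characteristics of the 16 reference datasets."""
    return _read("table1_characteristics.csv")


def load_table2() -> pd.DataFrame:
    """Full-dataset AUC (separability) per dataset and algorithm."""
    return _read("table2_full_auc.csv")


def load_table3() -> pd.DataFrame:
    """Stability sample sizes per dataset and algorithm."""
    return _read("table3_stability_n.csv")


def load_table5() -> pd.DataFrame:
    """Published multivariable NB model coefficients (multiplier scale)."""
    return _read("table5_published_models.csv")


@dataclass(frozen=True)
class ReferenceTables:
    """All four fixtures with consistent dataset row keys."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table5: pd.DataFrame

    def __post_init__(self) -> None:
        keys = list(self.table1["dataset"])
        for name in ("table2", "table3"):
            other = list(getattr(self, name)["dataset"])
            if other != keys:
                raise ValueError(f"row keys of {name} differ from the characteristics table")


def load_all() -> ReferenceTables:
    return ReferenceTables(
        table1=load_table1(), table2=load_table2(), table3=load_table3(), table5=load_table5()
    )


def build_meta_frame(algorithm: str) -> pd.DataFrame:
    """Join characteristics and stability sizes into one NB-regression input.

    Separability is the algorithm's own full-dataset AUC x 100;
    ``nonlinearity_high`` dichotomizes the characteristic at 5.0 points.
    """
    if algorithm not in ALGO_COLUMNS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    t1, t2, t3 = load_table1(), load_table2(), load_table3()
    return pd.DataFrame(
        {
            "dataset": t1["dataset"],
            "n_stable": t3[algorithm].astype(int),
            "minority_pct": t1["minority_pct"].astype(float),
            "separability": 100.0 * t2[algorithm].astype(float),
            "n_features": t1["n_features"].astype(float),
            "pct_continuous": t1["pct_continuous"].astype(float),
            "pct_core_linear": t1["pct_core_linear"].astype(float),
            "nonlinearity_high": (t1["nonlinearity"].astype(float) >= 5.0).astype(float),
        }
    )


def _median_half_even(values: np.ndarray) -> int:
    """Median of an even-length integer sample, rounding .5 to the even
    integer (this reproduces the printed medians from the stored columns)."""
    return int(np.round(np.median(values)))


def summarize_sample_sizes(table3: pd.DataFrame | None = None) -> dict[str, dict]:
    """Per-algorithm median, range, and mean/SD of natural-log sample sizes."""
    t3 = load_table3() if table3 is None else table3
    out = {}
    for algo in ALGO_COLUMNS:
        v = t3[algo].to_numpy(dtype=float)
        logs = np.log(v)
        out[algo] = {
            "median": _median_half_even(v),
            "range": (int(v.min()), int(v.max())),
            "log_mean": round(float(logs.mean()), 2),
            "log_sd": round(float(logs.std(ddof=1)), 2),
        }
    return out


def characteristic_summaries(table1: pd.DataFrame | None = None) -> dict[str, float]:
    """Means/SDs and medians of the six characteristics over the 16 datasets."""
    t1 = load_table1() if table1 is None else table1

    def mean_sd(col: str) -> tuple[float, float]:
        v = t1[col].to_numpy(dtype=float)
        return round(float(v.mean()), 2), round(float(v.std(ddof=1)), 2)

    minority_mean, minority_sd = mean_sd("minority_pct")
    nfeat_mean, nfeat_sd = mean_sd("n_features")
    cont_mean, cont_sd = mean_sd("pct_continuous")
    core_mean, core_sd = mean_sd("pct_core_linear")
    nl = t1["nonlinearity"].to_numpy(dtype=float)
    n_low = int((nl < 5.0).sum())
    return {
        "minority_mean": minority_mean,
        "minority_sd": minority_sd,
        "n_features_mean": round(nfeat_mean),
        "n_features_sd": round(nfeat_sd),
        "continuous_mean": round(cont_mean, 1),
        "continuous_sd": cont_sd,
        "core_linear_mean": core_mean,
        "core_linear_sd": core_sd,
        "nonlinearity_median": round(float(np.median(nl)), 2),
        "nonlinearity_range": (float(nl.min()), float(nl.max())),
        "n_low_nonlinearity": n_low,
        # display convention: half-up to one decimal (13/16 -> 81.3)
        "pct_low_nonlinearity": math.floor(1000.0 * n_low / len(nl) + 0.5) / 10.0,
    }


def epv_summary(
    table1: pd.DataFrame | None = None, table3: pd.DataFrame | None = None
) -> dict[str, int]:
    """Mean events-per-variable implied by the stability sizes, per algorithm.

    EPV per dataset = n_stable x (minority % / 100) / number of features;
    the mean over the 16 datasets is rounded to an integer.
    """
    t1 = load_table1() if table1 is None else table1
    t3 = load_table3() if table3 is None else table3
    frac = t1["minority_pct"].to_numpy(dtype=float) / 100.0
    feats = t1["n_features"].to_numpy(dtype=float)
    return {
        algo: int(round(float((t3[algo].to_numpy(dtype=float) * frac / feats).mean())))
        for algo in ALGO_COLUMNS
    }


def auc_gap_summary(table2: pd.DataFrame | None = None) -> float:
    """Mean per-dataset full-AUC gap of XGB over LR, to 3 decimals."""
    t2 = load_table2() if table2 is None else table2
    gap = t2["xgb"].to_numpy(dtype=float) - t2["lr"].to_numpy(dtype=float)
    return round(float(gap.mean()), 3)
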