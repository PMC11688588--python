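"""Negative binomial sample-size meta-models.

Stability sample sizes are discrete, strictly positive and heavily
right-skewed across datasets, so they are modelled as negative binomial
counts with a log link: exponentiated coefficients act as multipliers on
the expected sample size.  Two routes are offered:

* **refit** — :func:`fit_nb` / :func:`fit_nb_best_subset` fit NB
  regressions of observed stability sizes on dataset characteristics
  (dispersion estimated by maximum likelihood, best subset of at most three
  predictors chosen by AIC to avoid overfitting at meta-analysis sample
  sizes);
* **published** — :func:`published_models` exposes the reference
  multivariable equations for XGB, RF, LR and NN, and
  :func:`predict_sample_size` evaluates either kind of model on a new
  dataset's profile.

Predictor encoding (identical for fitting and prediction): minority class
proportion raw on 0-50; separability as (100 x AUC) - 50, so 50.0 — a
random classifier — is the baseline; nonlinearity as a 0/1 high indicator
(threshold 5.0 points); feature counts and percentages raw.  The intercept
is therefore the expected sample size at a vanishing minority class, random
separability, low nonlinearity and zero features — a mathematical anchor,
not a realistic dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from samplecurve.characteristics import DatasetProfile

__all__ = [
    "PREDICTORS",
    "NBRegressionFit",
    "PublishedModel",
    "MetaDataset",
    "make_meta_dataset",
    "encode_predictors",
    "fit_nb",
    "fit_nb_best_subset",
    "adjusted_pseudo_r2",
    "predict_sample_size",
    "events_per_variable",
    "published_models",
]

#: the six candidate dataset-level predictors, canonical order
PREDICTORS = (
    "minority_pct",
    "separability",
    "n_features",
    "pct_continuous",
    "pct_core_linear",
    "nonlinearity_high",
)

SEPARABILITY_BASELINE = 50.0

#: observed ranges of the reference meta-analysis datasets; predictions from
#: published models outside these trigger an extrapolation warning
OBSERVED_RANGES = {
    "minority_pct": (2.1, 50.0),
    "separability": (59.6, 97.9),
    "n_features": (8, 39),
    "pct_continuous": (3.0, 55.6),
    "pct_core_linear": (25.0, 100.0),
}


@dataclass
class MetaDataset:
    """Rows of (stability n, six characteristics) for one algorithm."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"n_stable", *PREDICTORS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"meta dataset missing columns: {sorted(missing)}")
        n = self.frame["n_stable"]
        if not ((n > 0) & (n == n.astype(int))).all():
            raise ValueError("n_stable values must be positive integers")

    def __len__(self) -> int:
        return len(self.frame)


def make_meta_dataset(
    n_stable: list[int], profiles: list[DatasetProfile], algorithm: str = "xgb"
) -> MetaDataset:
    """Join stability sizes with profiles, taking each profile's separability
    for ``algorithm``."""
    rows = []
    for n, p in zip(n_stable, profiles, strict=True):
        d = p.to_dict()
        rows.append(
            {
                "n_stable": n,
                "minority_pct": d["minority_pct"],
                "separability": d.get(f"separability_{algorithm}", d.get("separability_xgb")),
                "n_features": d["n_features"],
                "pct_continuous": d["pct_continuous"],
                "pct_core_linear": d["pct_core_linear"],
                "nonlinearity_high": float(d["nonlinearity_high"]),
            }
        )
    return MetaDataset(pd.DataFrame(rows))


def encode_predictors(frame: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    """Model encoding: separability centered at 50, nonlinearity as 0/1,
    everything else raw."""
    out = {}
    for name in predictors:
        if name not in frame.columns:
            raise ValueError(f"predictor {name!r} absent from meta dataset")
        col = frame[name].astype(float)
        if name == "separability":
            col = col - SEPARABILITY_BASELINE
        elif name == "nonlinearity_high":
            col = col.astype(bool).astype(float)
        out[name] = col
    return pd.DataFrame(out, index=frame.index)


@dataclass
class NBRegressionFit:
    """A fitted NB regression on the log-expected-count scale.

    ``coefficients`` includes the intercept first; ``multipliers`` are the
    exponentiated coefficients with Wald 95% intervals computed on the log
    scale.  ``dispersion`` is the NB overdispersion parameter alpha
    (variance = mu + alpha * mu**2; alpha -> 0 recovers Poisson).
    """

    predictor_names: tuple[str, ...]
    coefficients: dict[str, float]
    multipliers: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]
    dispersion: float
    aic: float
    deviance: float
    null_deviance: float
    n_obs: int
    pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def intercept_count(self) -> float:
        """Expected sample size with every encoded predictor at zero."""
        return self.multipliers["intercept"]

    @property
    def pseudo_r2(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def pseudo_r2_adj(self) -> float:
        return adjusted_pseudo_r2(self)


def _nb_mle(y: np.ndarray, X: pd.DataFrame):
    """Joint ML fit of coefficients and dispersion, with fallbacks for the
    small meta-analysis sample sizes this model is used at."""
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs", "nm"):
            try:
                res = model.fit(method=method, maxiter=2000, disp=0)
            except Exception:
                continue
            if res.mle_retvals.get("converged", False) and np.isfinite(res.llf):
                return res
    raise RuntimeError("negative binomial fit did not converge")


def fit_nb(meta: MetaDataset | pd.DataFrame, predictors: tuple[str, ...] = ()) -> NBRegressionFit:
    """Maximum-likelihood NB regression of n_stable on selected predictors.

    Deviances (residual and intercept-only) are evaluated at the fitted
    dispersion so the deviance-based pseudo-R^2 is well defined.
    """
    frame = meta.frame if isinstance(meta, MetaDataset) else meta
    predictors = tuple(predictors)
    if len(frame) < len(predictors) + 2:
        raise ValueError(
            f"{len(frame)} observations cannot support {len(predictors)} predictors"
        )
    y = frame["n_stable"].to_numpy(dtype=float)
    X = encode_predictors(frame, predictors)
    X.insert(0, "intercept", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank deficient")

    res = _nb_mle(y, X)
    alpha = float(res.params["alpha"])
    names = ["intercept", *predictors]
    coefs = {n: float(res.params[n]) for n in names}
    ci = res.conf_int()
    conf = {n: (math.exp(ci.loc[n, 0]), math.exp(ci.loc[n, 1])) for n in names}
    pvals = {n: float(res.pvalues[n]) for n in names}

    # deviances at the fitted dispersion via a GLM refit
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=fam).fit()
        null = sm.GLM(y, X[["intercept"]], family=fam).fit()
    return NBRegressionFit(
        predictor_names=predictors,
        coefficients=coefs,
        multipliers={n: math.exp(c) for n, c in coefs.items()},
        conf_intervals=conf,
        dispersion=alpha,
        aic=float(res.aic),
        deviance=float(glm.deviance),
        null_deviance=float(null.deviance),
        n_obs=len(frame),
        pvalues=pvals,
    )


def fit_nb_best_subset(
    meta: MetaDataset | pd.DataFrame,
    max_predictors: int = 3,
    candidates: tuple[str, ...] = PREDICTORS,
) -> NBRegressionFit:
    """Exhaustive best-subset NB regression by minimum AIC.

    All subsets of size 1..``max_predictors`` of the six characteristics
    (41 models for the defaults) plus the intercept-only model are fitted;
    ties break toward fewer predictors.  The AIC ranking of every candidate
    that converged is attached as ``.ranking`` (list of (subset, aic)).
    """
    subsets: list[tuple[str, ...]] = [()]
    for size in range(1, max_predictors + 1):
        subsets.extend(combinations(candidates, size))
    fits: list[tuple[tuple[str, ...], NBRegressionFit]] = []
    for subset in subsets:
        try:
            fits.append((subset, fit_nb(meta, subset)))
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"subset {subset} failed: {exc}")
    if not fits:
        raise RuntimeError("no candidate subset converged")
    fits.sort(key=lambda t: (round(t[1].aic, 10), len(t[0])))
    best = fits[0][1]
    best.ranking = [(subset, fit.aic) for subset, fit in fits]  # type: ignore[attr-defined]
    return best


def adjusted_pseudo_r2(fit: NBRegressionFit) -> float:
    """Deviance pseudo-R^2 adjusted for the number of predictors.

    ``R2 = 1 - D_res/D_null``; adjusted as
    ``1 - (1 - R2) * (n - 1) / (n - k - 1)`` with k predictors.
    """
    k = len(fit.predictor_names)
    n = fit.n_obs
    if n <= k + 1:
        raise ValueError(f"n={n} too small to adjust for k={k} predictors")
    return 1.0 - (1.0 - fit.pseudo_r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class PublishedModel:
    """A reference multivariable NB sample-size equation for one algorithm.

    ``intercept_count`` is the expected n at baseline (all encoded
    predictors zero); ``multipliers`` maps predictor name to the
    multiplicative effect of one encoded unit, with 95% CIs where printed.
    """

    algorithm: str
    intercept_count: float
    intercept_ci: tuple[float, float]
    multipliers: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]
    pseudo_r2_adj: float

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.multipliers)


def published_models() -> dict[str, PublishedModel]:
    """The four reference equations, loaded from the embedded fixture."""
    from samplecurve.tables import load_table5

    t5 = load_table5()
    models = {}
    for algo, g in t5.groupby("algorithm"):
        g = g.set_index("predictor")
        inter = g.loc["intercept"]
        rest = g.drop(index="intercept")
        models[algo] = PublishedModel(
            algorithm=algo,
            intercept_count=float(inter["estimate"]),
            intercept_ci=(float(inter["ci_low"]), float(inter["ci_high"])),
            multipliers={p: float(r["estimate"]) for p, r in rest.iterrows()},
            conf_intervals={
                p: (float(r["ci_low"]), float(r["ci_high"])) for p, r in rest.iterrows()
            },
            pseudo_r2_adj=float(inter["pseudo_r2_adj"]),
        )
    return models


def _encode_value(name: str, value: float) -> float:
    if name == "separability":
        return float(value) - SEPARABILITY_BASELINE
    if name == "nonlinearity_high":
        return float(bool(value))
    return float(value)


def _profile_value(profile: DatasetProfile | dict, name: str, algorithm: str) -> float:
    if isinstance(profile, DatasetProfile):
        if name == "separability":
            sep = profile.separability
            if algorithm in sep:
                return sep[algorithm]
            raise ValueError(
                f"profile lacks separability for {algorithm!r}; available: {sorted(sep)}"
            )
        if name == "nonlinearity_high":
            return float(profile.nonlinearity_high)
        return float(getattr(profile, name))
    if name not in profile:
        raise ValueError(f"missing predictor {name!r}")
    return float(profile[name])


def predict_sample_size(
    profile: DatasetProfile | dict,
    model: PublishedModel | NBRegressionFit,
) -> tuple[int, tuple[float, float]]:
    """Expected stability sample size under a multiplicative NB model.

    ``n = intercept * prod(multiplier_j ** x_j)`` over the model's encoded
    predictors, rounded up; the second return value is a conservative 95%
    interval obtained by propagating each term's CI bound-by-bound.
    Profiles outside the reference meta-analysis ranges trigger an
    extrapolation warning.
    """
    if isinstance(model, PublishedModel):
        algorithm = model.algorithm
        intercept = model.intercept_count
        icept_ci = model.intercept_ci
        multipliers = model.multipliers
        cis = model.conf_intervals
    else:
        algorithm = "xgb"
        intercept = model.intercept_count
        icept_ci = model.conf_intervals["intercept"]
        multipliers = {n: model.multipliers[n] for n in model.predictor_names}
        cis = {n: model.conf_intervals[n] for n in model.predictor_names}

    n_hat, lo, hi = intercept, icept_ci[0], icept_ci[1]
    for name, mult in multipliers.items():
        raw = _profile_value(profile, name, algorithm)
        rng = OBSERVED_RANGES.get(name)
        if rng and not rng[0] <= raw <= rng[1]:
            warnings.warn(
                f"{name}={raw:g} lies outside the reference range "
                f"[{rng[0]:g}, {rng[1]:g}]; prediction is an extrapolation"
            )
        x = _encode_value(name, raw)
        n_hat *= mult**x
        b1, b2 = cis[name][0] ** x, cis[name][1] ** x
        lo *= min(b1, b2)
        hi *= max(b1, b2)
    return math.ceil(n_hat), (lo, hi)


def events_per_variable(n: float, minority_prop: float, n_features: int) -> float:
    """Convert a sample size to events per variable: n * p_minority / features."""
    if n_features < 1:
        raise ValueError("n_features must be at least 1")
    if not 0 < minority_prop <= 0.5:
        raise ValueError("minority_prop must lie in (0, 0.5]")
    return n * minority_prop / n_features
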