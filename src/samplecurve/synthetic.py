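"""Synthetic tabular clinical datasets with controllable characteristics.

The generator emulates the structure of a focused clinical study: a modest
number of mixed continuous/binary features, a single binary outcome, and
tunable class imbalance, signal strength and nonlinearity.  The outcome
follows a latent logistic model

    logit P(y=1 | x) = alpha + sum_j beta_j x_j + gamma * q(x),

where the informative features carry linear coefficients of magnitude
``effect_scale`` (alternating sign), and ``q`` adds pairwise products and
squares of the informative features scaled by ``nonlinear_scale`` — terms a
plain logistic model cannot represent, so the flexible-vs-linear AUC gap
(the nonlinearity characteristic) grows with ``nonlinear_scale``.  Class
imbalance is set by shifting the intercept ``alpha`` (calibrated by
bisection to hit the target event rate), not by resampling, so feature
marginals are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from samplecurve.tabular import FeatureKind, FeatureSchema, TabularDataset

__all__ = ["GeneratorConfig", "calibrate_intercept", "generate_dataset"]

#: rows in the fixed draw used to calibrate the intercept
CALIBRATION_DRAW = 200_000
#: |mean event probability - minority_target| achieved by calibration
CALIBRATION_TOL = 1e-3


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    n, p:
        rows and features.
    pct_continuous:
        target percentage of continuous (standard normal) features; the
        rest are symmetric Bernoulli 0/1.  Counts are rounded to the
        nearest feature.
    n_informative:
        number of leading features with nonzero linear coefficients.
    effect_scale:
        magnitude of each informative linear coefficient; 0 gives a pure
        noise outcome (AUC 0.5), larger values raise separability.
    nonlinear_scale:
        magnitude of interaction/quadratic coefficients among the
        informative features; 0 keeps the data linear.
    minority_target:
        event rate in (0, 0.5]; 0.5 is balanced.
    """

    n: int = 20_000
    p: int = 12
    pct_continuous: float = 50.0
    n_informative: int = 4
    effect_scale: float = 0.8
    nonlinear_scale: float = 0.0
    minority_target: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be positive")
        if self.n_informative > self.p:
            raise ValueError("n_informative cannot exceed p")
        if not 0 < self.minority_target <= 0.5:
            raise ValueError("minority_target must lie in (0, 0.5]")
        if self.effect_scale < 0 or self.nonlinear_scale < 0:
            raise ValueError("scales must be non-negative")

    @property
    def n_continuous(self) -> int:
        return int(round(self.p * self.pct_continuous / 100.0))


def _feature_kinds(config: GeneratorConfig) -> list[FeatureKind]:
    """First ``n_continuous`` features are continuous, the rest binary; the
    informative block (leading features) therefore mixes both when possible."""
    n_cont = config.n_continuous
    return [FeatureKind.CONTINUOUS] * n_cont + [FeatureKind.BINARY] * (config.p - n_cont)


def _draw_features(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    X = np.empty((n, config.p))
    for j, kind in enumerate(_feature_kinds(config)):
        if kind is FeatureKind.CONTINUOUS:
            X[:, j] = rng.standard_normal(n)
        else:
            X[:, j] = rng.integers(0, 2, size=n).astype(float)
    return X


def _linear_coefs(config: GeneratorConfig) -> np.ndarray:
    beta = np.zeros(config.p)
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(config.n_informative)])
    beta[: config.n_informative] = config.effect_scale * signs
    return beta


def _latent_predictor(config: GeneratorConfig, X: np.ndarray) -> np.ndarray:
    """Linear part plus interaction/quadratic terms of informative features."""
    eta = X @ _linear_coefs(config)
    if config.nonlinear_scale > 0 and config.n_informative >= 1:
        k = config.n_informative
        gamma = config.nonlinear_scale
        for i in range(k):
            xi = X[:, i]
            eta = eta + gamma * (xi * xi - 1.0)  # centered square
            for j in range(i + 1, k):
                eta = eta + gamma * xi * X[:, j]
    return eta


def calibrate_intercept(config: GeneratorConfig) -> float:
    """Intercept alpha such that the mean event probability hits the target.

    With all coefficients zero the answer is the closed-form logit of the
    target.  Otherwise alpha is found by root bisection of the mean
    simulated probability over a fixed large calibration draw (tolerance
    0.001), using a seed derived from the config so generation stays
    deterministic.
    """
    if config.effect_scale == 0 and config.nonlinear_scale == 0:
        return float(np.log(config.minority_target / (1 - config.minority_target)))
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xCA11B,))
    )
    X = _draw_features(config, CALIBRATION_DRAW, rng)
    eta = _latent_predictor(config, X)

    def gap(alpha: float) -> float:
        return float(expit(alpha + eta).mean()) - config.minority_target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("calibration search range does not bracket the target rate")
    alpha = brentq(gap, lo, hi, xtol=1e-6)
    if abs(gap(alpha)) > CALIBRATION_TOL:
        raise RuntimeError("intercept calibration missed the target rate")
    return float(alpha)


def generate_dataset(config: GeneratorConfig) -> TabularDataset:
    """Draw one dataset from the generator; deterministic given the config."""
    alpha = calibrate_intercept(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xDA7A,))
    )
    X = _draw_features(config, config.n, rng)
    prob = expit(alpha + _latent_predictor(config, X))
    y = (rng.random(config.n) < prob).astype(int)
    kinds = _feature_kinds(config)
    schema = FeatureSchema(
        names=tuple(f"x{j + 1}" for j in range(config.p)),
        kinds=tuple(kinds),
    )
    return TabularDataset(X=X, y=y, schema=schema)
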