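"""Learning-curve fitting and inversion to the stability sample size.

Two curve families are supported.  The inverse power law

    AUC(n) = a * n**b + c,      a < 0, b < 0, 0.5 <= c <= 1,

rises concavely toward the asymptote ``c``, which is either fixed at the
observed full-dataset AUC or estimated.  When the power law fits poorly —
typically datasets that stabilize slowly — a logarithmic curve

    AUC(n) = beta0 + beta1 * log(n),      beta1 > 0,

is used instead (natural log, ordinary least squares).  Family arbitration
is explicit: all three candidates (power with fixed c, power with free c,
logarithmic) are fitted to the replicate-averaged points and the
small-sample corrected AIC from the Gaussian residual likelihood picks the
winner.

The *stability* sample size is the smallest n whose predicted AUC is within
``delta`` points (default 0.02) of the full-dataset AUC; both families
invert in closed form.  The threshold is a free choice — 0.01 and 0.05 are
common alternatives — and tightening it can only increase the answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from samplecurve.learning_curve import LearningCurveData

__all__ = [
    "CurveFitError",
    "PowerLawFit",
    "LogFit",
    "CurveFit",
    "StabilityResult",
    "fit_power_law",
    "fit_logarithmic",
    "select_curve",
    "predict_auc",
    "solve_n_for_stability",
]

#: stability solutions beyond this multiple of the largest observed n are
#: flagged as far extrapolations (the log family will always "reach" a target)
FAR_EXTRAPOLATION_FACTOR = 10.0


class CurveFitError(ValueError):
    """A curve family could not be fitted (non-convergence, degenerate data)."""


@dataclass(frozen=True)
class PowerLawFit:
    """AUC(n) = a*n**b + c with a < 0, b < 0 and c in [0.5, 1]."""

    a: float
    b: float
    c: float
    c_fixed: bool
    rss: float

    def predict(self, n) -> np.ndarray | float:
        return self.a * np.asarray(n, dtype=float) ** self.b + self.c

    @property
    def n_params(self) -> int:
        return 2 if self.c_fixed else 3


@dataclass(frozen=True)
class LogFit:
    """AUC(n) = beta0 + beta1*log(n), natural log."""

    beta0: float
    beta1: float
    rss: float

    def predict(self, n) -> np.ndarray | float:
        return self.beta0 + self.beta1 * np.log(np.asarray(n, dtype=float))

    @property
    def n_params(self) -> int:
        return 2


Family = Literal["power_fixed_c", "power_free_c", "logarithmic"]


@dataclass(frozen=True)
class CurveFit:
    """The selected curve family with all candidates and their AICc scores."""

    family: Family
    params: PowerLawFit | LogFit
    selection_score: float
    candidates: dict[Family, tuple[PowerLawFit | LogFit, float]]
    n_max_observed: int

    def predict(self, n) -> np.ndarray | float:
        return self.params.predict(n)


@dataclass(frozen=True)
class StabilityResult:
    """Smallest n within ``delta`` AUC points of the full-dataset AUC."""

    n_stable: int | None
    delta: float
    target_auc: float
    extrapolated: bool = False
    far_extrapolated: bool = False

    @property
    def reachable(self) -> bool:
        return self.n_stable is not None


def _curve_inputs(points: LearningCurveData) -> tuple[np.ndarray, np.ndarray]:
    ns = points.ns.astype(float)
    aucs = points.mean_aucs
    if len(np.unique(ns)) != len(ns):
        raise CurveFitError("duplicate n values in curve data")
    return ns, aucs


def fit_power_law(points: LearningCurveData, fix_c: bool = False) -> PowerLawFit:
    """Nonlinear least-squares fit of the inverse power law.

    With ``fix_c`` the asymptote is pinned to the curve's full-dataset AUC
    and only (a, b) are estimated.  Optimization is bounded (a < 0, b < 0,
    0.5 <= c <= 1) and restarted from several curvature guesses; the best
    converged restart by residual sum of squares wins.

    Raises
    ------
    CurveFitError
        Fewer points than parameters, flat responses, or no restart
        converging.
    """
    ns, aucs = _curve_inputs(points)
    n_params = 2 if fix_c else 3
    if len(ns) < n_params:
        raise CurveFitError(
            f"need at least {n_params} points for {'fixed' if fix_c else 'free'}-c power law"
        )
    if np.allclose(aucs, aucs[0]):
        raise CurveFitError("all responses identical; power law undetermined")

    full_auc = points.full_auc
    tiny = 1e-12
    n_min = float(ns[0])
    scaled = ns / n_min

    # well-scaled parameterization: u = a * n_min**b is the AUC deficit at
    # the smallest observed size, bounded in [-1, 0); avoids the flat ridge
    # of huge |a| against steep b that raw (a, b) optimization wanders into
    def residuals_fixed(theta):
        u, b = theta
        return u * scaled**b + full_auc - aucs

    def residuals_free(theta):
        u, b, c = theta
        return u * scaled**b + c - aucs

    best = None
    for b0 in (-0.25, -0.5, -1.0):
        c0 = max(float(aucs.max()), full_auc)
        c0 = min(max(c0, 0.5 + tiny), 1.0)
        u0 = min(float(aucs[0]) - c0, -tiny)
        try:
            if fix_c:
                sol = least_squares(
                    residuals_fixed,
                    x0=[u0, b0],
                    bounds=([-1.0, -5.0], [-tiny, -tiny]),
                )
            else:
                sol = least_squares(
                    residuals_free,
                    x0=[u0, b0, c0],
                    bounds=([-1.0, -5.0, 0.5], [-tiny, -tiny, 1.0]),
                )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            raise CurveFitError(f"power-law optimization failed: {exc}") from exc
        if not sol.success:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise CurveFitError("power-law fit did not converge from any restart")
    x, rss = best
    b_hat = float(x[1])
    a_hat = float(x[0]) * n_min ** (-b_hat)
    if fix_c:
        return PowerLawFit(a=a_hat, b=b_hat, c=full_auc, c_fixed=True, rss=rss)
    return PowerLawFit(a=a_hat, b=b_hat, c=float(x[2]), c_fixed=False, rss=rss)


def fit_logarithmic(points: LearningCurveData) -> LogFit:
    """Closed-form OLS of mean AUC on log(n)."""
    ns, aucs = _curve_inputs(points)
    if len(ns) < 2:
        raise CurveFitError("need at least 2 distinct n for the logarithmic fit")
    beta1, beta0 = np.polyfit(np.log(ns), aucs, deg=1)
    if beta1 <= 1e-12:
        warnings.warn(
            f"logarithmic fit is non-increasing (beta1={beta1:.4g}); "
            "curve cannot represent learning"
        )
    resid = aucs - (beta0 + beta1 * np.log(ns))
    return LogFit(beta0=float(beta0), beta1=float(beta1), rss=float(resid @ resid))


def _aicc(rss: float, n: int, n_curve_params: int) -> float:
    """Small-sample AIC from the Gaussian residual likelihood.

    The parameter count includes the residual variance.  Degenerate
    denominators (n too small for the correction) score +inf so the family
    drops out of selection.
    """
    k = n_curve_params + 1
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def select_curve(data: LearningCurveData) -> CurveFit:
    """Fit all three candidate families and keep the lowest-AICc one.

    A family that fails to fit is dropped; ties break toward fewer
    parameters.  Raises :class:`CurveFitError` only if every family fails.
    """
    if len(data.points) < 4:
        raise CurveFitError("need at least 4 points for curve selection")
    n = len(data.points)
    candidates: dict[Family, tuple[PowerLawFit | LogFit, float]] = {}
    for family, fitter in (
        ("power_fixed_c", lambda: fit_power_law(data, fix_c=True)),
        ("power_free_c", lambda: fit_power_law(data, fix_c=False)),
        ("logarithmic", lambda: fit_logarithmic(data)),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fitter()
        except CurveFitError:
            continue
        candidates[family] = (fit, _aicc(fit.rss, n, fit.n_params))
    if not candidates:
        raise CurveFitError("all curve families failed to fit")
    best_family = min(
        candidates, key=lambda f: (candidates[f][1], candidates[f][0].n_params)
    )
    fit, score = candidates[best_family]
    return CurveFit(
        family=best_family,
        params=fit,
        selection_score=score,
        candidates=candidates,
        n_max_observed=int(data.points[-1].n),
    )


def predict_auc(fit: CurveFit | PowerLawFit | LogFit, n: int | float) -> float:
    """Evaluate the fitted curve at training size ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(fit.predict(n))


def solve_n_for_stability(
    fit: CurveFit | PowerLawFit | LogFit,
    full_auc: float,
    delta: float = 0.02,
) -> StabilityResult:
    """Invert the fitted curve to the smallest n reaching ``full_auc - delta``.

    Power family: n = ceil(((target - c)/a)**(1/b)) when the target lies
    below the asymptote ``c``, otherwise unreachable.  Logarithmic family:
    n = ceil(exp((target - beta0)/beta1)) — this family has no asymptote and
    reaches any target, so far extrapolations are flagged.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    target = full_auc - delta
    params = fit.params if isinstance(fit, CurveFit) else fit
    n_max = fit.n_max_observed if isinstance(fit, CurveFit) else None

    if isinstance(params, PowerLawFit):
        if target >= params.c:
            return StabilityResult(n_stable=None, delta=delta, target_auc=target)
        n_exact = ((target - params.c) / params.a) ** (1.0 / params.b)
    else:
        if params.beta1 <= 0:
            return StabilityResult(n_stable=None, delta=delta, target_auc=target)
        n_exact = math.exp((target - params.beta0) / params.beta1)

    n_stable = max(1, math.ceil(n_exact - 1e-9))
    extrapolated = n_max is not None and n_stable > n_max
    far = n_max is not None and n_stable > FAR_EXTRAPOLATION_FACTOR * n_max
    if far:
        warnings.warn(
            f"n_stable={n_stable} lies beyond {FAR_EXTRAPOLATION_FACTOR:.0f}x the "
            f"largest observed n={n_max}; treat as a rough extrapolation"
        )
    return StabilityResult(
        n_stable=n_stable,
        delta=delta,
        target_auc=target,
        extrapolated=bool(extrapolated),
        far_extrapolated=bool(far),
    )
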