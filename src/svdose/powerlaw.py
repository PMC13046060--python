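"""Power-law model of precision decay: U(k) = alpha * k**(-beta) + gamma.

``alpha * k**(-beta)`` is the gain from averaging k small volumes — beta = 1/2
is the ideal central-limit regime, deviations absorb spatial correlation and
partial-volume effects — while ``gamma`` is the asymptotic floor: the residual
relative imprecision of the whole-kidney reference itself, approximately
sd(eps_wkp)/D_true, the best precision achievable no matter how many SVs are
averaged.

The estimator follows the scikit-learn protocol (fit/predict, trailing
underscore for fitted attributes) so it composes with sklearn tooling;
:func:`fit_power_law` is the plain-function wrapper operating on a
:class:`~svdose.precision_stats.PrecisionCurve`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .precision_stats import PrecisionCurve

__all__ = ["PowerLawDecay", "PowerLawFit", "fit_power_law", "evaluate", "asymptotic_floor", "r_squared"]

_SSR_ZERO = 1e-12


def _power_law(k: np.ndarray, alpha: float, beta: float, gamma: float) -> np.ndarray:
    return alpha * np.power(k, -beta) + gamma


def _r2(u: np.ndarray, pred: np.ndarray, weights: np.ndarray) -> float:
    # SST about the (weighted) mean; degenerate flat data: 1 if the fit is
    # exact, else 0 — degenerate curves must not crash reporting.
    resid = u - pred
    ssr = float(np.sum(weights * resid**2))
    sst = float(np.sum(weights * (u - np.average(u, weights=weights)) ** 2))
    if sst <= _SSR_ZERO:
        return 1.0 if ssr <= _SSR_ZERO else 0.0
    return 1.0 - ssr / sst


class PowerLawDecay(RegressorMixin, BaseEstimator):
    """Bounded nonlinear least-squares fit of ``u = alpha * k**(-beta) + gamma``.

    Bounds: alpha >= 0, beta in (0, beta_max], gamma >= 0, so the fitted
    curve is non-increasing in k.  Initialization: gamma0 = min(u),
    alpha0 = u(smallest k) - gamma0, beta0 = 0.5.  If the trust-region
    solver fails, a grid search over beta (step 0.05) with a non-negative
    linear solve for (alpha, gamma) picks the best candidate and refines it.

    Parameters
    ----------
    beta_max : float
        Upper bound on the decay exponent; 2.0 is a generous envelope
        around the theoretical 0.5.
    weight_by_n : bool
        Weight each point by its RD sample count when fitting a
        PrecisionCurve through :func:`fit_power_law`.  Off by default
        (pooled subset counts overstate effective sample size).

    Attributes
    ----------
    alpha_, beta_, gamma_ : float
        Fitted parameters (alpha and gamma in the units of u, i.e. percent).
    r2_ : float
        Coefficient of determination on the training points.
    converged_ : bool
    method_ : str
        ``"gradient"`` or ``"grid"`` — which path produced the solution.
    residuals_ : ndarray
        Observed minus fitted, per training point.
    param_se_ : ndarray or None
        Standard errors of (alpha, beta, gamma) from the Jacobian
        curvature; None when the degrees of freedom vanish.
    """

    def __init__(self, beta_max: float = 2.0, weight_by_n: bool = False):
        self.beta_max = beta_max
        self.weight_by_n = weight_by_n

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        k = np.asarray(X, dtype=float).reshape(-1)
        u = np.asarray(y, dtype=float).reshape(-1)
        if k.shape != u.shape:
            raise ValueError("X and y must have matching lengths")
        if np.unique(k).size < 3:
            raise ValueError("need at least 3 distinct k values (3 free parameters)")
        if np.any(k <= 0) or not (np.all(np.isfinite(k)) and np.all(np.isfinite(u))):
            raise ValueError("k must be positive and u finite")
        w = np.ones_like(u) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        sw = np.sqrt(w)

        lo = np.array([0.0, 1e-9, 0.0])
        hi = np.array([np.inf, self.beta_max, np.inf])

        def residuals(theta):
            return sw * (_power_law(k, *theta) - u)

        def ssr(theta):
            return float(np.sum(residuals(theta) ** 2))

        g0 = max(float(u.min()), 0.0)
        a0 = max(float(u[np.argmin(k)]) - g0, 1e-8)
        x0 = np.clip([a0, 0.5, g0], lo, hi)

        sol, method = None, "gradient"
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if res.success and ssr(res.x) <= ssr(x0) + _SSR_ZERO:
                sol = res
        except Exception:
            sol = None
        if sol is None:
            method = "grid"
            best, best_ssr = x0, ssr(x0)
            design = np.empty((k.size, 2))
            design[:, 1] = 1.0
            for b in np.arange(0.05, self.beta_max + 1e-9, 0.05):
                design[:, 0] = np.power(k, -b)
                coef, _ = nnls(design * sw[:, None], u * sw)
                cand = np.clip([coef[0], b, coef[1]], lo, hi)
                if ssr(cand) < best_ssr:
                    best, best_ssr = cand, ssr(cand)
            sol = least_squares(residuals, best, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)

        self.alpha_, self.beta_, self.gamma_ = (float(v) for v in sol.x)
        self.converged_ = bool(sol.success)
        self.method_ = method
        pred = _power_law(k, self.alpha_, self.beta_, self.gamma_)
        self.residuals_ = u - pred
        self.r2_ = _r2(u, pred, w)
        self.param_se_ = self._param_se(sol, k.size)
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _param_se(sol, n_points: int) -> np.ndarray | None:
        dof = n_points - 3
        if dof <= 0:
            return None
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (2.0 * sol.cost / dof)
        except np.linalg.LinAlgError:
            return None
        diag = np.diag(cov)
        if np.any(diag < 0):
            return None
        return np.sqrt(diag)

    def predict(self, X) -> np.ndarray:
        k = np.asarray(X, dtype=float).reshape(-1)
        if np.any(k <= 0):
            raise ValueError("k must be positive")
        return _power_law(k, self.alpha_, self.beta_, self.gamma_)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted (alpha, beta, gamma) with diagnostics."""

    alpha: float
    beta: float
    gamma: float
    r2: float
    converged: bool
    method: str
    residuals_percent: tuple[float, ...]
    param_se: tuple[float, float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "r2": self.r2,
            "converged": self.converged,
            "method": self.method,
            "residuals_percent": list(self.residuals_percent),
            "param_se": None if self.param_se is None else list(self.param_se),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLawFit":
        return cls(
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
            r2=float(d["r2"]),
            converged=bool(d["converged"]),
            method=str(d["method"]),
            residuals_percent=tuple(d["residuals_percent"]),
            param_se=None if d.get("param_se") is None else tuple(d["param_se"]),
        )


def fit_power_law(
    curve: PrecisionCurve, beta_max: float = 2.0, weight_by_n: bool = False
) -> PowerLawFit:
    """Fit U(k) = alpha * k**(-beta) + gamma to an empirical precision curve."""
    est = PowerLawDecay(beta_max=beta_max, weight_by_n=weight_by_n)
    weights = np.asarray(curve.n_samples, dtype=float) if weight_by_n else None
    est.fit(np.asarray(curve.k_values, dtype=float), np.asarray(curve.u_percent), sample_weight=weights)
    return PowerLawFit(
        alpha=est.alpha_,
        beta=est.beta_,
        gamma=est.gamma_,
        r2=est.r2_,
        converged=est.converged_,
        method=est.method_,
        residuals_percent=tuple(float(r) for r in est.residuals_),
        param_se=None if est.param_se_ is None else tuple(float(s) for s in est.param_se_),
    )


def evaluate(fit: PowerLawFit, k: float) -> float:
    """Predicted U(k) in percent; valid for any positive (also fractional) k."""
    if k <= 0:
        raise ValueError("k must be positive")
    return fit.alpha * k ** (-fit.beta) + fit.gamma


def asymptotic_floor(fit: PowerLawFit) -> float:
    """gamma: the k -> infinity limit of U(k), i.e. the residual relative
    imprecision of the WKP reference itself (approximately
    100 * sd(eps_wkp)/D_true) — the best achievable precision."""
    if not fit.converged:
        raise ValueError("fit did not converge; asymptote unreliable")
    return fit.gamma


def r_squared(fit: PowerLawFit, curve: PrecisionCurve) -> float:
    """1 - SSR/SST of the fit against an observed curve (SST about mean u)."""
    k = np.asarray(curve.k_values, dtype=float)
    u = np.asarray(curve.u_percent, dtype=float)
    pred = _power_law(k, fit.alpha, fit.beta, fit.gamma)
    return _r2(u, pred, np.ones_like(u))
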