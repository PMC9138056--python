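"""Nonlinear least-squares estimation of the incorporation-model parameters.

Both models are fitted by trust-region-reflective least squares
(:func:`scipy.optimize.least_squares`) with analytic residual Jacobians and a
Levenberg-Marquardt fallback for unbounded retries when the bounded solver
fails.  Initialization exploits the monotone shape of a relaxation curve:
``delta_eq`` starts at the last observed value, ``a`` at (first - last),
``c`` at -1 (pure dilution) and ``m`` near 0.

Bounds: ``c`` is confined to [-10, -0.01] (the system approaches equilibrium;
``c = -1`` is pure dilution and more negative values mean more metabolic
turnover) and ``m`` to [0, 1] per day (a negative metabolic constant is not
identified by this design).  Standard errors come from the scaled inverse
Gauss-Newton Hessian ``s^2 (J'J)^-1``; with the option
``se_from="replicates"`` they are instead the between-replicate standard
errors of per-replicate fits.

Non-convergence is reported through ``FitResult.converged`` — flagged, never
silently retried with a different start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import ModelDParams, ModelGParams

logger = logging.getLogger("isoturn")

C_BOUNDS = (-10.0, -0.01)
M_BOUNDS = (0.0, 1.0)


@dataclass
class FitResult:
    params: ModelGParams | ModelDParams
    covariance: np.ndarray
    r2: float
    n_obs: int
    residuals: np.ndarray
    converged: bool
    message: str = ""
    flags: list[str] = field(default_factory=list)


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R2 undefined")
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot


def _covariance(jac: np.ndarray, residuals: np.ndarray, n_free: int) -> np.ndarray:
    n = residuals.size
    dof = max(n - n_free, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((n_free, n_free), np.nan)
    return cov


def _finish(theta, cov, obs, pred, converged, message, flags, make_params):
    resid = obs - pred
    try:
        r2 = goodness_of_fit(obs, pred)
    except ValueError:
        r2 = math.nan
        flags = flags + ["zero-variance observations: R2 undefined"]
    params = make_params(theta, cov, r2)
    return FitResult(
        params=params,
        covariance=cov,
        r2=r2,
        n_obs=obs.size,
        residuals=resid,
        converged=converged,
        message=message,
        flags=flags,
    )


def fit_model_g(w_r, delta, se_from: str = "covariance", replicate_sets=None) -> FitResult:
    """Fit ``delta = delta_eq + a * w_r ** c`` to (weight-ratio, delta) pairs.

    Requires at least 4 distinct ``w_r`` values, all >= 1 (the series starts
    at the switch).  ``se_from="replicates"`` with ``replicate_sets`` (a list
    of per-replicate (w_r, delta) pairs) replaces the covariance SEs by
    between-replicate ones.
    """
    w_r = np.asarray(w_r, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if w_r.shape != delta.shape:
        raise ValueError("w_r and delta must have equal length")
    if np.unique(w_r).size < 4:
        raise ValueError("need >= 4 distinct weight ratios to fit 3 parameters")
    if np.any(w_r < 1):
        raise ValueError("all w_r must be >= 1 (observations start at the switch)")

    flags: list[str] = []
    order = np.argsort(w_r)
    d_first, d_last = delta[order[0]], delta[order[-1]]
    x0 = np.array([d_last, d_first - d_last, -1.0])
    lo = np.array([-np.inf, -np.inf, C_BOUNDS[0]])
    hi = np.array([np.inf, np.inf, C_BOUNDS[1]])

    def residual(theta):
        d_eq, a, c = theta
        return d_eq + a * w_r ** c - delta

    def jacobian(theta):
        _, a, c = theta
        wc = w_r ** c
        return np.column_stack([np.ones_like(w_r), wc, a * wc * np.log(w_r)])

    sol = least_squares(residual, x0, jac=jacobian, bounds=(lo, hi), method="trf")
    if not sol.success:
        logger.warning("model G trf solver failed (%s); retrying with LM", sol.message)
        sol = least_squares(residual, x0, jac=jacobian, method="lm")
        flags.append("bounded solver failed; Levenberg-Marquardt fallback used")
    converged = bool(sol.success)
    if not converged:
        flags.append("non-convergence: estimates are the last iterate")
    if np.ptp(delta) < 1e-9:
        flags.append("degenerate input: all delta equal, c unidentifiable")

    cov = _covariance(sol.jac, sol.fun, 3)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if se_from == "replicates":
        if not replicate_sets:
            raise ValueError("se_from='replicates' requires replicate_sets")
        reps = np.array(
            [fit_model_g(w, d).params for w, d in replicate_sets], dtype=object
        )
        vals = np.array([[p.delta_eq, p.a, p.c] for p in reps], dtype=float)
        se = vals.std(axis=0, ddof=1) / math.sqrt(len(reps))
        flags.append("SEs from between-replicate spread")
    elif se_from != "covariance":
        raise ValueError(f"unknown se_from {se_from!r}")

    def make(theta, cov, r2):
        # c is bounded strictly below 0, so the constructor invariant holds
        return ModelGParams(
            delta_eq=theta[0], a=theta[1], c=theta[2],
            se_delta_eq=se[0], se_c=se[2], r2=r2,
        )

    return _finish(sol.x, cov, delta, delta - sol.fun, converged, sol.message, flags, make)


def fit_model_d(t, delta, k: float, se_from: str = "covariance", replicate_sets=None) -> FitResult:
    """Fit ``delta = delta_eq + a * exp(-(m + k) t)`` with ``k`` held fixed.

    ``t`` is days since the diet switch; ``k`` (per day) comes from the
    replicate's dry-weight change and is not estimated.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if t.shape != delta.shape:
        raise ValueError("t and delta must have equal length")
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct times to fit 3 parameters")
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (days since the switch)")
    if k < 0:
        raise ValueError("k must be >= 0")

    flags: list[str] = []
    order = np.argsort(t)
    d_first, d_last = delta[order[0]], delta[order[-1]]
    x0 = np.array([d_last, d_first - d_last, 1e-4])
    lo = np.array([-np.inf, -np.inf, M_BOUNDS[0]])
    hi = np.array([np.inf, np.inf, M_BOUNDS[1]])

    def residual(theta):
        d_eq, a, m = theta
        return d_eq + a * np.exp(-(m + k) * t) - delta

    def jacobian(theta):
        _, a, m = theta
        e = np.exp(-(m + k) * t)
        return np.column_stack([np.ones_like(t), e, -a * t * e])

    sol = least_squares(residual, x0, jac=jacobian, bounds=(lo, hi), method="trf")
    if not sol.success:
        logger.warning("model D trf solver failed (%s); retrying with LM", sol.message)
        sol = least_squares(residual, x0, jac=jacobian, method="lm")
        flags.append("bounded solver failed; Levenberg-Marquardt fallback used")
    converged = bool(sol.success)
    if not converged:
        flags.append("non-convergence: estimates are the last iterate")
    if np.ptp(delta) < 1e-9:
        flags.append("degenerate input: all delta equal, m unidentifiable")

    cov = _covariance(sol.jac, sol.fun, 3)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if se_from == "replicates":
        if not replicate_sets:
            raise ValueError("se_from='replicates' requires replicate_sets")
        vals = np.array(
            [
                [p.delta_eq, p.a, p.m]
                for p in (fit_model_d(tt, dd, kk).params for tt, dd, kk in replicate_sets)
            ],
            dtype=float,
        )
        se = vals.std(axis=0, ddof=1) / math.sqrt(len(vals))
        flags.append("SEs from between-replicate spread")
    elif se_from != "covariance":
        raise ValueError(f"unknown se_from {se_from!r}")

    def make(theta, cov, r2):
        m = max(theta[2], 0.0)
        return ModelDParams(
            delta_eq=theta[0], a=theta[1], m=m, k=k,
            se_delta_eq=se[0], se_m=se[2], r2=r2,
        )

    return _finish(sol.x, cov, delta, delta - sol.fun, converged, sol.message, flags, make)


def confidence_intervals(result: FitResult, level: float = 0.95) -> np.ndarray:
    """t-based parameter confidence intervals from the fit covariance.

    Returns an array of (lower, upper) rows in the parameter order
    (delta_eq, a, c-or-m).  Uses n - 3 residual degrees of freedom.
    """
    from scipy.stats import t as t_dist

    dof = max(result.n_obs - 3, 1)
    q = t_dist.ppf(0.5 + level / 2.0, dof)
    se = np.sqrt(np.clip(np.diag(result.covariance), 0, np.inf))
    p = result.params
    center = np.array(
        [p.delta_eq, p.a, p.c if isinstance(p, ModelGParams) else p.m], dtype=float
    )
    return np.column_stack([center - q * se, center + q * se])
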