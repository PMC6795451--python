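"""Biexponential (two-compartment) serum-concentration model.

An IV-bolus dose of an antibody that distributes between a central and a
peripheral compartment produces a serum concentration-time curve that is a
sum of two decaying exponentials,

    C(t) = A e^(-alpha t) + B e^(-beta t),

where ``A`` and ``B`` are the hybrid zero-time intercepts (ug/mL) and
``alpha``, ``beta`` the hybrid first-order rate constants (1/day).  One term
describes the fast distribution phase, the other the slow elimination phase;
no ordering of the two rates is imposed.

This module provides the parameter container, closed-form evaluation and
integration (AUC), and a scikit-learn style nonlinear least-squares
estimator with curve-peeling initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BiexponentialParams",
    "PKFit",
    "BiexponentialPKModel",
    "concentration_at",
    "auc_closed_form",
    "auc_trapezoid",
    "fit_biexponential",
    "coefficient_of_determination",
]


@dataclass(frozen=True)
class BiexponentialParams:
    """Parameters of ``C(t) = A exp(-alpha t) + B exp(-beta t)``.

    All four parameters must be strictly positive: the intercepts because a
    bolus dose contributes positive concentration to both phases, the rates
    because the drug is cleared (C must decay to zero).
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "alpha", "beta"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def c0(self) -> float:
        """Concentration at t=0 (the full bolus), A + B."""
        return self.A + self.B

    def canonicalized(self) -> "BiexponentialParams":
        """Return an equivalent parameter set with alpha >= beta (fast term first)."""
        if self.alpha >= self.beta:
            return self
        return BiexponentialParams(self.B, self.A, self.beta, self.alpha)


def concentration_at(params: BiexponentialParams, t):
    """Evaluate C(t) at time(s) ``t`` (days); scalar in, scalar out.

    Raises ValueError for negative times: the model describes the decay
    after the bolus at t=0 only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    c = params.A * np.exp(-params.alpha * t) + params.B * np.exp(-params.beta * t)
    return c if c.ndim else float(c)


def auc_closed_form(params: BiexponentialParams, t0: float = 0.0, t1: float = math.inf) -> float:
    """Exact area under C(t) over [t0, t1] (ug/mL*day); t1 may be inf.

    Antiderivative of each exponential term:
    (A/alpha)(e^(-alpha t0) - e^(-alpha t1)) + (B/beta)(e^(-beta t0) - e^(-beta t1)).
    """
    if t0 < 0 or t1 < t0:
        raise ValueError(f"require 0 <= t0 <= t1, got [{t0}, {t1}]")
    ea1 = 0.0 if math.isinf(t1) else math.exp(-params.alpha * t1)
    eb1 = 0.0 if math.isinf(t1) else math.exp(-params.beta * t1)
    return (params.A / params.alpha) * (math.exp(-params.alpha * t0) - ea1) + (
        params.B / params.beta
    ) * (math.exp(-params.beta * t0) - eb1)


def auc_trapezoid(times, values) -> float:
    """Trapezoidal AUC over sampled (time, value) points; no extrapolation.

    This reproduces AUCs computed on the measured sampling grid (the
    noncompartmental convention), which on a convex decay curve slightly
    overestimates the exact integral.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("need >= 2 (time, value) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def coefficient_of_determination(observed, predicted) -> float:
    """R^2 = 1 - SS_res / SS_tot on the untransformed values.

    Returns NaN when the observations have zero variance (undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class PKFit:
    """Result of a biexponential fit: parameters, standard errors, R^2."""

    params: BiexponentialParams
    se: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    converged: bool = False
    message: str = ""
    degenerate: bool = False


def _curve_peel_init(t, y):
    """Deterministic starting values by classical curve peeling.

    Fit the log-linear terminal phase (last >=3 points) for the slow term,
    then the positive part of the residual for the fast term.  Falls back to
    crude heuristics when a phase cannot be resolved.
    """
    n = len(t)
    k_tail = max(3, n // 3)
    tt, yt = t[-k_tail:], y[-k_tail:]
    slope, intercept = np.polyfit(tt, np.log(np.maximum(yt, 1e-12)), 1)
    beta = max(-slope, 1e-6)
    B = max(math.exp(intercept), 1e-9)
    resid = y - B * np.exp(-beta * t)
    mask = (resid > 0) & (t < tt[0])
    if mask.sum() >= 2:
        slope2, intercept2 = np.polyfit(t[mask], np.log(resid[mask]), 1)
        alpha = max(-slope2, beta * 1.5)
        A = max(math.exp(intercept2), 1e-9)
    else:
        alpha = beta * 10.0
        A = max(y[0] - B, 0.1 * B)
    return A, B, alpha, beta


class BiexponentialPKModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares estimator for the biexponential decay curve.

    Optimizes (log A, log B, log alpha, log beta) so positivity holds by
    construction.  The constraint that the back-extrapolated C(0) = A + B
    must exceed the first post-dose measurement is enforced as a penalty
    residual active only when violated.

    Parameters
    ----------
    first_postdose_conc : float, optional
        First measured post-dose concentration; when given, C(0) is
        constrained to exceed it.
    canonicalize : bool, default False
        Report parameters with alpha >= beta (fast phase first).
    max_nfev : int
        Function-evaluation budget for the optimizer.

    Attributes
    ----------
    params_ : BiexponentialParams
    se_ : dict mapping parameter name to its standard error
    r_squared_ : float
    converged_ : bool
    degenerate_ : bool
        True when the two rate constants collapsed onto each other or one
        coefficient vanished (effectively mono-exponential data).
    """

    _PENALTY = 1e4

    def __init__(self, first_postdose_conc=None, canonicalize=False, max_nfev=2000):
        self.first_postdose_conc = first_postdose_conc
        self.canonicalize = canonicalize
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise ValueError("X and y must have the same length")
        if t.size < 5:
            raise ValueError("need at least 5 time points spanning both decay phases")
        if np.any(t < 0) or np.any(y <= 0):
            raise ValueError("times must be >= 0 and concentrations > 0")
        order = np.argsort(t)
        t, y = t[order], y[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be distinct")

        theta0 = np.log(_curve_peel_init(t, y))
        cmin = self.first_postdose_conc

        def residuals(theta):
            A, B, alpha, beta = np.exp(theta)
            r = A * np.exp(-alpha * t) + B * np.exp(-beta * t) - y
            if cmin is not None:
                r = np.append(r, self._PENALTY * max(0.0, cmin - (A + B)))
            return r

        res = least_squares(residuals, theta0, method="lm" if cmin is None else "trf",
                            max_nfev=self.max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        A, B, alpha, beta = np.exp(res.x)
        params = BiexponentialParams(A, B, alpha, beta)
        if self.canonicalize:
            params = params.canonicalized()
            A, B, alpha, beta = params.A, params.B, params.alpha, params.beta

        pred = concentration_at(params, t)
        r2 = coefficient_of_determination(y, pred)

        # Delta-method SEs: cov of log-params from the Gauss-Newton curvature,
        # scaled by param value to return SEs on the natural scale.
        n, p = t.size, 4
        se = {}
        converged = bool(res.success)
        if n > p:
            J = res.jac[:n, :]
            s2 = float(np.sum((pred - y) ** 2)) / (n - p)
            try:
                cov_log = np.linalg.inv(J.T @ J) * s2
                dlog = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
                se = dict(zip(("A", "B", "alpha", "beta"), np.exp(res.x) * dlog))
            except np.linalg.LinAlgError:
                converged = False
        rate_gap = abs(alpha - beta) / max(alpha, beta)
        degenerate = rate_gap < 1e-6 or min(A, B) < 1e-6 * max(A, B)

        self.params_ = params
        self.se_ = se
        self.r_squared_ = r2
        self.converged_ = converged and not degenerate
        self.degenerate_ = degenerate
        self.message_ = res.message
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(concentration_at(self.params_, t))

    def auc(self, t0: float = 0.0, t1: float = math.inf) -> float:
        """Closed-form AUC of the fitted curve over [t0, t1]."""
        return auc_closed_form(self.params_, t0, t1)

    def result_(self) -> PKFit:
        return PKFit(self.params_, self.se_, self.r_squared_,
                     self.converged_, self.message_, self.degenerate_)


def fit_biexponential(times, concentrations, first_postdose_conc=None,
                      canonicalize=False) -> PKFit:
    """Fit C(t) = A e^(-alpha t) + B e^(-beta t) to a concentration profile.

    Thin wrapper over :class:`BiexponentialPKModel`; returns a :class:`PKFit`
    carrying the parameters, delta-method standard errors, R^2 on the raw
    concentration scale, and convergence/degeneracy flags (mono-exponential
    data is flagged, not an error).
    """
    model = BiexponentialPKModel(first_postdose_conc=first_postdose_conc,
                                 canonicalize=canonicalize)
    model.fit(times, concentrations)
    return model.result_()
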