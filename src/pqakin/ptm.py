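"""First-order kinetics of increasing post-translational modifications.

Deamidation of asparagine and N-terminal pyroglutamate formation proceed in
serum as pseudo-first-order reactions on the pool of unmodified molecules,
so the modified fraction follows

    P(t) = 1 - (1 - P0) e^(-k t),

rising from the initial level ``P0`` toward complete conversion.  The
internal unit convention is strict: ``P0`` and P(t) are fractions in [0, 1]
and ``k`` is a fraction per day.  Percent-scale I/O is converted at the
boundary (a rate printed as "0.5394% per day" is 0.005394/day here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .pk import coefficient_of_determination

__all__ = [
    "FirstOrderPTMParams",
    "PTMFit",
    "FirstOrderPTMModel",
    "ptm_level_at",
    "fit_first_order_ptm",
]


@dataclass(frozen=True)
class FirstOrderPTMParams:
    """Parameters of the first-order modification law for one site.

    p0 : initial modified fraction in [0, 1].
    k : formation rate constant (fraction per day, >= 0).
    site : free-text site label (e.g. "Asn site 2").
    """

    p0: float
    k: float
    site: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError(f"p0 must be within [0, 1], got {self.p0!r}")
        if not (math.isfinite(self.k) and self.k >= 0.0):
            raise ValueError(f"k must be >= 0 and finite, got {self.k!r}")


def ptm_level_at(ptm: FirstOrderPTMParams, t):
    """Modified fraction P(t) = 1 - (1 - p0) e^(-k t) at time(s) t >= 0 (days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = 1.0 - (1.0 - ptm.p0) * np.exp(-ptm.k * t)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class PTMFit:
    """Result of a first-order PTM fit (parameters as fractions)."""

    params: FirstOrderPTMParams
    se: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    converged: bool = False
    message: str = ""


class FirstOrderPTMModel(RegressorMixin, BaseEstimator):
    """Least-squares estimator of (P0, k) for one modification site.

    P0 is estimated jointly with k (not pinned to the pre-dose sample) via a
    bounded trust-region fit with P0 in [0, 1] and k >= 0.

    Parameters
    ----------
    input_scale : {"percent", "fraction"}
        Scale of the y values passed to :meth:`fit` / returned by
        :meth:`predict`.  Fitted parameters are always fractions.
    site : str
        Label copied into the fitted parameter set.

    Attributes
    ----------
    params_ : FirstOrderPTMParams
    se_ : dict of standard errors (fraction scale)
    r_squared_ : float
    converged_ : bool
    """

    def __init__(self, input_scale="percent", site=""):
        self.input_scale = input_scale
        self.site = site

    def _to_fraction(self, y):
        if self.input_scale == "percent":
            return y / 100.0
        if self.input_scale == "fraction":
            return y
        raise ValueError(f"input_scale must be 'percent' or 'fraction', got {self.input_scale!r}")

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = self._to_fraction(np.asarray(y, dtype=float).reshape(-1))
        if t.size != y.size:
            raise ValueError("X and y must have the same length")
        if t.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(t < 0) or np.any((y < 0) | (y > 1)):
            raise ValueError("times must be >= 0 and levels within the valid range")
        order = np.argsort(t)
        t, y = t[order], y[order]

        constant = np.ptp(y) == 0.0
        if constant:
            params = FirstOrderPTMParams(float(y[0]), 0.0, self.site)
            self.params_, self.se_ = params, {"p0": 0.0, "k": 0.0}
            self.r_squared_ = float("nan")  # zero-variance data: R^2 undefined
            self.converged_ = True
            self.message_ = "constant series: k = 0"
            self.n_features_in_ = 1
            return self

        # crude slope-based start; clipped into the feasible box
        p0_init = float(np.clip(y[0], 1e-6, 1 - 1e-6))
        span = t[-1] - t[0]
        k_init = max((y[-1] - y[0]) / max(1.0 - p0_init, 1e-6) / max(span, 1e-6), 1e-8)

        def residuals(theta):
            p0, k = theta
            return 1.0 - (1.0 - p0) * np.exp(-k * t) - y

        res = least_squares(residuals, [p0_init, k_init],
                            bounds=([0.0, 0.0], [1.0, np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        p0, k = res.x
        params = FirstOrderPTMParams(float(p0), float(k), self.site)
        pred = ptm_level_at(params, t)
        n, p = t.size, 2
        se = {}
        if n > p:
            s2 = float(np.sum((pred - y) ** 2)) / (n - p)
            try:
                cov = np.linalg.inv(res.jac.T @ res.jac) * s2
                d = np.sqrt(np.maximum(np.diag(cov), 0.0))
                se = {"p0": float(d[0]), "k": float(d[1])}
            except np.linalg.LinAlgError:
                pass

        self.params_ = params
        self.se_ = se
        self.r_squared_ = coefficient_of_determination(y, pred)
        self.converged_ = bool(res.success)
        self.message_ = res.message
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        frac = np.asarray(ptm_level_at(self.params_, t))
        return frac * 100.0 if self.input_scale == "percent" else frac

    def result_(self) -> PTMFit:
        return PTMFit(self.params_, self.se_, self.r_squared_,
                      self.converged_, self.message_)


def fit_first_order_ptm(times, levels, input_scale="percent", site="") -> PTMFit:
    """Fit P(t) = 1 - (1 - P0) e^(-k t) to a modification time course.

    An all-equal series yields (P0 = level, k = 0) with an explanatory
    message rather than an optimizer failure.
    """
    model = FirstOrderPTMModel(input_scale=input_scale, site=site)
    model.fit(times, levels)
    return model.result_()
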