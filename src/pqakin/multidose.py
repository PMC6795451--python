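"""Repeated-dose predictions by linear superposition.

With linear (dose-proportional) kinetics, the concentration under repeated
identical doses is the sum of time-shifted single-dose curves.  For doses
given every ``tau`` days, the trough immediately before dose m (given at
time (m-1) tau) sums the m-1 earlier doses at ages tau..(m-1) tau, and the
peak immediately after adds the fresh bolus C(0) = A + B:

    C_pre(m)  = sum_{i=1}^{m-1} C(i tau)
    C_post(m) = C_pre(m) + C(0)

Each circulating dose has been modifying since it was given, so the variant
concentration weights every aged dose by its own modified fraction,
P(age) * C(age), and the observable modified *level* at a trough or peak is
the ratio of variant to total concentration.  As m grows these sums
converge geometrically to closed-form steady states; the steady-state
variant levels are

    P_pre(ss) = [A (1/(e^{a T}-1) - (1-P0)/(e^{(a+k) T}-1))
               + B (1/(e^{b T}-1) - (1-P0)/(e^{(b+k) T}-1))]
               / [A/(e^{a T}-1) + B/(e^{b T}-1)]

(T = tau, a/b the two rates) and the post-dose analogue adds P0 (A+B) to
the numerator and A+B to the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import ExposureSummary, pqa_auc_closed_form
from .pk import BiexponentialParams, auc_closed_form, concentration_at
from .ptm import FirstOrderPTMParams, ptm_level_at

__all__ = [
    "DoseRegimen",
    "superposed_concentration_at",
    "pre_dose_concentration",
    "post_dose_concentration",
    "steady_state_concentration",
    "pqa_pre_dose_concentration",
    "pqa_post_dose_concentration",
    "pqa_level_pre_dose",
    "pqa_level_post_dose",
    "steady_state_pqa_level",
    "doses_to_steady_state",
    "predict_regimen",
    "simplified_regimen_auc",
]


@dataclass(frozen=True)
class DoseRegimen:
    """Identical doses at times 0, tau, ..., (n_doses - 1) tau."""

    tau: float
    n_doses: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau!r}")
        if int(self.n_doses) != self.n_doses or self.n_doses < 1:
            raise ValueError(f"n_doses must be an integer >= 1, got {self.n_doses!r}")

    def dose_times(self) -> np.ndarray:
        return self.tau * np.arange(self.n_doses, dtype=float)


def _check_m(m: int) -> None:
    if int(m) != m or m < 1:
        raise ValueError(f"dose number m must be an integer >= 1, got {m!r}")


def superposed_concentration_at(pk: BiexponentialParams, regimen: DoseRegimen, t) -> float:
    """Total concentration at time t: sum of single-dose curves for all doses given by t.

    Right-continuous at dose instants (a dose at exactly t is included); use
    :func:`pre_dose_concentration` for the left limit.
    """
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    ages = t - regimen.dose_times()
    ages = ages[ages >= 0]
    return float(np.sum(concentration_at(pk, ages))) if ages.size else 0.0


def pre_dose_concentration(pk: BiexponentialParams, tau: float, m: int) -> float:
    """Trough immediately before dose m: sum_{i=1}^{m-1} C(i tau); 0 for m=1."""
    _check_m(m)
    if m == 1:
        return 0.0
    ages = tau * np.arange(1, m, dtype=float)
    return float(np.sum(concentration_at(pk, ages)))


def post_dose_concentration(pk: BiexponentialParams, tau: float, m: int) -> float:
    """Peak immediately after dose m: the trough plus the fresh bolus A + B."""
    return pre_dose_concentration(pk, tau, m) + pk.c0


def steady_state_concentration(pk: BiexponentialParams, tau: float, phase: str = "pre") -> float:
    """Limit of the trough ("pre") or peak ("post") as the dose count grows.

    Geometric-series closed form: pre = A/(e^{alpha tau}-1) + B/(e^{beta tau}-1);
    post adds A + B.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")

    def accum(coef, rate):
        x = rate * tau
        return 0.0 if x > 700 else coef / math.expm1(x)  # e^x overflows past ~709

    pre = accum(pk.A, pk.alpha) + accum(pk.B, pk.beta)
    if phase == "pre":
        return pre
    if phase == "post":
        return pre + pk.c0
    raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")


def pqa_pre_dose_concentration(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                               tau: float, m: int) -> float:
    """Variant trough before dose m: each aged dose contributes P(age) C(age)."""
    _check_m(m)
    if m == 1:
        return 0.0
    ages = tau * np.arange(1, m, dtype=float)
    return float(np.sum(concentration_at(pk, ages) * ptm_level_at(ptm, ages)))


def pqa_post_dose_concentration(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                                tau: float, m: int) -> float:
    """Variant peak after dose m: the trough plus the fresh bolus at level P0."""
    return pqa_pre_dose_concentration(pk, ptm, tau, m) + ptm.p0 * pk.c0


def pqa_level_pre_dose(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                       tau: float, m: int) -> float:
    """Modified fraction at the trough before dose m (ratio of variant to total)."""
    _check_m(m)
    if m < 2:
        raise ValueError("pre-dose level undefined before the first dose (m >= 2)")
    denom = pre_dose_concentration(pk, tau, m)
    return pqa_pre_dose_concentration(pk, ptm, tau, m) / denom


def pqa_level_post_dose(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                        tau: float, m: int) -> float:
    """Modified fraction at the peak after dose m; equals P0 at the first dose."""
    _check_m(m)
    return pqa_post_dose_concentration(pk, ptm, tau, m) / post_dose_concentration(pk, tau, m)


def _series_pqa_numerator(pk, ptm, tau, n_terms, tol=1e-14):
    """sum_{i=1}^{n} P(i tau) C(i tau), stopping early once terms are negligible."""
    total = 0.0
    chunk = 4096
    i0 = 1
    while i0 <= n_terms:
        i = np.arange(i0, min(i0 + chunk, n_terms + 1), dtype=float)
        terms = concentration_at(pk, i * tau) * ptm_level_at(ptm, i * tau)
        total += float(np.sum(terms))
        if terms[-1] < tol * max(total, 1e-300):
            return total, True
        i0 += chunk
    return total, False


def steady_state_pqa_level(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                           tau: float, phase: str = "pre", method: str = "closed_form",
                           n_terms: int = 100_000) -> float:
    """Steady-state modified fraction at the trough ("pre") or peak ("post").

    method="closed_form" evaluates the geometric-series limits exactly;
    method="series" sums the age-weighted contributions term by term (capped
    at ``n_terms``, raising if the sum has not converged), which serves as
    an independent numerical check of the closed forms.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if phase not in ("pre", "post"):
        raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")

    if method == "closed_form":
        def g(rate):
            x = rate * tau
            return 0.0 if x > 700 else 1.0 / math.expm1(x)

        numer = pk.A * (g(pk.alpha) - (1.0 - ptm.p0) * g(pk.alpha + ptm.k)) + \
            pk.B * (g(pk.beta) - (1.0 - ptm.p0) * g(pk.beta + ptm.k))
        denom = steady_state_concentration(pk, tau, "pre")
    elif method == "series":
        numer, ok = _series_pqa_numerator(pk, ptm, tau, n_terms)
        if not ok:
            raise RuntimeError(
                f"series did not converge within {n_terms} terms; "
                "increase n_terms or use method='closed_form'")
        denom = steady_state_concentration(pk, tau, "pre")
    else:
        raise ValueError(f"unknown method {method!r}")

    if phase == "post":
        numer += ptm.p0 * pk.c0
        denom += pk.c0
    return numer / denom


def doses_to_steady_state(pk: BiexponentialParams, ptm: FirstOrderPTMParams | None,
                          tau: float, tolerance: float = 0.01, max_doses: int = 10_000) -> int:
    """Smallest dose count after which troughs and peaks sit within ``tolerance``
    (relative) of their steady-state values.

    When a PTM parameter set is supplied the variant levels must converge
    too, not just the total concentrations.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ss = [steady_state_concentration(pk, tau, ph) for ph in ("pre", "post")]
    targets = [
        (lambda m, ph=ph: pre_dose_concentration(pk, tau, m) if ph == "pre"
         else post_dose_concentration(pk, tau, m), s)
        for ph, s in zip(("pre", "post"), ss)
    ]
    if ptm is not None:
        for ph in ("pre", "post"):
            s = steady_state_pqa_level(pk, ptm, tau, ph)
            fn = (lambda m, ph=ph: (pqa_level_pre_dose(pk, ptm, tau, m) if m >= 2 else 0.0)
                  if ph == "pre" else pqa_level_post_dose(pk, ptm, tau, m))
            targets.append((fn, s))
    for m in range(1, max_doses + 1):
        if all(abs(fn(m) - s) <= tolerance * abs(s) for fn, s in targets):
            return m
    raise RuntimeError(f"no convergence within {max_doses} doses")


def predict_regimen(pk: BiexponentialParams, ptm: FirstOrderPTMParams | None,
                    regimen: DoseRegimen) -> pd.DataFrame:
    """Per-dose trough/peak table for a regimen (concentrations, variant
    concentrations and variant levels in percent), one row per dose."""
    rows = []
    for m in range(1, regimen.n_doses + 1):
        row = {
            "dose_index": m,
            "time_days": (m - 1) * regimen.tau,
            "pre_conc": pre_dose_concentration(pk, regimen.tau, m),
            "post_conc": post_dose_concentration(pk, regimen.tau, m),
        }
        if ptm is not None:
            row["pre_pqa_conc"] = pqa_pre_dose_concentration(pk, ptm, regimen.tau, m)
            row["post_pqa_conc"] = pqa_post_dose_concentration(pk, ptm, regimen.tau, m)
            row["pre_level_pct"] = (100.0 * pqa_level_pre_dose(pk, ptm, regimen.tau, m)
                                    if m >= 2 else float("nan"))
            row["post_level_pct"] = 100.0 * pqa_level_post_dose(pk, ptm, regimen.tau, m)
        rows.append(row)
    return pd.DataFrame(rows)


def simplified_regimen_auc(pk: BiexponentialParams, ptm: FirstOrderPTMParams | None,
                           regimen: DoseRegimen, window: float) -> ExposureSummary:
    """Multiple-dose exposure over [0, window] from trough/peak values only.

    The first dosing interval is integrated exactly (closed form on the
    single-dose curve); every later interval is approximated by a straight
    line from its peak (post-dose) to the next trough (pre-dose), i.e. a
    trapezoid of width tau.  The same construction applies to the variant
    curve using the age-weighted trough/peak values.  Windows shorter than
    one interval fall back to the single-dose integral.
    """
    tau = regimen.tau
    if window <= 0:
        raise ValueError("window must be positive")
    if window < tau:  # sub-interval window: plain single-dose exposure
        total = auc_closed_form(pk, 0.0, window)
        pqa = total if ptm is None else pqa_auc_closed_form(pk, ptm, 0.0, window)
        return ExposureSummary(0.0, window, total, pqa)
    n_int = int(round(window / tau))
    if abs(n_int * tau - window) > 1e-9 * max(tau, window):
        raise ValueError("window must be a whole number of dosing intervals")
    n_int = min(n_int, regimen.n_doses)  # no doses beyond the regimen

    total = auc_closed_form(pk, 0.0, tau)
    # interval following dose m (m = 2..n_int): peak of dose m -> trough of dose m+1
    for m in range(2, n_int + 1):
        total += tau * (post_dose_concentration(pk, tau, m)
                        + pre_dose_concentration(pk, tau, m + 1)) / 2.0

    if ptm is None:
        return ExposureSummary(0.0, n_int * tau, total, total)

    pqa = pqa_auc_closed_form(pk, ptm, 0.0, tau)
    for m in range(2, n_int + 1):
        pqa += tau * (pqa_post_dose_concentration(pk, ptm, tau, m)
                      + pqa_pre_dose_concentration(pk, ptm, tau, m + 1)) / 2.0
    return ExposureSummary(0.0, n_int * tau, total, pqa)
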