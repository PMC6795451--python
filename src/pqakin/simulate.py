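"""Synthetic single- and multiple-dose study data.

Generates concentration and PTM-level tables with the statistical structure
the analysis assumes: biexponential decay (superposed across doses for a
repeated regimen), first-order PTM accrual diluted by each fresh dose, and
assay noise — multiplicative lognormal on concentrations (constant CV, the
usual ELISA error structure) and additive Gaussian in percentage points on
PTM levels (truncated to [0, 100]).  Concentration noise and PTM noise draw
from independent child streams of the master seed, so changing one never
perturbs the other and a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .multidose import (
    DoseRegimen,
    pqa_level_post_dose,
    pqa_level_pre_dose,
    post_dose_concentration,
    pre_dose_concentration,
    superposed_concentration_at,
)
from .pk import BiexponentialParams, concentration_at, fit_biexponential
from .ptm import FirstOrderPTMParams, fit_first_order_ptm, ptm_level_at

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "simulate_single_dose_study",
    "simulate_multidose_study",
    "parameter_recovery_experiment",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan: regimen, plain sampling times, trough/peak instants."""

    regimen: DoseRegimen
    sample_times: tuple = ()
    pre_post_times: tuple = ()
    n_subjects: int = 1

    def __post_init__(self) -> None:
        for ts in (self.sample_times, self.pre_post_times):
            arr = np.asarray(ts, dtype=float)
            if arr.size and (np.any(arr < 0) or np.any(np.diff(arr) < 0)):
                raise ValueError("sampling times must be non-negative and sorted")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @classmethod
    def single_dose_default(cls, n_subjects: int = 1) -> "StudyDesign":
        """One IV dose, the standard 12-point 56-day collection schedule."""
        return cls(DoseRegimen(tau=56.0, n_doses=1),
                   sample_times=tuple(reference.SINGLE_DOSE_SAMPLING_DAYS),
                   n_subjects=n_subjects)

    @classmethod
    def multi_dose_default(cls, n_subjects: int = 1) -> "StudyDesign":
        """Five biweekly doses: dense first interval, trough/peak pairs after."""
        return cls(reference.BIWEEKLY_5_DOSES,
                   sample_times=tuple(reference.MULTI_DOSE_FIRST_INTERVAL_DAYS),
                   pre_post_times=tuple(reference.MULTI_DOSE_PREPOST_DAYS),
                   n_subjects=n_subjects)


@dataclass(frozen=True)
class NoiseModel:
    """Assay-noise settings.

    conc_cv : proportional CV of the concentration assay (fraction).
    ptm_sd_pct : additive SD of PTM levels, in percentage points.
    seed : master seed; concentration and PTM streams are independent
        children of it.
    """

    conc_cv: float = 0.05
    ptm_sd_pct: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_cv < 0 or self.ptm_sd_pct < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def streams(self):
        c1, c2 = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(c1), np.random.default_rng(c2)


def _apply_conc_noise(values, cv, rng):
    if cv == 0:
        return np.asarray(values, dtype=float)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.asarray(values, dtype=float) * np.exp(rng.normal(0.0, sigma, size=len(values)))


def _apply_ptm_noise(pct, sd, rng):
    if sd == 0:
        return np.asarray(pct, dtype=float)
    return np.clip(np.asarray(pct, dtype=float) + rng.normal(0.0, sd, size=len(pct)), 0.0, 100.0)


def simulate_single_dose_study(pk: BiexponentialParams, ptms, design: StudyDesign,
                               noise: NoiseModel):
    """Simulate one single-dose study.

    Returns (conc, ptm) DataFrames in the standard dialects: conc has
    subject_id, time_days, conc_ug_per_ml; ptm has subject_id, site_id,
    time_days, ptm_percent (one block per site).
    """
    rng_c, rng_p = noise.streams()
    t = np.asarray(design.sample_times, dtype=float)
    conc_rows, ptm_rows = [], []
    for s in range(design.n_subjects):
        subject = f"subject_{s + 1}"
        conc = _apply_conc_noise(concentration_at(pk, t), noise.conc_cv, rng_c)
        conc_rows.append(pd.DataFrame(
            {"subject_id": subject, "time_days": t, "conc_ug_per_ml": conc}))
        for ptm in ptms:
            pct = _apply_ptm_noise(100.0 * ptm_level_at(ptm, t), noise.ptm_sd_pct, rng_p)
            ptm_rows.append(pd.DataFrame(
                {"subject_id": subject, "site_id": ptm.site, "time_days": t,
                 "ptm_percent": pct}))
    conc_df = pd.concat(conc_rows, ignore_index=True)
    ptm_df = (pd.concat(ptm_rows, ignore_index=True) if ptm_rows
              else pd.DataFrame(columns=["subject_id", "site_id", "time_days", "ptm_percent"]))
    return conc_df, ptm_df


def _multidose_model_values(pk, ptm, regimen, sample_times, pre_post_times):
    """Noise-free (time, phase, conc, level_pct) rows for a repeated regimen.

    Plain times use the right-continuous superposed curve; trough/peak
    instants use the left-limit (pre) and bolus-included (post) values.
    """
    rows = []
    for t in sample_times:
        c = superposed_concentration_at(pk, regimen, t)
        lvl = None
        if ptm is not None:
            # level at an arbitrary instant: age-weighted mean over doses on board
            ages = t - regimen.dose_times()
            ages = ages[ages >= 0]
            num = float(np.sum(concentration_at(pk, ages) * ptm_level_at(ptm, ages)))
            lvl = 100.0 * num / c if c > 0 else float("nan")
        rows.append((t, "sample", c, lvl))
    for t in pre_post_times:
        m = int(round(t / regimen.tau)) + 1  # dose number administered at t
        rows.append((t, "pre", pre_dose_concentration(pk, regimen.tau, m),
                     None if ptm is None else
                     100.0 * pqa_level_pre_dose(pk, ptm, regimen.tau, m)))
        if m <= regimen.n_doses:
            rows.append((t, "post", post_dose_concentration(pk, regimen.tau, m),
                         None if ptm is None else
                         100.0 * pqa_level_post_dose(pk, ptm, regimen.tau, m)))
    return rows


def simulate_multidose_study(pk: BiexponentialParams, ptms, design: StudyDesign,
                             noise: NoiseModel):
    """Simulate one repeated-dose study; as the single-dose variant but with
    a ``phase`` column ('sample', 'pre', 'post') since trough/peak pairs
    share a clock time."""
    rng_c, rng_p = noise.streams()
    conc_rows, ptm_rows = [], []
    base = _multidose_model_values(pk, None, design.regimen,
                                   design.sample_times, design.pre_post_times)
    per_site = {p.site: _multidose_model_values(pk, p, design.regimen,
                                                design.sample_times, design.pre_post_times)
                for p in ptms}
    for s in range(design.n_subjects):
        subject = f"subject_{s + 1}"
        times = [r[0] for r in base]
        phases = [r[1] for r in base]
        conc = _apply_conc_noise([r[2] for r in base], noise.conc_cv, rng_c)
        conc_rows.append(pd.DataFrame(
            {"subject_id": subject, "time_days": times, "phase": phases,
             "conc_ug_per_ml": conc}))
        for site, rows in per_site.items():
            pct = _apply_ptm_noise([r[3] for r in rows], noise.ptm_sd_pct, rng_p)
            ptm_rows.append(pd.DataFrame(
                {"subject_id": subject, "site_id": site, "time_days": [r[0] for r in rows],
                 "phase": [r[1] for r in rows], "ptm_percent": pct}))
    conc_df = pd.concat(conc_rows, ignore_index=True)
    ptm_df = (pd.concat(ptm_rows, ignore_index=True) if ptm_rows
              else pd.DataFrame(columns=["subject_id", "site_id", "time_days",
                                         "phase", "ptm_percent"]))
    return conc_df, ptm_df


def parameter_recovery_experiment(pk: BiexponentialParams, ptm: FirstOrderPTMParams,
                                  n_replicates: int = 100, conc_cv: float = 0.05,
                                  ptm_sd_pct: float = 0.3, seed: int = 0,
                                  design: StudyDesign | None = None) -> pd.DataFrame:
    """Monte-Carlo check that fitting recovers the generating parameters.

    Simulates ``n_replicates`` single-dose studies at the given noise
    levels, refits each, and reports per-parameter bias, RMSE, and the
    median absolute relative error.  Each replicate uses an independent
    child stream of ``seed``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    design = design or StudyDesign.single_dose_default()
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    truth = {"A": pk.A, "B": pk.B, "alpha": pk.alpha, "beta": pk.beta,
             "p0": ptm.p0, "k": ptm.k}
    est = {name: [] for name in truth}
    for child in children:
        nm = NoiseModel(conc_cv, ptm_sd_pct, seed=child.entropy % (2**31))
        conc, ptm_df = simulate_single_dose_study(pk, [ptm], design, nm)
        fit = fit_biexponential(conc["time_days"], conc["conc_ug_per_ml"])
        # order the fitted terms to match the fast/slow roles of the truth
        p = fit.params.canonicalized()
        if pk.alpha < pk.beta:
            p = BiexponentialParams(p.B, p.A, p.beta, p.alpha)
        est["A"].append(p.A)
        est["B"].append(p.B)
        est["alpha"].append(p.alpha)
        est["beta"].append(p.beta)
        pfit = fit_first_order_ptm(ptm_df["time_days"], ptm_df["ptm_percent"],
                                   input_scale="percent", site=ptm.site)
        est["p0"].append(pfit.params.p0)
        est["k"].append(pfit.params.k)
    rows = []
    for name, values in est.items():
        v = np.asarray(values)
        tr = truth[name]
        err = v - tr
        rows.append({
            "parameter": name,
            "truth": tr,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_abs_rel_err": float(np.median(np.abs(err) / abs(tr))) if tr != 0 else float("nan"),
        })
    return pd.DataFrame(rows)
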