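"""Two-sample two-stage least-squares (TSTSLS) causal estimator.

Stage 1 regresses the microbiome exposure (log P/B ratio) on the antibiotic
usage count by ordinary least squares in the microbiome cohort; stage 2
regresses incident disease status on the same count by maximum-likelihood
logistic regression in the outcome cohort. The causal effect of the
exposure on disease is the ratio of coefficients

    beta_D,MB = beta_D,hAB / beta_MB,hAB

with the delta-method (Pacini-Windmeijer) standard error

    se_D,MB = sqrt((se_D,hAB^2 + beta_D,MB^2 * se_MB,hAB^2) / beta_MB,hAB^2).

Wald z-scores against the standard normal give p-values and the
confidence interval is beta +/- 1.96 * se. Multiplicity across the disease
panel is handled by Benjamini-Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import INSTRUMENT_COLUMNS

__all__ = [
    "Stage1Fit",
    "Stage2Fit",
    "CausalEstimate",
    "WeakInstrumentError",
    "WeakInstrumentWarning",
    "SeparationError",
    "fit_stage1_linear",
    "fit_stage2_logistic",
    "tstsls_ratio",
    "bh_fdr",
    "run_disease_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = [
    "disease", "instrument", "n_cases", "n_controls",
    "beta_mb_hab", "se_mb_hab", "beta_d_hab", "se_d_hab",
    "beta_d_mb", "se_d_mb", "z", "p", "p_fdr", "ci_low", "ci_high", "status",
]


class WeakInstrumentError(ValueError):
    """The instrument carries no usable signal (zero variance or zero slope)."""


class WeakInstrumentWarning(UserWarning):
    """Stage-1 slope is within ``weak_z_threshold`` standard errors of zero."""


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


@dataclass(frozen=True)
class Stage1Fit:
    """Instrument -> exposure linear-regression slope and standard error."""

    beta_mb_hab: float
    se_mb_hab: float
    n: int
    instrument_name: str


@dataclass(frozen=True)
class Stage2Fit:
    """Instrument -> outcome logistic-regression slope and standard error."""

    beta_d_hab: float
    se_d_hab: float
    n_cases: int
    n_controls: int
    disease: str


@dataclass(frozen=True)
class CausalEstimate:
    """Ratio-of-coefficients causal estimate with Wald inference."""

    beta_d_mb: float
    se_d_mb: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    p_fdr: float
    disease: str
    instrument: str


def _design(df, xcol, covariates):
    cols = [df[xcol].astype(float)]
    names = [xcol]
    for cov in covariates or []:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c])
                names.append(c)
        else:
            cols.append(col.astype(float))
            names.append(cov)
    X = pd.concat(cols, axis=1)
    X.columns = names
    return sm.add_constant(X, has_constant="add")


def fit_stage1_linear(mb, exposure, instrument="total", covariates=None,
                      value_col="log_pb"):
    """OLS of the microbiome exposure on the antibiotic count.

    ``mb`` (person_id, log_pb) is inner-joined with the exposure table;
    covariates, when given, enter additively. Raises
    :class:`WeakInstrumentError` if the instrument column has zero variance.
    """
    xcol = INSTRUMENT_COLUMNS[instrument]
    df = mb.merge(exposure, on="person_id", how="inner")
    if len(df) < 3:
        raise ValueError("stage 1 requires at least 3 joined observations")
    if df[xcol].nunique() < 2:
        raise WeakInstrumentError(f"instrument {instrument!r} has zero variance")
    X = _design(df, xcol, covariates)
    res = sm.OLS(df[value_col].astype(float), X).fit()
    return Stage1Fit(
        beta_mb_hab=float(res.params[xcol]),
        se_mb_hab=float(res.bse[xcol]),
        n=int(len(df)),
        instrument_name=instrument,
    )


def fit_stage2_logistic(outcomes, exposure, disease, instrument="total",
                        covariates=None):
    """ML logistic regression of incident status on the antibiotic count.

    Persons classified ``prevalent_excluded`` for the disease are dropped;
    ``incident`` codes as 1 and ``censored_nonevent`` as 0. Raises
    :class:`SeparationError` on perfect separation or non-convergence and
    ``ValueError`` when there are no cases (or no controls) after joining.
    """
    xcol = INSTRUMENT_COLUMNS[instrument]
    sub = outcomes[outcomes["disease"] == disease]
    if sub.empty:
        raise ValueError(f"no outcome rows for disease {disease!r}")
    sub = sub[sub["status"] != "prevalent_excluded"]
    df = sub.merge(exposure, on="person_id", how="inner")
    y = (df["status"] == "incident").astype(float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0:
        raise ValueError(f"no incident cases for disease {disease!r}")
    if n_controls == 0:
        raise ValueError(f"no controls for disease {disease!r}")

    X = _design(df, xcol, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, ConvergenceWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed for {disease!r}: {exc}") from exc
    beta = float(res.params[xcol])
    se = float(res.bse[xcol])
    if not (np.isfinite(beta) and np.isfinite(se)) or abs(beta) > 50:
        raise SeparationError(f"diverging logistic fit for {disease!r}")
    return Stage2Fit(
        beta_d_hab=beta, se_d_hab=se,
        n_cases=n_cases, n_controls=n_controls, disease=disease,
    )


def tstsls_ratio(stage1: Stage1Fit, stage2: Stage2Fit, ci_multiplier=1.96,
                 weak_z_threshold=2.0) -> CausalEstimate:
    """Combine the two stage fits into the ratio causal estimate.

    Emits :class:`WeakInstrumentWarning` when the stage-1 slope is within
    ``weak_z_threshold`` standard errors of zero (the delta-method variance
    is unreliable there) and raises :class:`WeakInstrumentError` when it is
    exactly zero.
    """
    b1, s1 = stage1.beta_mb_hab, stage1.se_mb_hab
    if b1 == 0:
        raise WeakInstrumentError("stage-1 slope is zero; ratio undefined")
    if weak_z_threshold is not None and s1 > 0 and abs(b1 / s1) < weak_z_threshold:
        warnings.warn(
            f"weak instrument: |stage-1 z| = {abs(b1 / s1):.2f} < {weak_z_threshold}",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    beta = stage2.beta_d_hab / b1
    se = float(np.sqrt((stage2.se_d_hab**2 + beta**2 * s1**2) / b1**2))
    if se > 0:
        z = beta / se
        p = float(2.0 * norm.sf(abs(z)))
    else:  # degenerate: both stage SEs are zero
        z = np.inf * np.sign(beta) if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    return CausalEstimate(
        beta_d_mb=float(beta),
        se_d_mb=se,
        z=float(z),
        p=p,
        ci_low=float(beta - ci_multiplier * se),
        ci_high=float(beta + ci_multiplier * se),
        p_fdr=float("nan"),
        disease=stage2.disease,
        instrument=stage1.instrument_name,
    )


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_disease_panel(mb, exposure_s2, exposure_s1, outcomes, diseases=None,
                      instrument="total", covariates=None, min_cases=50,
                      ci_multiplier=1.96, weak_z_threshold=2.0) -> pd.DataFrame:
    """Run the full panel: one shared stage-1 fit, one stage-2 fit per disease.

    Diseases with fewer than ``min_cases`` incident cases in the analysis
    set, or whose logistic fit separates, are reported with a skip status
    and excluded from the FDR adjustment, which is computed across the
    successfully estimated panel.
    """
    if diseases is None:
        diseases = list(dict.fromkeys(outcomes["disease"]))
    if len(diseases) == 0:
        raise ValueError("empty disease list")
    stage1 = fit_stage1_linear(mb, exposure_s2, instrument=instrument,
                               covariates=covariates)
    persons = set(exposure_s1["person_id"])
    oc = outcomes[outcomes["person_id"].isin(persons)]

    rows = []
    for disease in diseases:
        base = {
            "disease": disease,
            "instrument": instrument,
            "beta_mb_hab": stage1.beta_mb_hab,
            "se_mb_hab": stage1.se_mb_hab,
        }
        sub = oc[oc["disease"] == disease]
        n_inc = int((sub["status"] == "incident").sum())
        if n_inc < min_cases:
            rows.append({**base, "n_cases": n_inc, "status": "too_few_cases"})
            continue
        try:
            stage2 = fit_stage2_logistic(oc, exposure_s1, disease,
                                         instrument=instrument, covariates=covariates)
            est = tstsls_ratio(stage1, stage2, ci_multiplier=ci_multiplier,
                               weak_z_threshold=weak_z_threshold)
        except SeparationError:
            rows.append({**base, "n_cases": n_inc, "status": "separation"})
            continue
        rows.append(
            {
                **base,
                "n_cases": stage2.n_cases,
                "n_controls": stage2.n_controls,
                "beta_d_hab": stage2.beta_d_hab,
                "se_d_hab": stage2.se_d_hab,
                "beta_d_mb": est.beta_d_mb,
                "se_d_mb": est.se_d_mb,
                "z": est.z,
                "p": est.p,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "status": "ok",
            }
        )
    panel = pd.DataFrame(rows)
    panel["p_fdr"] = np.nan
    ok = panel["status"] == "ok"
    if ok.any():
        panel.loc[ok, "p_fdr"] = bh_fdr(panel.loc[ok, "p"].to_numpy())
    for col in PANEL_COLUMNS:
        if col not in panel.columns:
            panel[col] = np.nan
    return panel[PANEL_COLUMNS]
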