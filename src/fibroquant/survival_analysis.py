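"""Kaplan–Meier incidence, log-rank tests, and Cox models with backward elimination.

Thin, typed wrappers around lifelines that fix the study's conventions:
follow-up truncated at 3 years (administrative censoring), events precede
censorings at tied times, Efron approximation for tied event times in the
Cox partial likelihood, Wald confidence intervals on the log hazard ratio,
univariate screening at p < 0.1 followed by backward elimination until all
retained covariates have p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .clinical_scores import CutoffRule

DEFAULT_HORIZON_YEARS = 3.0


def truncate_followup(times, events, horizon: float = DEFAULT_HORIZON_YEARS):
    """Administratively censor at the horizon (event times past it become
    censorings at the horizon)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with at-risk counts and cumulative incidence."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_incidence_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    covariates: tuple[str, ...]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.covariates),
                "hr": [self.hazard_ratios[c] for c in self.covariates],
                "ci_lower": [self.ci_lower[c] for c in self.covariates],
                "ci_upper": [self.ci_upper[c] for c in self.covariates],
                "p": [self.p_values[c] for c in self.covariates],
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimator; ties resolved events-before-censorings."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    ev = kmf.event_table
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two (times, events) groups.

    Returns (chi-square statistic, two-sided p).  With no events in either
    group the statistic is 0 and p = 1.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("each group needs at least one subject")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _fit_cox(
    df: pd.DataFrame,
    covariate_cols: list[str],
    duration_col: str,
    event_col: str,
) -> CoxFit:
    data = df[[duration_col, event_col, *covariate_cols]].astype(float).dropna()
    cph = CoxPHFitter()  # Efron ties (lifelines default)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        nan = {c: float("nan") for c in covariate_cols}
        return CoxFit(
            covariates=tuple(covariate_cols),
            hazard_ratios=dict(nan),
            ci_lower=dict(nan),
            ci_upper=dict(nan),
            p_values=dict(nan),
            log_likelihood=float("nan"),
            n=len(data),
            n_events=int(data[event_col].sum()),
            converged=False,
            message=str(exc),
        )
    s = cph.summary
    return CoxFit(
        covariates=tuple(covariate_cols),
        hazard_ratios={c: float(s.loc[c, "exp(coef)"]) for c in covariate_cols},
        ci_lower={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariate_cols},
        ci_upper={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariate_cols},
        p_values={c: float(s.loc[c, "p"]) for c in covariate_cols},
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data[event_col].sum()),
    )


def _indicator_column(df: pd.DataFrame, rule: CutoffRule | str) -> tuple[pd.DataFrame, str]:
    if isinstance(rule, str):
        return df, rule
    col = f"{rule.variable}_high"
    out = df.copy()
    out[col] = rule.apply(df[rule.variable])
    return out, col


def cox_univariate(
    df: pd.DataFrame,
    rule: CutoffRule | str,
    duration_col: str = "time_years",
    event_col: str = "event",
) -> CoxFit:
    """Single-covariate proportional-hazards fit for a cutoff rule (or an
    existing binary column).  Monotone-likelihood cases come back flagged
    ``converged=False`` rather than raising."""
    data, col = _indicator_column(df, rule)
    return _fit_cox(data, [col], duration_col, event_col)


@dataclass(frozen=True)
class BackwardEliminationResult:
    """Final multivariate fit plus the full audit trail."""

    final: CoxFit | None
    screened_in: tuple[str, ...]
    univariate: dict[str, CoxFit]
    audit: tuple[str, ...] = field(default_factory=tuple)


def cox_multivariate_backward(
    df: pd.DataFrame,
    candidates: list[CutoffRule | str],
    p_enter: float = 0.1,
    p_stay: float = 0.05,
    duration_col: str = "time_years",
    event_col: str = "event",
) -> BackwardEliminationResult:
    """Univariate screen (p < p_enter) then backward elimination (drop the
    worst covariate while any p ≥ p_stay), refitting after each removal.

    Terminates in at most |candidates| refits; the final model, if any, has
    all p-values below ``p_stay``.  An empty screen returns ``final=None``
    with the audit trail explaining why.
    """
    data = df
    cols: list[str] = []
    for cand in candidates:
        data, col = _indicator_column(data, cand)
        cols.append(col)

    audit: list[str] = []
    uni: dict[str, CoxFit] = {}
    kept: list[str] = []
    for col in cols:
        fit = _fit_cox(data, [col], duration_col, event_col)
        uni[col] = fit
        p = fit.p_values[col]
        if fit.converged and p < p_enter:
            kept.append(col)
            audit.append(f"screen: keep {col} (univariate p={p:.4g} < {p_enter})")
        else:
            reason = f"p={p:.4g} >= {p_enter}" if fit.converged else "non-convergence"
            audit.append(f"screen: drop {col} ({reason})")
    screened = tuple(kept)
    if not kept:
        audit.append("screen: no candidate passed; empty model")
        return BackwardEliminationResult(None, screened, uni, tuple(audit))

    current = list(kept)
    fit = _fit_cox(data, current, duration_col, event_col)
    while fit.converged and len(current) > 0:
        worst = max(current, key=lambda c: fit.p_values[c])
        if fit.p_values[worst] < p_stay:
            break
        audit.append(f"eliminate: {worst} (p={fit.p_values[worst]:.4g} >= {p_stay})")
        current.remove(worst)
        if not current:
            audit.append("eliminate: all covariates removed; empty model")
            return BackwardEliminationResult(None, screened, uni, tuple(audit))
        fit = _fit_cox(data, current, duration_col, event_col)
    if not fit.converged:
        audit.append(f"fit: non-convergence ({fit.message})")
    return BackwardEliminationResult(fit, screened, uni, tuple(audit))
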