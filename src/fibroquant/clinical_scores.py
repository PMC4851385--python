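"""Noninvasive fibrosis scores and ROC-based dichotomization.

APRI = (AST / AST-ULN) / platelets[10⁹/L] × 100 and
FIB-4 = (age × AST) / (platelets[10⁹/L] × √ALT) are the standard serum
indices; platelets are always in 10⁹/L here (a count printed as
12.1 ×10⁴/μL is 121 ×10⁹/L).

Risk-factor cutoffs come from ROC analysis: every threshold candidate
(midpoints between sorted distinct values, plus one below the minimum and
one above the maximum) is scored by the Youden index J = sensitivity +
specificity − 1, and the maximizer wins, ties going to the lowest
threshold.  Thresholds are strict: a value exactly at the cutoff falls in
the low group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabPanel:
    """One patient's labs in formula units."""

    age: float  # years
    ast: float  # IU/L
    ast_uln: float  # IU/L
    alt: float  # IU/L
    platelets: float  # 10^9/L
    pt_inr: float = 1.0
    albumin: float = 4.0  # g/dL
    bilirubin: float = 0.8  # mg/dL

    def __post_init__(self):
        for name in ("ast", "ast_uln", "alt", "platelets", "pt_inr", "albumin"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.age < 0 or self.bilirubin < 0:
            raise ValueError("age and bilirubin must be non-negative")


@dataclass(frozen=True)
class CutoffRule:
    """Dichotomization rule: indicator 1 iff value is on the risk side."""

    variable: str
    threshold: float
    direction: str = "greater"  # "greater" or "less_or_equal"

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction not in ("greater", "less_or_equal"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def apply(self, values: np.ndarray | pd.Series) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.direction == "greater":
            ind = v > self.threshold
        else:
            ind = v <= self.threshold
        out = ind.astype(float)
        out[np.isnan(v)] = np.nan
        return out


def apri_values(ast, ast_uln, platelets) -> np.ndarray:
    """Vectorized APRI; raises on non-positive denominators."""
    ast, ast_uln, platelets = map(lambda x: np.asarray(x, dtype=float), (ast, ast_uln, platelets))
    if np.any(ast_uln <= 0) or np.any(platelets <= 0):
        raise ValueError("AST ULN and platelets must be strictly positive")
    return (ast / ast_uln) / platelets * 100.0


def fib4_values(age, ast, alt, platelets) -> np.ndarray:
    """Vectorized FIB-4; raises on non-positive ALT or platelets."""
    age, ast, alt, platelets = map(lambda x: np.asarray(x, dtype=float), (age, ast, alt, platelets))
    if np.any(alt <= 0) or np.any(platelets <= 0):
        raise ValueError("ALT and platelets must be strictly positive")
    return (age * ast) / (platelets * np.sqrt(alt))


def apri(panel: LabPanel) -> float:
    return float(apri_values(panel.ast, panel.ast_uln, panel.platelets))


def fib4(panel: LabPanel) -> float:
    return float(fib4_values(panel.age, panel.ast, panel.alt, panel.platelets))


def _sens_spec(values: np.ndarray, outcomes: np.ndarray, threshold: float, direction: str):
    if direction == "greater":
        flagged = values > threshold
    else:
        flagged = values <= threshold
    sens = flagged[outcomes == 1].mean()
    spec = (~flagged[outcomes == 0]).mean()
    return sens, spec


def youden_j(values, outcomes, rule: CutoffRule) -> float:
    """J = sensitivity + specificity − 1 of a rule on labeled values."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    sens, spec = _sens_spec(v, y, rule.threshold, rule.direction)
    return float(sens + spec - 1.0)


def roc_cutoff(values, outcomes, variable: str = "value") -> CutoffRule:
    """ROC-derived cutoff maximizing the Youden index.

    Candidates are the midpoints between sorted distinct values plus one
    threshold below the minimum and one above the maximum; ties are broken
    by the lowest threshold.  Direction is "greater" when the outcome-positive
    group has the higher mean (risk factor), else "less_or_equal".
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and outcomes must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    direction = "greater" if v[y == 1].mean() >= v[y == 0].mean() else "less_or_equal"
    u = np.unique(v)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best_j, best_thr = -np.inf, candidates[0]
    for thr in candidates:  # ascending, so strict improvement keeps lowest tie
        sens, spec = _sens_spec(v, y, thr, direction)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return CutoffRule(variable=variable, threshold=float(best_thr), direction=direction)


def dichotomize(cohort: pd.DataFrame, rules: list[CutoffRule]) -> pd.DataFrame:
    """Binary design matrix (one ``<variable>_high`` column per rule).

    Missing input values propagate as missing indicators; the per-column
    missing counts are attached as ``result.attrs['missing']``.  Idempotent
    and order-independent across rules.
    """
    unknown = [r.variable for r in rules if r.variable not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown cohort variables: {unknown}")
    out = pd.DataFrame(index=cohort.index)
    missing: dict[str, int] = {}
    for rule in rules:
        col = f"{rule.variable}_high"
        ind = rule.apply(cohort[rule.variable])
        out[col] = pd.array(
            [pd.NA if np.isnan(x) else int(x) for x in ind], dtype="Int8"
        )
        missing[col] = int(np.isnan(ind).sum())
    out.attrs["missing"] = missing
    return out


#: Study-style default rules: ROC-derived fiber/age/INR/score cutoffs plus
#: upper-limit-of-normal style lab rules.
DEFAULT_CUTOFF_RULES: tuple[CutoffRule, ...] = (
    CutoffRule("epa", 3.6, "greater"),
    CutoffRule("cpa", 11.0, "greater"),
    CutoffRule("age", 70.0, "greater"),
    CutoffRule("pt_inr", 1.07, "greater"),
    CutoffRule("apri", 1.75, "greater"),
    CutoffRule("fib4", 3.5, "greater"),
    CutoffRule("ast", 38.0, "greater"),
    CutoffRule("alt", 43.0, "greater"),
    CutoffRule("bilirubin", 1.0, "greater"),
    CutoffRule("platelets", 106.0, "less_or_equal"),
    CutoffRule("albumin", 4.0, "less_or_equal"),
)
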