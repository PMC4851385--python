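"""End-to-end study orchestration: images → fiber medians → survival report.

``run_full_pipeline`` quantifies every section image in a directory, joins
the per-section CPA/EPA medians onto the clinical cohort by patient id,
computes APRI/FIB-4, derives (or applies) the dichotomization cutoffs, and
runs the full statistical chain — Kaplan–Meier incidence curves for the
fiber strata, log-rank comparisons, univariate Cox screening, and the
multivariate Cox model after backward elimination — writing CSV/JSON
outputs plus a run manifest (config hash, seed, versions) so a rerun with
the same config and seed reproduces every numeric output bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_scores import (
    DEFAULT_CUTOFF_RULES,
    CutoffRule,
    apri_values,
    dichotomize,
    fib4_values,
    roc_cutoff,
)
from .errors import FibroquantError
from .evg_quant import default_color_model, run_quantification
from .survival_analysis import (
    cox_multivariate_backward,
    cox_univariate,
    km_estimate,
    logrank_test,
    truncate_followup,
)
from .synthetic_data import (
    CohortSpec,
    SectionSpec,
    generate_cohort,
    generate_section,
    write_cohort,
    write_ground_truth,
)

log = logging.getLogger("fibroquant.pipeline")

IMAGE_GLOBS = ("*.png", "*.tif", "*.tiff")

#: Candidate predictors screened in the Cox stage (variables dichotomized by
#: the active cutoff rules).
DEFAULT_COX_CANDIDATES = (
    "age",
    "epa",
    "cpa",
    "pt_inr",
    "apri",
    "fib4",
    "platelets",
    "albumin",
    "ast",
    "alt",
    "bilirubin",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    images_dir: str | None
    cohort_csv: str
    out_dir: str
    tile_area_mm2: float = 1.0
    min_tissue_fraction: float = 0.01
    cutoff_mode: str = "default"  # "default" or "auto_roc" (fiber cutoffs from ROC)
    cox_candidates: tuple[str, ...] = DEFAULT_COX_CANDIDATES
    km_strata: tuple[str, ...] = ("epa", "cpa", "combined", "fstage")
    allow_partial: bool = False
    horizon_years: float = 3.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("cox_candidates", "km_strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def simulate_study(
    out_dir: str | Path,
    n_patients: int = 189,
    n_sections: int = 30,
    seed: int = 0,
    section_px: int = 192,
    color_noise_sd: float = 8.0,
    cohort_spec: CohortSpec | None = None,
) -> dict[str, Path]:
    """Generate a complete synthetic study on disk.

    Writes the cohort CSV and, for the first ``n_sections`` patients, an
    EvG-like section whose true fiber fractions are that patient's CPA/EPA,
    with the patient id in the image sidecar so the pipeline can join them.
    """
    out = Path(out_dir)
    images = out / "images"
    spec = cohort_spec or CohortSpec(n=n_patients, seed=seed)
    cohort = generate_cohort(spec)
    cohort_path = write_cohort(cohort, out / "cohort.csv")
    for i in range(min(n_sections, len(cohort))):
        row = cohort.iloc[i]
        sec = generate_section(
            SectionSpec(
                width_px=section_px,
                height_px=section_px,
                true_collagen_fraction=min(row["cpa"] / 100.0, 0.6),
                true_elastin_fraction=min(row["epa"] / 100.0, 0.3),
                true_nucleus_fraction=0.08,
                color_noise_sd=color_noise_sd,
                seed=seed * 100003 + i,
            )
        )
        write_ground_truth(sec, images, row["patient_id"], patient_id=row["patient_id"])
    return {"cohort": cohort_path, "images": images}


def _quantify_images(config: RunConfig, model) -> pd.DataFrame:
    from .evg_quant import read_section_image, sidecar_path

    rows = []
    img_dir = Path(config.images_dir)
    paths = sorted(p for g in IMAGE_GLOBS for p in img_dir.glob(g))
    paths = [p for p in paths if not p.stem.endswith("_labels")]
    for p in paths:
        meta = {}
        sc = sidecar_path(p)
        if sc.exists():
            meta = json.loads(sc.read_text())
        pid = meta.get("patient_id", p.stem)
        res = run_quantification(
            p,
            model,
            tile_area_mm2=config.tile_area_mm2,
            min_tissue_fraction=config.min_tissue_fraction,
        )
        rows.append(
            {
                "patient_id": pid,
                "measured_cpa": res.median_cpa,
                "measured_epa": res.median_epa,
                "n_tiles_included": res.n_tiles_included,
            }
        )
    return pd.DataFrame(rows)


def _active_rules(config: RunConfig, cohort: pd.DataFrame) -> list[CutoffRule]:
    rules = [r for r in DEFAULT_CUTOFF_RULES if r.variable in cohort.columns]
    if config.cutoff_mode == "auto_roc":
        replaced = []
        for rule in rules:
            if rule.variable in ("epa", "cpa") and cohort["event"].nunique() == 2:
                replaced.append(
                    roc_cutoff(cohort[rule.variable], cohort["event"], rule.variable)
                )
            else:
                replaced.append(rule)
        rules = replaced
    elif config.cutoff_mode != "default":
        raise FibroquantError(f"unknown cutoff_mode {config.cutoff_mode!r}")
    return rules


def _km_rows(name: str, group: str, curve) -> list[dict]:
    return [
        {
            "stratum": name,
            "group": group,
            "time_years": t,
            "survival": s,
            "cumulative_incidence": 1.0 - s,
        }
        for t, s in zip(curve.times, curve.survival)
    ]


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole study and write the report bundle.

    Returns a summary dict; files land in ``config.out_dir``:
    ``cohort_quantified.csv``, ``km_curves.csv``, ``logrank.csv``,
    ``table_hr.csv`` (univariate + final multivariate), ``summary.json``,
    ``manifest.json``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(config.cohort_csv)
    log.info("stage=load n_patients=%d", len(cohort))

    # ---- image quantification and join -----------------------------------
    if config.images_dir is not None:
        model = default_color_model()
        measured = _quantify_images(config, model)
        log.info("stage=quantify n_images=%d", len(measured))
        if len(measured):
            unknown = set(measured.patient_id) - set(cohort.patient_id)
            if unknown and not config.allow_partial:
                raise FibroquantError(
                    f"image ids not present in cohort: {sorted(unknown)}"
                )
            measured = measured[measured.patient_id.isin(cohort.patient_id)]
            cohort = cohort.merge(measured, on="patient_id", how="left")
            has = cohort["measured_cpa"].notna()
            cohort["fiber_source"] = np.where(has, "image", "cohort")
            cohort.loc[has, "cpa"] = cohort.loc[has, "measured_cpa"]
            cohort.loc[has, "epa"] = cohort.loc[has, "measured_epa"]

    # ---- scores, truncation, cutoffs --------------------------------------
    if "apri" not in cohort.columns:
        cohort["apri"] = apri_values(cohort["ast"], cohort["ast_uln"], cohort["platelets"])
    if "fib4" not in cohort.columns:
        cohort["fib4"] = fib4_values(
            cohort["age"], cohort["ast"], cohort["alt"], cohort["platelets"]
        )
    cohort["time_years"], cohort["event"] = truncate_followup(
        cohort["time_years"], cohort["event"], config.horizon_years
    )
    rules = _active_rules(config, cohort)
    indicators = dichotomize(cohort, rules)
    for col in indicators.columns:
        cohort[col] = indicators[col].astype("float").to_numpy()
    log.info("stage=cutoffs n_rules=%d mode=%s", len(rules), config.cutoff_mode)

    # ---- Kaplan–Meier strata ----------------------------------------------
    km_rows: list[dict] = []
    logrank_rows: list[dict] = []
    times, events = cohort["time_years"].to_numpy(), cohort["event"].to_numpy()
    overall = km_estimate(times, events)
    km_rows += _km_rows("overall", "all", overall)

    def _two_group(name: str, mask_high: np.ndarray):
        hi, lo = mask_high.astype(bool), ~mask_high.astype(bool)
        if hi.sum() == 0 or lo.sum() == 0:
            return
        km_rows.extend(_km_rows(name, "high", km_estimate(times[hi], events[hi])))
        km_rows.extend(_km_rows(name, "low", km_estimate(times[lo], events[lo])))
        stat, p = logrank_test((times[hi], events[hi]), (times[lo], events[lo]))
        logrank_rows.append({"stratum": name, "chi_square": stat, "p": p})

    if "epa" in config.km_strata and "epa_high" in cohort:
        _two_group("elastin", cohort["epa_high"].to_numpy())
    if "cpa" in config.km_strata and "cpa_high" in cohort:
        _two_group("collagen", cohort["cpa_high"].to_numpy())
    if "combined" in config.km_strata and {"epa_high", "cpa_high"} <= set(cohort):
        both = (cohort["epa_high"] + cohort["cpa_high"]).to_numpy()
        for lvl, label in ((2, "both_high"), (1, "one_high"), (0, "both_low")):
            m = both == lvl
            if m.sum():
                km_rows.extend(_km_rows("combined", label, km_estimate(times[m], events[m])))
    if "fstage" in config.km_strata and "f4" in cohort and "epa_high" in cohort:
        for f4_value, fname in ((0, "F3"), (1, "F4")):
            sub = (cohort["f4"] == f4_value).to_numpy()
            if sub.sum():
                hi = sub & (cohort["epa_high"] == 1).to_numpy()
                lo = sub & (cohort["epa_high"] == 0).to_numpy()
                for mask, g in ((hi, "high"), (lo, "low")):
                    if mask.sum():
                        km_rows.extend(
                            _km_rows(f"elastin_{fname}", g, km_estimate(times[mask], events[mask]))
                        )
    log.info("stage=km n_strata_rows=%d", len(km_rows))

    # ---- Cox ---------------------------------------------------------------
    candidate_rules = [r for r in rules if r.variable in config.cox_candidates]
    hr_rows: list[dict] = []
    for rule in candidate_rules:
        fit = cox_univariate(cohort, rule)
        col = f"{rule.variable}_high"
        hr_rows.append(
            {
                "stage": "univariate",
                "variable": col,
                "threshold": rule.threshold,
                "direction": rule.direction,
                "hr": fit.hazard_ratios.get(col),
                "ci_lower": fit.ci_lower.get(col),
                "ci_upper": fit.ci_upper.get(col),
                "p": fit.p_values.get(col),
                "converged": fit.converged,
            }
        )
    backward = cox_multivariate_backward(cohort, list(candidate_rules))
    if backward.final is not None:
        for col in backward.final.covariates:
            hr_rows.append(
                {
                    "stage": "multivariate_final",
                    "variable": col,
                    "threshold": np.nan,
                    "direction": "",
                    "hr": backward.final.hazard_ratios[col],
                    "ci_lower": backward.final.ci_lower[col],
                    "ci_upper": backward.final.ci_upper[col],
                    "p": backward.final.p_values[col],
                    "converged": backward.final.converged,
                }
            )
    log.info("stage=cox n_candidates=%d final=%s", len(candidate_rules),
             backward.final.covariates if backward.final else ())

    # ---- outputs ------------------------------------------------------------
    cohort.to_csv(out / "cohort_quantified.csv", index=False, float_format="%.8g")
    pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False, float_format="%.8g")
    pd.DataFrame(logrank_rows).to_csv(out / "logrank.csv", index=False, float_format="%.8g")
    pd.DataFrame(hr_rows).to_csv(out / "table_hr.csv", index=False, float_format="%.8g")
    summary = {
        "n_patients": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
        "cumulative_incidence_3y": overall.cumulative_incidence_at(config.horizon_years),
        "median_cpa": float(np.median(cohort["cpa"])),
        "median_epa": float(np.median(cohort["epa"])),
        "cutoffs": {r.variable: r.threshold for r in rules},
        "final_model": list(backward.final.covariates) if backward.final else [],
        "elimination_audit": list(backward.audit),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "fibroquant_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("stage=write out=%s elapsed=%.2fs", out, time.time() - t0)
    return summary
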