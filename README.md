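# fibroquant

Automated quantification of collagen and elastin fibers in Elastica van
Gieson (EvG)-stained liver biopsy sections, and the downstream survival
analysis that links fiber burden to hepatocellular carcinoma (HCC) risk in
chronic hepatitis C with advanced fibrosis (METAVIR F3/F4).

It is aimed at digital-pathology and hepatology researchers who want a
reproducible, testable implementation of the proportional-area pipeline:

1. **Pixel classification.** A whole-slide RGB image with known resolution
   (default 0.46 μm/px) is color-calibrated against the glass background,
   then every pixel is assigned one of five classes — collagen fiber,
   elastin fiber, nucleus, cytoplasm, glass — by a quadratic discriminant
   (equal priors, minimum squared Mahalanobis distance) in a fixed opponent
   color space.
2. **Tile medians.** The section is compartmented into 1 mm² tiles
   (2173 × 2173 px = 4,721,929 px at 0.46 μm/px). Per tile, the collagen
   and elastin proportional areas are

   CPA = 100 · n<sub>collagen</sub> / n<sub>tissue</sub>,  EPA = 100 · n<sub>elastin</sub> / n<sub>tissue</sub>,

   where n<sub>tissue</sub> sums the four tissue classes (glass never enters the
   denominator). The section summary is the **median over tiles**, which
   makes it insensitive to large vascular (glass-dominated) areas.
3. **Survival analysis.** APRI and FIB-4 are computed, predictors are
   dichotomized at ROC-derived (Youden index) or fixed cutoffs, and HCC
   incidence within a 3-year window is analyzed by Kaplan–Meier curves,
   log-rank tests, univariate Cox screening (p < 0.1) and multivariate Cox
   with backward elimination (retain p < 0.05, Efron ties).

Because no slide archive or patient registry ships with the package, a
first-class synthetic-data module generates (a) EvG-like sections with
per-pixel ground-truth labels and controllable true fiber fractions, and
(b) cohorts with the reference statistical structure: correlated
log-normal fiber burdens (Pearson r = 0.477), baseline demographics/labs,
F4 assigned by a logistic link on fiber burden, and HCC onset from a
piecewise-exponential proportional-hazards model calibrated so the marginal
cumulative incidence is 5%/12%/16% at 1/2/3 years.

## Worked example

Quantify a synthetic section generated with 14.1% collagen and 2.5%
elastin:

```python
from fibroquant import SectionSpec, generate_section, write_section_image

sec = generate_section(SectionSpec(width_px=256, height_px=256,
                                   true_collagen_fraction=0.141,
                                   true_elastin_fraction=0.025, seed=7))
write_section_image(sec.image, "case1.png")
```

```console
$ fibroquant quantify --image case1.png
{"median_cpa": 14.0998, "median_epa": 2.4993, "n_tiles_included": 1, "tile_side_px": 2173}
```

The medians recover the generating fractions to within 0.05 percentage
points (the 256-px section fits in one partial 1 mm² tile; the small
residual is glass-border rounding). A full synthetic study — cohort CSV,
section images, joined analysis — runs as:

```console
$ fibroquant simulate-study --out study --n-patients 189 --n-sections 6 --seed 1
$ fibroquant analyze --cohort study/cohort.csv --images study/images --out study/analysis
{
 "cumulative_incidence_3y": 0.1376,
 "final_model": ["epa_high", "age_high"],
 "median_cpa": 8.74,
 "median_epa": 2.46,
 "n_events": 26,
 "n_patients": 189,
 ...
}
```

Here 26 of 189 simulated patients developed HCC within 3 years (13.8%
cumulative incidence — one draw around the calibrated 16%), and backward
elimination retained high elastin (EPA > 3.6%) and age > 70 as independent
predictors; the full audit trail of screened/eliminated covariates is in
`study/analysis/summary.json`, hazard ratios in `table_hr.csv`, and
Kaplan–Meier curves in `km_curves.csv`. `fibroquant report` renders the
curves as PNGs plus a markdown digest.

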