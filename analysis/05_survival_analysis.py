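"""Survival association analysis on a feature-level synthetic cohort.

Generates a 150-patient cohort (point-level scenes, no rasters) whose
hazard decreases with stromal neutrophil infiltration, then runs the
survival stack: covariate-adjusted multivariate Cox for the planted
feature, the maximal-χ² optimal cutoff with Kaplan–Meier/log-rank on the
resulting groups, and inverse-variance fixed-effects pooling of the
per-stage stratum effects.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mifspatial.survival import (
    StratumEffect,
    fit_cox,
    fixed_effects_pool,
    km_logrank,
    xtile_cutoff,
)
from mifspatial.synth import CohortSpec, SceneSpec, SurvivalModel, generate_cohort

FEATURE = "pct_neutrophil_TS"
spec = CohortSpec(
    n_patients=150,
    scene=SceneSpec(n_cells=200, width_px=512, height_px=384,
                    nucleus_radius_px=3.0, render=False),
    survival_model=SurvivalModel(beta={FEATURE: -0.08}),
    censoring_rate=0.25,
    seed=42,
)
cohort = generate_cohort(spec)
df = cohort.clinical.merge(cohort.true_features, on="patient_id")

terms = fit_cox(df, FEATURE, adjust=["sex", "age", "t_stage", "vpi", "vte"])
cox_rows = [{"term": t, "HR": v.hr, "ci_low": v.ci_low, "ci_high": v.ci_high,
             "p": v.p} for t, v in terms.items()]
cox = pd.DataFrame(cox_rows)
Path("results").mkdir(exist_ok=True)
cox.to_csv("results/cox_results.csv", index=False)
print("multivariate Cox (planted log-HR -0.08 per % stromal neutrophils):")
print(cox.round(4).to_string(index=False))

cut = xtile_cutoff(df[FEATURE].to_numpy(), df.time_days.to_numpy(),
                   df.event.to_numpy(), n_permutations=200, seed=1)
groups = np.where(df[FEATURE] > cut.cutoff, "high", "low")
chi2, p, _ = km_logrank(df.time_days, df.event, groups)
pd.DataFrame([{"feature": FEATURE, "cutoff": cut.cutoff, "chi2": cut.chi2,
               "p_raw": cut.p_raw, "p_permutation": cut.p_permutation,
               "n_low": cut.n_low, "n_high": cut.n_high}]) \
    .to_csv("results/cutpoints.csv", index=False)
print(f"\noptimal cutoff {cut.cutoff:.2f}% (chi2 {cut.chi2:.2f}, raw p {cut.p_raw:.2g}, "
      f"permutation p {cut.p_permutation:.3f}); KM log-rank p {p:.2g}")

strata = []
for stage, sub in df.groupby("stage_group"):
    t = fit_cox(sub, FEATURE)[FEATURE]
    strata.append(StratumEffect(log_hr=t.coef, se=t.se, label=stage))
pooled = fixed_effects_pool(strata)
pd.DataFrame(
    [{"stratum": s.label, "log_hr": s.log_hr, "se": s.se} for s in strata]
    + [{"stratum": "pooled", "log_hr": pooled.log_hr, "se": pooled.se}]
).to_csv("results/pooled.csv", index=False)
print(f"fixed-effects pooled HR across stage strata: {pooled.hr:.3f} "
      f"(95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f}, p {pooled.p:.2g})")
print("-> results/cox_results.csv, results/cutpoints.csv, results/pooled.csv")
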