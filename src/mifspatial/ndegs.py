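"""The six-gene neutrophil-differentiation expression gene score (NDEGS).

The score is a frozen linear combination of the expression of six genes
selected in the source cohort's training split:

    NDEGS = 0.706*CTSZ + 1.225*PLAUR + 1.268*NME2
          + 1.339*NPM1 + 1.349*EIF3E + 1.555*PPIA

The coefficients are scale-bound: the caller must supply expression on a
single declared normalisation scale (the score is not re-fit here).
Cohorts are split 7:3 into training and validation, the optimal cutoff is
learned on training only via the maximal-χ² cutpoint scan and applied
unchanged to validation; performance is reported as KM/log-rank, a Cox HR
of the high-score group and IPCW time-dependent AUC (cumulative/dynamic) at
1, 3 and 5 years.  Tumour mutational burden (TMB) utilities classify
samples at the conventional 20 mut/Mb cutoff (boundary inclusive: TMB-H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import fit_cox, km_logrank, xtile_cutoff

__all__ = [
    "NDEGS_COEFFICIENTS",
    "ndegs_score",
    "NdegsResult",
    "assign_risk_group",
    "SplitEvaluation",
    "split_and_evaluate",
    "tmb",
    "TMB_CUTOFF",
]

#: Frozen published coefficients of the six-gene score.
NDEGS_COEFFICIENTS: dict[str, float] = {
    "CTSZ": 0.706,
    "PLAUR": 1.225,
    "NME2": 1.268,
    "NPM1": 1.339,
    "EIF3E": 1.349,
    "PPIA": 1.555,
}

TMB_CUTOFF = 20.0  # mut/Mb; >= cutoff is TMB-H


def ndegs_score(expression: pd.DataFrame | pd.Series | dict) -> pd.Series | float:
    """The frozen linear score; missing genes raise (no imputation)."""
    if isinstance(expression, (pd.Series, dict)):
        e = pd.Series(expression, dtype=float)
        missing = [g for g in NDEGS_COEFFICIENTS if g not in e.index]
        if missing:
            raise ValueError(f"missing genes: {missing}")
        if (e[list(NDEGS_COEFFICIENTS)] < 0).any():
            raise ValueError("expression must be non-negative")
        return float(sum(c * e[g] for g, c in NDEGS_COEFFICIENTS.items()))
    missing = [g for g in NDEGS_COEFFICIENTS if g not in expression.columns]
    if missing:
        raise ValueError(f"missing genes: {missing}")
    sub = expression[list(NDEGS_COEFFICIENTS)].astype(float)
    if (sub.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    return sub.mul(pd.Series(NDEGS_COEFFICIENTS)).sum(axis=1)


@dataclass
class NdegsResult:
    score: float
    risk_group: str  # "high" iff score > cutoff
    cutoff: float


def assign_risk_group(score: float, cutoff: float) -> NdegsResult:
    return NdegsResult(score=score, cutoff=cutoff,
                       risk_group="high" if score > cutoff else "low")


@dataclass
class SplitEvaluation:
    cutoff: float
    train_chi2: float
    val_logrank_chi2: float
    val_logrank_p: float
    val_hr: float
    val_hr_ci: tuple[float, float]
    val_auc: dict[float, float]  # horizon (years) -> AUC
    val_mean_auc: float
    n_train: int
    n_val: int


def split_and_evaluate(
    scores,
    times,
    events,
    train_frac: float = 0.7,
    seed: int = 0,
    auc_years: tuple[float, ...] = (1.0, 3.0, 5.0),
    min_events: int = 5,
    min_group_frac: float = 0.1,
) -> SplitEvaluation:
    """Train/validation split evaluation of the score.

    The cutpoint is learned on the training split only (maximal log-rank χ²)
    and applied unchanged to validation.  Time-dependent AUC uses the
    inverse-probability-of-censoring-weighted cumulative/dynamic estimator
    with the censoring distribution from the training split; horizons beyond
    the validation follow-up are dropped.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = scores.size
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    tr, va = order[:n_train], order[n_train:]
    for name, idx in (("training", tr), ("validation", va)):
        if events[idx].sum() < min_events:
            raise ValueError(f"too few events in the {name} split "
                             f"({int(events[idx].sum())} < {min_events})")

    cut = xtile_cutoff(scores[tr], times[tr], events[tr], min_group_frac=min_group_frac)
    high_va = scores[va] > cut.cutoff
    if high_va.all() or not high_va.any():
        raise ValueError("training cutoff does not split the validation cohort")
    chi2, p, _ = km_logrank(times[va], events[va],
                            np.where(high_va, "high", "low"))
    cox = fit_cox(
        pd.DataFrame({"high": high_va.astype(int), "time_days": times[va], "event": events[va]}),
        "high",
    )["high"]

    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    surv_tr = Surv.from_arrays(events[tr].astype(bool), times[tr])
    surv_va = Surv.from_arrays(events[va].astype(bool), times[va])
    horizon_days = np.array(auc_years) * 365.25
    t_lo = max(float(times[va].min()), float(times[tr].min()))
    t_hi = min(float(times[va].max()), float(times[tr].max()))
    ok = (horizon_days > t_lo) & (horizon_days < t_hi)
    aucs: dict[float, float] = {}
    mean_auc = float("nan")
    # drop horizons from the top while the training censoring distribution
    # cannot support them (IPCW weights undefined there)
    while ok.any():
        try:
            a, mean_auc = cumulative_dynamic_auc(
                surv_tr, surv_va, scores[va], horizon_days[ok]
            )
        except ValueError:
            ok[np.nonzero(ok)[0][-1]] = False
            continue
        for yr, v in zip(np.array(auc_years)[ok], a):
            aucs[float(yr)] = float(v)
        mean_auc = float(mean_auc)
        break
    return SplitEvaluation(
        cutoff=cut.cutoff, train_chi2=cut.chi2,
        val_logrank_chi2=chi2, val_logrank_p=p,
        val_hr=cox.hr, val_hr_ci=(cox.ci_low, cox.ci_high),
        val_auc=aucs, val_mean_auc=mean_auc,
        n_train=int(tr.size), n_val=int(va.size),
    )


def tmb(
    mutations: pd.DataFrame,
    interrogated_mb: float = 38.0,
    sample_col: str = "sample",
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Tumour mutational burden per sample from a MAF-like table.

    TMB = somatic mutation rows / megabases interrogated; group is TMB-H
    iff TMB >= 20 mut/Mb (boundary inclusive).  ``samples`` may list ids
    that must appear in the output even with zero mutations.
    """
    if interrogated_mb <= 0:
        raise ValueError(f"interrogated_mb must be positive, got {interrogated_mb}")
    if sample_col not in mutations.columns:
        raise ValueError(f"missing column {sample_col!r}")
    counts = mutations.groupby(sample_col).size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    out = pd.DataFrame({
        "sample": counts.index,
        "n_mutations": counts.to_numpy(),
        "tmb": counts.to_numpy() / interrogated_mb,
    })
    out["tmb_group"] = np.where(out["tmb"] >= TMB_CUTOFF, "TMB-H", "TMB-L")
    return out.reset_index(drop=True)
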