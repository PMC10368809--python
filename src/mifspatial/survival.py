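"""Survival association statistics.

Multivariate Cox proportional-hazards fits (Efron ties, via lifelines),
Kaplan–Meier curves with log-rank tests, an outcome-based optimal-cutpoint
scan that maximises the two-group log-rank χ² over candidate thresholds
(the X-tile idea) with an optional permutation correction for maximal
selection, inverse-variance fixed-effects pooling of stratum effects, and a
descriptive cohort summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "CoxTerm",
    "fit_cox",
    "km_logrank",
    "logrank_chi2",
    "CutpointResult",
    "xtile_cutoff",
    "StratumEffect",
    "PooledEffect",
    "fixed_effects_pool",
    "cohort_summary",
]


@dataclass
class CoxTerm:
    """One covariate's estimate from a Cox fit."""

    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


def fit_cox(
    records: pd.DataFrame,
    feature: str,
    adjust: list[str] | None = None,
    time_col: str = "time_days",
    event_col: str = "event",
) -> dict[str, CoxTerm]:
    """Multivariate Cox PH fit of ``feature`` adjusted for covariates.

    Requires >= 10 events and no constant covariate; non-convergence is
    re-raised with a diagnostic.  Returns per-term HR = exp(coef), Wald 95%
    CI and p-value.
    """
    adjust = adjust or []
    cols = [feature] + adjust
    df = records[cols + [time_col, event_col]].dropna()
    n_events = int(df[event_col].sum())
    if n_events < 10:
        raise ValueError(f"too few events for a Cox fit: {n_events} < 10")
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # noqa: BLE001 - surfaced with context
        raise RuntimeError(f"Cox fit failed (separation or non-convergence): {exc}") from exc
    s = cph.summary
    out = {}
    for term in cols:
        row = s.loc[term]
        out[term] = CoxTerm(
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
    return out


def km_logrank(times, events, groups) -> tuple[float, float, dict]:
    """k-sample log-rank test plus Kaplan–Meier estimates per group.

    Returns ``(chi2, p, curves)`` where ``curves[label]`` is the KM survival
    function (DataFrame) of that group.  Requires >= 2 non-empty groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    curves = {}
    for lab in labels:
        sel = groups == lab
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel], label=str(lab))
        curves[lab] = km.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


def logrank_chi2(times, events, in_group_b) -> float:
    """Two-group log-rank χ² (vectorised; independent of the lifelines path).

    ``in_group_b`` is a boolean membership vector.  Implements the classic
    observed-minus-expected sum over distinct event times with the
    hypergeometric variance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    b = np.asarray(in_group_b, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], b[order]
    n = t.size
    # at-risk counts just before each distinct event time
    uniq = np.unique(t[e == 1])
    if uniq.size == 0:
        return 0.0
    o_minus_e = 0.0
    var = 0.0
    for tt in uniq:
        at_risk = t >= tt
        n_tot = int(at_risk.sum())
        n_b = int((at_risk & g).sum())
        d_tot = int(((t == tt) & (e == 1)).sum())
        d_b = int(((t == tt) & (e == 1) & g).sum())
        if n_tot < 2:
            continue
        exp_b = d_tot * n_b / n_tot
        v = d_tot * (n_b / n_tot) * (1 - n_b / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        o_minus_e += d_b - exp_b
        var += v
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


@dataclass
class CutpointResult:
    cutoff: float
    chi2: float
    n_low: int
    n_high: int
    p_raw: float
    p_permutation: float | None = None
    scanned: pd.DataFrame | None = None  # candidate cutoffs and their χ²


def xtile_cutoff(
    values,
    times,
    events,
    min_group_frac: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Outcome-based optimal cutpoint maximising the log-rank χ².

    Candidates are the observed feature values whose split (``value > c`` =
    high group) leaves both groups with at least ``min_group_frac`` of the
    cohort; ties in χ² break toward the lower cutoff.  The raw p is the
    χ²(1 df) tail of the best statistic (anti-conservative under maximal
    selection); ``n_permutations > 0`` adds a permutation-adjusted p that
    re-maximises over cutoffs for each permutation of the feature.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    if np.unique(values).size < 3:
        raise ValueError("feature needs at least 3 distinct values")
    if not 0.0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must be in (0, 0.5)")

    uniq_t = np.unique(times[events == 1])
    # at-risk and event-at-time indicators per distinct event time (m x n)
    at_risk = times[None, :] >= uniq_t[:, None]
    event_at = (times[None, :] == uniq_t[:, None]) & (events[None, :] == 1)
    n_tot = at_risk.sum(axis=1).astype(float)
    d_tot = event_at.sum(axis=1).astype(float)

    def scan(vals) -> tuple[float, float, pd.DataFrame]:
        cands = np.unique(vals)[:-1]  # top value cannot split
        high = vals[None, :] > cands[:, None]  # candidates x subjects
        n_high = high.sum(axis=1)
        keep = np.minimum(n_high, n - n_high) >= min_group_frac * n
        cands, high, n_high = cands[keep], high[keep], n_high[keep]
        if cands.size == 0:
            raise ValueError(
                f"no candidate cutoff leaves both groups >= {min_group_frac:.0%} of n={n}"
            )
        if uniq_t.size == 0:
            chi2s = np.zeros(cands.size)
        else:
            n_b = high @ at_risk.T.astype(float)         # candidates x event times
            d_b = high @ event_at.T.astype(float)
            frac = n_b / n_tot
            with np.errstate(invalid="ignore", divide="ignore"):
                v = d_tot * frac * (1 - frac) * (n_tot - d_tot) / np.maximum(n_tot - 1, 1)
            v[:, n_tot < 2] = 0.0
            o_minus_e = (d_b - d_tot * frac).sum(axis=1)
            var = v.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                chi2s = np.where(var > 0, o_minus_e**2 / var, 0.0)
        best = int(np.argmax(chi2s > chi2s.max() - 1e-12))  # ties -> lower cutoff
        scanned = pd.DataFrame({
            "cutoff": cands, "chi2": chi2s,
            "n_low": n - n_high, "n_high": n_high,
        })
        return float(cands[best]), float(chi2s[best]), scanned

    cutoff, chi2, scanned = scan(values)
    high = values > cutoff
    p_raw = float(stats.chi2.sf(chi2, df=1))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(values)
            try:
                _, chi2_b, _ = scan(perm)
            except ValueError:
                chi2_b = 0.0
            if chi2_b >= chi2:
                exceed += 1
        p_perm = (1 + exceed) / (1 + n_permutations)
    return CutpointResult(
        cutoff=cutoff, chi2=chi2, n_low=int((~high).sum()), n_high=int(high.sum()),
        p_raw=p_raw, p_permutation=p_perm, scanned=scanned,
    )


@dataclass
class StratumEffect:
    """A stratum's log hazard ratio and its standard error."""

    log_hr: float
    se: float
    label: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")


@dataclass
class PooledEffect:
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    weights: list[float] = field(default_factory=list)


def fixed_effects_pool(strata: list[StratumEffect]) -> PooledEffect:
    """Inverse-variance fixed-effects pooling of stratum log hazard ratios.

    ``w_i = 1/SE_i²``, pooled estimate ``Σ w_i θ_i / Σ w_i`` with standard
    error ``(Σ w_i)^(-1/2)``; Wald 95% CI and two-sided p.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    w = np.array([1.0 / s.se**2 for s in strata])
    theta = np.array([s.log_hr for s in strata])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    ci = 1.959963984540054 * se
    return PooledEffect(
        log_hr=pooled, se=se, hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - ci)), ci_high=float(np.exp(pooled + ci)),
        p=float(2 * stats.norm.sf(abs(z))), weights=(w / w.sum()).tolist(),
    )


def cohort_summary(
    clinical: pd.DataFrame,
    group_col: str = "stage_group",
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive table: per-variable counts and percentages by group.

    Categorical variables get per-level counts with within-group percentages
    and a χ² test across groups; numeric variables get median (IQR) and a
    Mann–Whitney U test (two groups).  Missing columns raise.
    """
    if group_col not in clinical.columns:
        raise ValueError(f"missing column {group_col!r}")
    categorical = categorical or []
    numeric = numeric or []
    for c in categorical + numeric:
        if c not in clinical.columns:
            raise ValueError(f"missing column {c!r}")
    groups = sorted(clinical[group_col].dropna().unique())
    rows = []
    for var in categorical:
        tab = pd.crosstab(clinical[var], clinical[group_col])
        if tab.shape[0] > 1 and tab.shape[1] > 1 and (tab.values.sum(axis=0) > 0).all():
            p = float(stats.chi2_contingency(tab.values)[1])
        else:
            p = float("nan")
        for level in tab.index:
            row = {"variable": var, "level": str(level), "p": p}
            for g in groups:
                cnt = int(tab.loc[level, g]) if g in tab.columns else 0
                tot = int(tab[g].sum()) if g in tab.columns else 0
                row[f"n_{g}"] = cnt
                row[f"pct_{g}"] = 100.0 * cnt / tot if tot else float("nan")
            rows.append(row)
    for var in numeric:
        row = {"variable": var, "level": "median (IQR)"}
        vals_by_g = [clinical.loc[clinical[group_col] == g, var].dropna() for g in groups]
        if len(groups) == 2 and all(len(v) for v in vals_by_g):
            row["p"] = float(stats.mannwhitneyu(*vals_by_g).pvalue)
        else:
            row["p"] = float("nan")
        for g, v in zip(groups, vals_by_g):
            row[f"n_{g}"] = int(v.size)
            row[f"pct_{g}"] = float("nan")
            row[f"median_{g}"] = float(v.median()) if v.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
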