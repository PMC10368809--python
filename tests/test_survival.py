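"""Cox fits, log-rank, optimal cutpoints and fixed-effects pooling."""

import numpy as np
import pandas as pd
import pytest

from mifspatial.survival import (
    StratumEffect,
    cohort_summary,
    fit_cox,
    fixed_effects_pool,
    km_logrank,
    logrank_chi2,
    xtile_cutoff,
)
from mifspatial.synth import SurvivalModel, simulate_survival


def _ph_frame(beta, n, seed, censoring=0.2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t, e = simulate_survival(beta * x, SurvivalModel(), censoring, rng)
    return pd.DataFrame({"x": x, "time_days": t, "event": e})


def test_cox_recovers_planted_coefficient():
    df = _ph_frame(0.5, 1000, 3)
    term = fit_cox(df, "x")["x"]
    assert abs(term.coef - 0.5) < 0.1
    assert term.ci_low < term.hr < term.ci_high


def test_cox_null_coverage():
    covered = 0
    for seed in range(100):
        df = _ph_frame(0.0, 500, seed)
        term = fit_cox(df, "x")["x"]
        covered += term.ci_low <= 1.0 <= term.ci_high
    assert covered >= 90


def test_cox_rejects_degenerate_input():
    df = _ph_frame(0.0, 100, 1)
    with pytest.raises(ValueError, match="constant"):
        fit_cox(df.assign(c=1.0), "x", adjust=["c"])
    few = df.iloc[:12].assign(event=[1] * 5 + [0] * 7)
    with pytest.raises(ValueError, match="events"):
        fit_cox(few, "x")


def test_logrank_identical_groups_is_null():
    df = _ph_frame(0.0, 50, 2)
    times = np.concatenate([df.time_days, df.time_days])
    events = np.concatenate([df.event, df.event])
    groups = np.array(["A"] * 50 + ["B"] * 50)
    chi2, p, curves = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)
    assert set(curves) == {"A", "B"}


def test_logrank_hand_worked_six_subjects():
    """Three events at 1,2,3 in group A vs 4,5,6 in group B.

    Hand-worked log-rank table: O_B = 3, E_B = 0.5 + 0.6 + 0.75 + 3 = 4.85,
    V = 0.25 + 0.24 + 0.1875 = 0.6775, chi2 = 1.85^2 / 0.6775 = 5.05166...
    """
    times = np.array([1, 2, 3, 4, 5, 6], float)
    events = np.ones(6, int)
    groups = np.array(list("AAABBB"))
    expected = 1.85**2 / 0.6775
    assert logrank_chi2(times, events, groups == "B") == pytest.approx(expected, rel=1e-9)
    chi2, _, _ = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(expected, rel=1e-6)


def test_logrank_all_censored_and_label_swap():
    times = np.array([3.0, 5.0, 7.0, 9.0])
    events = np.zeros(4, int)
    assert logrank_chi2(times, events, np.array([1, 1, 0, 0], bool)) == 0.0
    df = _ph_frame(0.8, 80, 5)
    grp = df.x > 0
    a = logrank_chi2(df.time_days, df.event, grp)
    b = logrank_chi2(df.time_days, df.event, ~grp)
    assert a == pytest.approx(b, rel=1e-9)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        km_logrank([1.0, 2.0], [1, 1], ["A", "A"])


def test_xtile_recovers_planted_cutoff():
    # feature levels 0 < 1 < 2; hazard doubles for levels >= 1
    rng = np.random.default_rng(4)
    n = 300
    feature = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.5, 0.25, 0.25])
    high = feature >= 1.0
    t, e = simulate_survival(np.where(high, np.log(2.0), 0.0), SurvivalModel(), 0.1, rng)
    res = xtile_cutoff(feature, t, e)
    assert res.cutoff == 0.0  # separates the planted groups exactly
    assert np.array_equal(feature > res.cutoff, high)
    assert res.p_raw < 1e-4


def test_xtile_degenerate_inputs():
    t = np.arange(1.0, 21.0)
    e = np.ones(20, int)
    with pytest.raises(ValueError, match="distinct"):
        xtile_cutoff(np.ones(20), t, e)
    skew = np.r_[np.zeros(18), 5.0, 10.0]  # every split violates the group bound
    with pytest.raises(ValueError, match="candidate"):
        xtile_cutoff(skew, t, e, min_group_frac=0.2)


def test_xtile_permutation_p_is_calibrated_and_corrects_raw():
    """Under the null the permutation-adjusted p is ~uniform while the raw
    maximal-chi2 p is anti-conservative (stochastically smaller)."""
    from scipy import stats

    p_perm, p_raw = [], []
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        n = 60
        v = rng.normal(size=n)
        t, e = simulate_survival(np.zeros(n), SurvivalModel(), 0.2, rng)
        res = xtile_cutoff(v, t, e, n_permutations=60, seed=seed)
        p_perm.append(res.p_permutation)
        p_raw.append(res.p_raw)
    ks = stats.kstest(p_perm, "uniform")
    assert ks.pvalue > 0.01
    assert np.mean(p_raw) < np.mean(p_perm)
    assert np.mean(np.array(p_raw) <= np.array(p_perm)) > 0.9


def test_fixed_effects_pooling_exact():
    s = StratumEffect(log_hr=0.3, se=0.1, label="only")
    pooled = fixed_effects_pool([s])
    assert pooled.log_hr == pytest.approx(0.3, abs=1e-15)
    assert pooled.se == pytest.approx(0.1, abs=1e-15)

    two = fixed_effects_pool([
        StratumEffect(0.2, 0.1), StratumEffect(0.4, 0.1)
    ])
    assert two.log_hr == pytest.approx(0.3, abs=1e-12)
    assert two.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    limit = fixed_effects_pool([
        StratumEffect(0.25, 0.05), StratumEffect(5.0, 1e6)
    ])
    assert limit.log_hr == pytest.approx(0.25, abs=1e-6)

    with pytest.raises(ValueError):
        fixed_effects_pool([])
    with pytest.raises(ValueError):
        StratumEffect(0.1, 0.0)


def test_pooled_se_never_exceeds_min_stratum_se():
    rng = np.random.default_rng(6)
    for _ in range(20):
        strata = [StratumEffect(rng.normal(), float(rng.uniform(0.05, 1.0)))
                  for _ in range(int(rng.integers(1, 6)))]
        pooled = fixed_effects_pool(strata)
        assert pooled.se <= min(s.se for s in strata) + 1e-12


def test_cohort_summary_reproduces_published_proportions(table1_clinical):
    summary = cohort_summary(table1_clinical, categorical=["histology", "relapse"])
    luad = summary[(summary.variable == "histology") & (summary.level == "LUAD")]
    n_luad = luad[["n_IA-IIA", "n_IIB-IIIB"]].to_numpy().sum()
    assert n_luad == 382
    assert round(100.0 * n_luad / len(table1_clinical), 1) == 69.1
    rel = summary[(summary.variable == "relapse") & (summary.level == "1")]
    assert round(float(rel["pct_IA-IIA"].iloc[0]), 1) == 32.9
    assert round(float(rel["pct_IIB-IIIB"].iloc[0]), 1) == 67.1
    with pytest.raises(ValueError, match="missing column"):
        cohort_summary(table1_clinical, categorical=["nope"])
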