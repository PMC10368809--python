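"""Generator-level checks: determinism, composition, survival links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mifspatial.panels import PANELS
from mifspatial.survival import fit_cox, km_logrank
from mifspatial.synth import (
    CohortSpec,
    PackingError,
    SceneSpec,
    SurvivalModel,
    generate_cohort,
    generate_expression,
    generate_scene,
    simulate_survival,
)


def test_same_seed_bit_identical():
    spec = SceneSpec(n_cells=60, width_px=256, height_px=192, seed=5)
    ch1, gt1 = generate_scene(spec)
    ch2, gt2 = generate_scene(SceneSpec(n_cells=60, width_px=256, height_px=192, seed=5))
    for p in PANELS:
        assert np.array_equal(ch1[p], ch2[p])
        assert np.array_equal(gt1.panels[p].nucleus_labels, gt2.panels[p].nucleus_labels)
        assert gt1.panels[p].marker_truth == gt2.panels[p].marker_truth
    assert np.array_equal(gt1.compartment_mask, gt2.compartment_mask)


def test_different_seed_differs():
    spec_a = SceneSpec(n_cells=60, width_px=256, height_px=192, seed=5)
    spec_b = SceneSpec(n_cells=60, width_px=256, height_px=192, seed=6)
    _, gt_a = generate_scene(spec_a)
    _, gt_b = generate_scene(spec_b)
    assert not np.array_equal(
        gt_a.panels["panel1"].nucleus_labels, gt_b.panels["panel1"].nucleus_labels
    )


def test_empty_scene():
    ch, gt = generate_scene(SceneSpec(n_cells=0, width_px=128, height_px=96))
    for p in PANELS:
        assert gt.panels[p].nucleus_labels.max() == 0
        assert gt.panels[p].phenotype_of == {}


def test_invalid_mixture_rejected():
    spec = SceneSpec(phenotype_mixture={"panel1": {"CD4 T": 0.6, "other": 0.6},
                                        "panel2": {"other": 1.0}})
    with pytest.raises(ValueError, match="sum"):
        spec.validate()


def test_infeasible_packing_raises():
    # passes the area invariant but cannot satisfy the hard-core distance
    spec = SceneSpec(n_cells=110, width_px=100, height_px=100,
                     nucleus_radius_px=4.0, render=False)
    with pytest.raises(PackingError, match="cells"):
        generate_scene(spec)


def test_composition_converges_to_mixture():
    mix = {"other": 0.5, "CD4 T": 0.14, "Treg": 0.05, "activated T": 0.08,
           "B": 0.08, "neutrophil": 0.15}
    spec = SceneSpec(
        n_cells=5000, width_px=1024, height_px=768, nucleus_radius_px=2.0,
        render=False, seed=3,
        phenotype_mixture={"panel1": mix, "panel2": {"other": 1.0}},
    )
    _, gt = generate_scene(spec)
    phenos = list(gt.panels["panel1"].phenotype_of.values())
    n = len(phenos)
    for name, p in mix.items():
        obs = sum(x == name for x in phenos) / n
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= tol, (name, obs, p)


def test_interaction_zero_matches_random_labelling_envelope():
    """With no interaction terms the cross-phenotype nearest-neighbour
    distance sits inside the random-labelling (CSR-of-labels) envelope."""
    from scipy.spatial import cKDTree

    spec = SceneSpec(n_cells=300, width_px=768, height_px=576, render=False, seed=9)
    _, gt = generate_scene(spec)
    pt = gt.panels["panel1"]
    pos = np.array([pt.centroids[i + 1] for i in range(spec.n_cells)])
    labels = np.array([pt.phenotype_of[i + 1] for i in range(spec.n_cells)])

    def cross_nn(lab):
        a = pos[lab == "CD4 T"]
        b = pos[lab == "neutrophil"]
        return cKDTree(b).query(a)[0].mean()

    obs = cross_nn(labels)
    rng = np.random.default_rng(0)
    null = np.array([cross_nn(rng.permutation(labels)) for _ in range(200)])
    lo, hi = np.quantile(null, [0.005, 0.995])
    assert lo <= obs <= hi


def test_attraction_decreases_pair_distance_monotonically():
    """Mean Delaunay A-B edge length falls as attraction strength rises."""
    from mifspatial.spatial import build_delaunay, pair_distance

    def mean_ab(seed, strength):
        spec = SceneSpec(
            n_cells=250, width_px=640, height_px=480, render=False, seed=seed,
            interaction=[("CD4 T", "neutrophil", strength)],
        )
        _, gt = generate_scene(spec)
        pt = gt.panels["panel1"]
        pts = np.array([pt.centroids[i + 1] for i in range(spec.n_cells)])
        cls = [pt.phenotype_of[i + 1] for i in range(spec.n_cells)]
        g = build_delaunay(pts, cls, spec.pixel_size_um)
        return pair_distance(g, "CD4 T", "neutrophil")

    strengths = [0.0, 1.5, 4.0]
    means = [np.mean([mean_ab(s, w) for s in range(4)]) for w in strengths]
    assert means[0] > means[1] > means[2], means


def test_weibull_baseline_recovered_when_beta_zero():
    model = SurvivalModel(baseline_shape=1.2, baseline_scale_days=1500.0)
    rng = np.random.default_rng(42)
    t, e = simulate_survival(np.zeros(1000), model, censoring_rate=0.0, rng=rng)
    assert e.all()
    ks = stats.kstest(t, stats.weibull_min(c=1.2, scale=1500.0).cdf)
    assert ks.pvalue > 0.01


def test_censoring_boundaries():
    model = SurvivalModel()
    rng = np.random.default_rng(0)
    t, e = simulate_survival(np.zeros(200), model, censoring_rate=1.0, rng=rng)
    assert (e == 0).all() and (t > 0).all()
    t, e = simulate_survival(np.zeros(500), model, censoring_rate=0.4,
                             rng=np.random.default_rng(1))
    assert abs(e.mean() - 0.6) < 0.07  # realised event rate near target


def test_cohort_counts_and_outputs():
    spec = CohortSpec(n_patients=1, sections_per_patient=1,
                      scene=SceneSpec(n_cells=40, width_px=256, height_px=192), seed=2)
    cohort = generate_cohort(spec)
    assert len(cohort.patients) == 1
    assert len(cohort.patients[0].sections) == 1
    channels, _ = cohort.patients[0].sections[0]
    assert set(channels) == set(PANELS)  # exactly two panel rasters
    assert len(cohort.clinical) == 1
    assert {"time_days", "event", "stage_group", "sex", "age", "t_stage",
            "vpi", "vte"} <= set(cohort.clinical.columns)


def test_unknown_beta_feature_rejected():
    spec = CohortSpec(
        n_patients=3, scene=SceneSpec(n_cells=30, width_px=256, height_px=192, render=False),
        survival_model=SurvivalModel(beta={"pct_unicorn_TS": 1.0}),
    )
    with pytest.raises(ValueError, match="pct_unicorn_TS"):
        generate_cohort(spec)


def test_hazard_link_doubling_beta_doubles_log_hr():
    rng = np.random.default_rng(7)
    x = rng.normal(size=2000)
    model = SurvivalModel()

    def recovered(beta):
        t, e = simulate_survival(beta * x, model, censoring_rate=0.2,
                                 rng=np.random.default_rng(8))
        df = pd.DataFrame({"x": x, "time_days": t, "event": e})
        return fit_cox(df, "x")["x"].coef

    b1, b2 = recovered(0.3), recovered(0.6)
    assert abs(b2 - 2 * b1) < 0.2


def test_expression_shape_and_validation():
    df = generate_expression(2, 0.0, 1)
    assert len(df) == 2
    assert {"CTSZ", "PLAUR", "NME2", "NPM1", "EIF3E", "PPIA",
            "time_days", "event"} <= set(df.columns)
    with pytest.raises(ValueError):
        generate_expression(1, 0.0, 1)


def test_expression_null_rarely_significant():
    hits = 0
    for seed in range(100):
        df = generate_expression(100, 0.0, seed)
        half = df.true_score > df.true_score.median()
        _, p, _ = km_logrank(df.time_days, df.event,
                             np.where(half, "hi", "lo"))
        hits += p < 0.05
    assert hits <= 10  # non-significant in >= 90% of null seeds


def test_expression_effect_recovered_by_cox():
    df = generate_expression(500, 1.0, 7).rename(columns={"true_score": "s"})
    coef = fit_cox(df, "s")["s"].coef
    assert abs(coef - 1.0) < 0.15
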