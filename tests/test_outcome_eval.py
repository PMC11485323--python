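"""Outcome encoding, AUC machinery, clustered CV, splines, importance,
selection and trajectories, checked against nulls and constructions with
known answers."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from neovital.outcome_eval import (
    FIXED_MODEL_FEATURES,
    auc,
    cluster_folds,
    clustered_cv,
    encode_outcomes,
    encode_outcome_table,
    fixed_model,
    prevalence,
    rank_metrics,
    select_features,
    spline_risk_curve,
    trajectory,
    variable_importance,
)
from neovital.synthetic_cohort import designed_auc_cohort


# --- encoding / prevalence --------------------------------------------------


@pytest.mark.parametrize(
    "category, flags",
    [
        ("Death", (1, 1, 1, 1)),
        ("Severe", (1, 1, 1, 0)),
        ("Moderate", (1, 1, 0, 0)),
        ("Mild", (1, 0, 0, 0)),
        ("Favorable", (0, 0, 0, 0)),
    ],
)
def test_encode_outcomes_nesting(category, flags):
    out = encode_outcomes(category)
    assert (out["unfavorable"], out["mod_sev_death"], out["sev_death"], out["death"]) == flags


def test_encode_outcomes_rejects_unknown_category():
    with pytest.raises(ValueError):
        encode_outcomes("Critical")


def test_flags_are_nested_for_any_category():
    for c in ("Death", "Severe", "Moderate", "Mild", "Favorable"):
        f = encode_outcomes(c)
        assert f["death"] <= f["sev_death"] <= f["mod_sev_death"] <= f["unfavorable"]


def test_prevalence_counts_and_percent():
    cats = ["Death"] * 40 + ["Severe"] * 40 + ["Moderate"] * 41 + ["Mild"] * 144 + [
        "Favorable"
    ] * 319
    cohort = encode_outcome_table(pd.DataFrame({"outcome_category": cats}))
    p = prevalence(cohort).set_index("outcome")
    assert p.loc["unfavorable", "count"] == 265
    assert p.loc["unfavorable", "percent"] == pytest.approx(45.4, abs=0.05)
    assert p.loc["death", "percent"] == pytest.approx(6.8, abs=0.05)


def test_prevalence_all_favorable_and_empty():
    cohort = encode_outcome_table(pd.DataFrame({"outcome_category": ["Favorable"] * 10}))
    p = prevalence(cohort)
    assert (p["percent"] == 0).all()
    with pytest.raises(ValueError):
        prevalence(cohort.iloc[:0])


# --- AUC --------------------------------------------------------------------


def test_auc_perfect_separation():
    r = auc(np.r_[np.zeros(5), np.ones(5)], np.r_[np.zeros(5), np.ones(5)])
    assert r.auc == 1.0


def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(8)
    x = rng.normal(size=200).round(1)  # ties on purpose
    y = rng.integers(0, 2, size=200)
    r = auc(x, y, oriented=False)
    cases, controls = x[y == 1], x[y == 0]
    conc = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    assert r.auc == pytest.approx(conc / (len(cases) * len(controls)), abs=1e-12)


def test_auc_independent_labels_near_half():
    rng = np.random.default_rng(1)
    r = auc(rng.normal(size=20000), rng.integers(0, 2, size=20000), oriented=False)
    assert r.auc == pytest.approx(0.5, abs=0.02)


def test_auc_binormal_closed_form():
    delta = 1.19
    rng = np.random.default_rng(5)
    n = 40000
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=n) + delta * y
    r = auc(x, y)
    assert r.auc == pytest.approx(norm.cdf(delta / math.sqrt(2)), abs=0.01)


def test_auc_orientation_folds_risk_decreasing_metrics():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, size=2000)
    x = -1.0 * y + rng.normal(size=2000)
    r = auc(x, y)
    assert r.auc > 0.5 and r.orientation == -1
    assert auc(-x, y).auc == pytest.approx(r.auc, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=500)
    x = rng.normal(size=500) + 0.8 * y
    a1 = auc(x, y).auc
    a2 = auc(np.exp(x), y).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_auc_single_class_undefined():
    assert math.isnan(auc(np.arange(5.0), np.ones(5)).auc)


def test_rank_metrics_orders_by_auc():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, size=400)
    df = pd.DataFrame(
        {
            "day_of_life": 7,
            "good": y + rng.normal(0, 0.5, 400),
            "weak": y + rng.normal(0, 3.0, 400),
            "noise": rng.normal(size=400),
            "unfavorable": y,
        }
    )
    res = rank_metrics(df, ["good", "weak", "noise"], "unfavorable", day_of_life=7)
    assert [r.metric for r in res] == ["good", "weak", "noise"]
    assert [r.rank for r in res] == [1, 2, 3]


# --- clustered CV -----------------------------------------------------------


def _twin_cohort(n=600, target=0.85, seed=0, twin_every=5):
    df = designed_auc_cohort(target, n, seed)
    preg = [f"preg{i // 2:05d}" if (i // 2) % twin_every == 0 else f"preg_s{i:05d}"
            for i in range(n)]
    df["pregnancy_id"] = preg
    return df


def test_cluster_folds_never_split_a_pregnancy():
    df = _twin_cohort()
    for seed in (0, 1, 99):
        assign = cluster_folds(df["pregnancy_id"], 10, seed)
        fold_of = df["pregnancy_id"].map(assign)
        per_preg = fold_of.groupby(df["pregnancy_id"]).nunique()
        assert (per_preg == 1).all()
        # balanced within one cluster of each other
        sizes = fold_of.value_counts()
        assert sizes.max() - sizes.min() <= 2


def test_cluster_folds_requires_enough_clusters():
    with pytest.raises(ValueError):
        cluster_folds(["a", "a", "b"], 3, 0)


def test_clustered_cv_on_singleton_clusters_recovers_known_auc():
    df = designed_auc_cohort(0.85, 4000, seed=11)
    r = clustered_cv(df, ["marker"], "unfavorable", seed=1)
    assert r.auc == pytest.approx(0.85, abs=0.02)


def test_clustered_cv_null_is_half():
    # a single shuffle has sd ~0.013; average a few to pin down the mean
    rng = np.random.default_rng(7)
    df = designed_auc_cohort(0.85, 3000, seed=3)
    vals = []
    for rep in range(3):
        df["unfavorable"] = rng.permutation(df["unfavorable"].to_numpy())
        vals.append(clustered_cv(df, ["marker"], "unfavorable", seed=rep).auc)
    assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


def test_clustered_cv_deterministic_given_seed():
    df = _twin_cohort(800, seed=5)
    a = clustered_cv(df, ["marker"], "unfavorable", seed=42).auc
    b = clustered_cv(df, ["marker"], "unfavorable", seed=42).auc
    assert a == b


# --- spline risk curves -----------------------------------------------------


def test_spline_curve_flat_under_null():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(
        {"m": rng.normal(size=2000), "unfavorable": rng.integers(0, 2, size=2000)}
    )
    c = spline_risk_curve(df, "m", "unfavorable")
    assert np.nanmax(np.abs(c.probability - c.event_rate)) < 0.1
    assert c.significant.mean() < 0.2


def test_spline_curve_recovers_monotone_logistic_risk():
    rng = np.random.default_rng(10)
    x = rng.normal(size=4000)
    p = 1 / (1 + np.exp(-(-0.3 + 1.2 * x)))
    y = (rng.random(4000) < p).astype(int)
    df = pd.DataFrame({"m": x, "unfavorable": y})
    c = spline_risk_curve(df, "m", "unfavorable")
    truth = 1 / (1 + np.exp(-(-0.3 + 1.2 * c.grid)))
    inside = (truth >= c.ci_low - 0.03) & (truth <= c.ci_high + 0.03)
    assert inside.mean() > 0.9
    assert c.significant.any()


def test_spline_curve_requires_variation_and_size():
    df = pd.DataFrame({"m": np.ones(100), "unfavorable": np.r_[np.zeros(50), np.ones(50)]})
    with pytest.raises(ValueError):
        spline_risk_curve(df, "m", "unfavorable")
    small = pd.DataFrame({"m": np.arange(20.0), "unfavorable": [0, 1] * 10})
    with pytest.raises(ValueError):
        spline_risk_curve(small, "m", "unfavorable")


# --- fixed model, importance, selection -------------------------------------


@pytest.fixture(scope="module")
def signal_cohort():
    """sp_walk carries the outcome signal; the other two are noise."""
    rng = np.random.default_rng(12)
    n = 1500
    y = rng.integers(0, 2, size=n)
    df = pd.DataFrame(
        {
            "infant_id": [f"i{k}" for k in range(n)],
            "pregnancy_id": [f"p{k}" for k in range(n)],
            "day_of_life": 7,
            "sp_walk": -1.4 * y + rng.normal(size=n),
            "sp_mean": rng.normal(size=n),
            "hr_entropy_diff": rng.normal(size=n),
            "unfavorable": y,
        }
    )
    return df


def test_fixed_model_tracks_the_single_informative_feature(signal_cohort):
    fm = fixed_model(signal_cohort, "unfavorable", day_of_life=7, seed=2)
    single = auc(signal_cohort["sp_walk"], signal_cohort["unfavorable"]).auc
    assert fm.auc == pytest.approx(single, abs=0.03)


def test_fixed_model_all_noise_near_half(signal_cohort):
    df = signal_cohort.copy()
    rng = np.random.default_rng(0)
    df["sp_walk"] = rng.normal(size=len(df))
    fm = fixed_model(df, "unfavorable", day_of_life=7, seed=2)
    assert fm.auc == pytest.approx(0.5, abs=0.04)


def test_fixed_model_robust_to_duplicated_feature(signal_cohort):
    df = signal_cohort.copy()
    df["sp_walk_copy"] = df["sp_walk"]
    a = clustered_cv(df, list(FIXED_MODEL_FEATURES), "unfavorable", seed=2).auc
    b = clustered_cv(df, [*FIXED_MODEL_FEATURES, "sp_walk_copy"], "unfavorable", seed=2).auc
    assert abs(a - b) < 0.01


def test_variable_importance_of_noise_is_negligible(signal_cohort):
    d = variable_importance(
        signal_cohort, list(FIXED_MODEL_FEATURES), "sp_mean", "unfavorable", seed=2
    )
    assert abs(d) < 0.02


def test_variable_importance_of_the_signal_feature_is_the_signal(signal_cohort):
    d = variable_importance(
        signal_cohort, list(FIXED_MODEL_FEATURES), "sp_walk", "unfavorable", seed=2
    )
    single = auc(signal_cohort["sp_walk"], signal_cohort["unfavorable"]).auc
    assert d == pytest.approx(single - 0.5, abs=0.05)


def test_variable_importance_rejects_absent_metric(signal_cohort):
    with pytest.raises(ValueError):
        variable_importance(signal_cohort, ["sp_walk"], "hr_mean", "unfavorable")


def test_select_features_finds_the_informative_metric(signal_cohort):
    got = select_features(
        signal_cohort, ["sp_walk", "sp_mean", "hr_entropy_diff"], "unfavorable", seed=2
    )
    assert got == ["sp_walk"]


def test_select_features_drops_a_perfectly_redundant_copy(signal_cohort):
    df = signal_cohort.copy()
    df["sp_walk_copy"] = df["sp_walk"]
    got = select_features(df, ["sp_walk", "sp_walk_copy", "sp_mean"], "unfavorable", seed=2)
    assert len(got) == 1 and got[0] in ("sp_walk", "sp_walk_copy")


def test_select_features_all_noise_selects_nothing(signal_cohort):
    df = signal_cohort.copy()
    rng = np.random.default_rng(3)
    for c in ("sp_walk", "sp_mean", "hr_entropy_diff"):
        df[c] = rng.normal(size=len(df))
    got = select_features(df, ["sp_walk", "sp_mean", "hr_entropy_diff"], "unfavorable", seed=2)
    # pure noise: nothing, or at most one spuriously-best metric
    assert len(got) <= 1


def test_select_features_empty_candidates_rejected(signal_cohort):
    with pytest.raises(ValueError):
        select_features(signal_cohort, [], "unfavorable")


# --- trajectories -----------------------------------------------------------


def _multi_day_cohort(auc_by_day):
    rng = np.random.default_rng(20)
    frames = []
    for day, target in auc_by_day.items():
        df = designed_auc_cohort(target, 400, seed=100 + day)
        df["day_of_life"] = day
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def test_trajectory_constant_auc_smooths_to_itself():
    df = _multi_day_cohort({d: 0.8 for d in range(1, 8)})
    t = trajectory(df, "marker", "unfavorable", days=range(1, 8))
    defined = np.isfinite(t.auc)
    assert defined.all()
    np.testing.assert_allclose(t.smoothed, np.convolve(t.auc, np.ones(1), "same"), atol=0.05)


def test_trajectory_single_defined_day_dominates_window():
    df = _multi_day_cohort({3: 0.8})
    t = trajectory(df, "marker", "unfavorable", days=range(1, 6))
    assert np.isfinite(t.auc).sum() == 1
    np.testing.assert_allclose(t.smoothed, t.auc[2])


def test_trajectory_monotone_signal_gives_monotone_smoothed_curve():
    targets = {d: 0.55 + 0.04 * d for d in range(1, 9)}
    df = _multi_day_cohort(targets)
    t = trajectory(df, "marker", "unfavorable", days=range(1, 9))
    assert (np.diff(t.smoothed) > -0.015).all()
    assert t.smoothed[-1] > t.smoothed[0] + 0.1
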