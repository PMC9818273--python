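"""Survival-stage tests: Cox fitting against simulation ground truth,
screening behavior, concordance properties, bootstrap comparison, tertile
stratification and Kaplan-Meier group tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnspatial.prognosis import (
    assign_groups,
    bootstrap_compare,
    build_index,
    concordance,
    fit_cox,
    km_analysis,
    screen_univariate,
    stratify,
    tertile_thresholds,
)
from lnspatial.prognosis import test_independence as independent_of_n_stage
from lnspatial.synthetic import SurvivalSimSpec, draw_n_stage, simulate_survival


def surv_frame(time, event, **covs):
    return pd.DataFrame({"time": time, "event": event, **covs})


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


def test_identical_groups_have_zero_coefficient():
    time = np.tile([3.0, 5.0, 8.0, 13.0, 21.0, 34.0], 2)
    event = np.tile([1, 0, 1, 1, 0, 1], 2)
    group = np.repeat([0.0, 1.0], 6)
    fit = fit_cox(surv_frame(time, event, g=group), ["g"])
    assert abs(fit.beta[0]) < 1e-6
    assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)


def test_exponential_rate_ratio_recovered():
    rng = np.random.default_rng(100)
    n = 5000
    group = rng.integers(0, 2, n).astype(float)
    time = rng.exponential(1.0 / np.where(group == 1, 2.0, 1.0))
    fit = fit_cox(surv_frame(time, np.ones(n, int), g=group), ["g"])
    assert 1.8 <= fit.hr[0] <= 2.2


def test_fit_cox_error_conditions():
    with pytest.raises(ValueError, match="no observed events"):
        fit_cox(surv_frame([1.0, 2.0], [0, 0], x=[0.0, 1.0]), ["x"])
    with pytest.raises(ValueError, match="constant"):
        fit_cox(surv_frame([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 1.0, 1.0]), ["x"])


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def _cohort(rng, n=300, beta=1.0):
    factors = pd.DataFrame(
        {"f_signal": rng.normal(size=n), "f_noise": rng.normal(size=n)},
        index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
    )
    cov = factors.copy()
    cov["n_stage"] = draw_n_stage(n, (0.3, 0.5, 0.2), rng)
    spec = SurvivalSimSpec(betas={"f_signal": beta, "n_stage": 0.5}, scale=30.0, censor_rate=0.01)
    surv = simulate_survival(cov, spec, rng)
    clinical = cov[["n_stage"]].join(surv)
    return factors, clinical


def test_screen_retains_signal_not_alpha_zero():
    rng = np.random.default_rng(7)
    factors, clinical = _cohort(rng)
    retained = screen_univariate(factors, clinical)
    assert "f_signal" in retained
    assert screen_univariate(factors, clinical, alpha=0.0) == []


def test_screen_rejects_empty_table():
    with pytest.raises(ValueError, match="empty factor table"):
        screen_univariate(pd.DataFrame(), pd.DataFrame({"time": [1.0], "event": [1]}))


def test_independence_drops_collinear_factor():
    rng = np.random.default_rng(8)
    factors, clinical = _cohort(rng)
    factors = factors.copy()
    factors["f_collinear"] = 2.0 * clinical["n_stage"] - 1.0
    assert not independent_of_n_stage("f_collinear", factors, clinical)
    assert independent_of_n_stage("f_signal", factors, clinical)


def test_confounded_factor_dropped_more_often_than_kept():
    rng = np.random.default_rng(9)
    kept = 0
    reps = 40
    for _ in range(reps):
        n = 250
        n_stage = draw_n_stage(n, (0.3, 0.5, 0.2), rng)
        # factor's only association with survival flows through N stage
        factors = pd.DataFrame(
            {"f_conf": n_stage + rng.normal(0, 0.25, n)},
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )
        cov = pd.DataFrame({"n_stage": n_stage}, index=factors.index)
        spec = SurvivalSimSpec(betas={"n_stage": 1.0}, scale=30.0, censor_rate=0.01)
        surv = simulate_survival(cov, spec, rng)
        clinical = cov.join(surv)
        if "f_conf" in screen_univariate(factors, clinical) and independent_of_n_stage(
            "f_conf", factors, clinical
        ):
            kept += 1
    assert kept < reps / 3


# ---------------------------------------------------------------------------
# combined index
# ---------------------------------------------------------------------------


def test_build_index_location_and_permutation_invariance():
    rng = np.random.default_rng(12)
    factors, clinical = _cohort(rng, n=400)
    fit, index = build_index(factors, clinical, ["f_signal", "f_noise"])

    shifted = factors.copy()
    shifted["f_signal"] = shifted["f_signal"] + 10.0
    fit2, index2 = build_index(shifted, clinical, ["f_signal", "f_noise"])
    np.testing.assert_allclose(fit2.hr, fit.hr, rtol=1e-5)
    np.testing.assert_allclose(index2 - index, fit.beta[0] * 10.0, atol=1e-5)
    # group assignment from each index's own tertiles is unchanged
    g1 = assign_groups(index, tertile_thresholds(index))
    g2 = assign_groups(index2, tertile_thresholds(index2))
    assert (g1 == g2).all()

    perm = rng.permutation(len(factors))
    fit3, index3 = build_index(factors.iloc[perm], clinical.iloc[perm], ["f_signal", "f_noise"])
    np.testing.assert_allclose(index3.loc[index.index], index, atol=1e-9)


def test_build_index_requires_retained_factor():
    rng = np.random.default_rng(13)
    factors, clinical = _cohort(rng, n=50)
    with pytest.raises(ValueError, match="no retained factors"):
        build_index(factors, clinical, [])


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def test_perfect_ranking_has_unit_concordance():
    time = np.array([2.0, 5.0, 9.0, 14.0])
    index = -time  # higher index fails earlier
    assert concordance(index, time, np.ones(4, int)) == 1.0
    assert concordance(-index, time, np.ones(4, int)) == 0.0  # antisymmetry


def test_uninformative_index_near_half():
    rng = np.random.default_rng(15)
    n = 2000
    time = rng.exponential(10.0, n)
    index = rng.normal(size=n)
    assert concordance(index, time, np.ones(n, int)) == pytest.approx(0.5, abs=0.03)


# ---------------------------------------------------------------------------
# bootstrap comparison
# ---------------------------------------------------------------------------


def test_identical_indices_give_p_one_and_seeded_determinism():
    rng = np.random.default_rng(16)
    n = 120
    time = rng.exponential(10, n)
    event = rng.integers(0, 2, n)
    event[0] = 1
    idx = rng.normal(size=n)
    out = bootstrap_compare(idx, idx.copy(), time, event, n_boot=200, seed=5)
    assert out["p"] == 1.0
    out2 = bootstrap_compare(idx, idx.copy(), time, event, n_boot=200, seed=5)
    assert out == out2
    with pytest.warns(UserWarning, match="small"):
        bootstrap_compare(idx, idx, time, event, n_boot=50, seed=1)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def test_tertiles_of_one_to_nine():
    idx = pd.Series(np.arange(1.0, 10.0), index=[f"P{i}" for i in range(9)])
    t_low, t_high = tertile_thresholds(idx)
    assert t_low == pytest.approx(11.0 / 3.0, abs=1e-9)
    assert t_high == pytest.approx(19.0 / 3.0, abs=1e-9)
    strat = stratify(idx)
    assert strat.group_sizes() == {"G1": 3, "G2": 3, "G3": 3}


def test_degenerate_identical_indices_all_low_risk():
    idx = pd.Series(np.ones(6), index=[f"P{i}" for i in range(6)])
    with pytest.warns(UserWarning, match="degenerate"):
        strat = stratify(idx)
    assert strat.group_sizes() == {"G1": 6, "G2": 0, "G3": 0}


def test_tertiles_require_three_patients():
    with pytest.raises(ValueError, match="at least 3"):
        tertile_thresholds(np.array([1.0, 2.0]))


def test_shifted_validation_cohort_changes_group_proportions():
    rng = np.random.default_rng(18)
    disc = pd.Series(rng.normal(0, 1, 300), index=[f"D{i}" for i in range(300)])
    val = pd.Series(rng.normal(-1.0, 1, 300), index=[f"V{i}" for i in range(300)])
    thresholds = tertile_thresholds(disc)
    groups = assign_groups(val, thresholds)
    sizes = groups.value_counts()
    assert sizes.get("G1", 0) > 130  # downward shift over-represents low risk


@given(st.lists(st.floats(-50, 50), min_size=3, max_size=60, unique=True))
@settings(max_examples=60, deadline=None)
def test_discovery_tertile_sizes_differ_by_at_most_two(values):
    idx = pd.Series(values, index=[f"P{i}" for i in range(len(values))])
    strat = stratify(idx)
    sizes = list(strat.group_sizes().values())
    assert max(sizes) - min(sizes) <= 2
    # ties broken toward the lower-risk group
    t_low, t_high = strat.thresholds
    assert (idx[strat.labels == "G1"] <= t_low + 1e-12).all()
    assert (idx[strat.labels == "G3"] > t_high - 1e-12).all()


# ---------------------------------------------------------------------------
# Kaplan-Meier analysis
# ---------------------------------------------------------------------------


def test_group_without_events_has_full_survival():
    clinical = surv_frame(
        time=[40.0, 50.0, 60.0, 10.0, 20.0, 30.0],
        event=[0, 0, 0, 1, 1, 1],
    )
    clinical.index = [f"P{i}" for i in range(6)]
    groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=clinical.index)
    out = km_analysis(groups, clinical, horizon=36.0)
    assert out["survival_at_horizon"]["G1"] == 1.0
    assert out["survival_at_horizon"]["G2"] == 0.0


def test_identical_groups_have_unit_hazard_ratio():
    time = np.tile([3.0, 6.0, 9.0, 15.0, 25.0, 40.0], 2)
    event = np.tile([1, 1, 0, 1, 0, 1], 2)
    clinical = surv_frame(time=time, event=event)
    clinical.index = [f"P{i}" for i in range(12)]
    groups = pd.Series(["G1"] * 6 + ["G2"] * 6, index=clinical.index)
    out = km_analysis(groups, clinical)
    row = out["pairwise"].iloc[0]
    assert row["HR"] == pytest.approx(1.0, abs=1e-4)
    assert row["p_logrank"] > 0.95


def test_km_requires_two_groups():
    clinical = surv_frame(time=[1.0, 2.0], event=[1, 1])
    clinical.index = ["a", "b"]
    with pytest.raises(ValueError, match="two non-empty groups"):
        km_analysis(pd.Series(["G1", "G1"], index=clinical.index), clinical)
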