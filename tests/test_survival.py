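import math

import numpy as np
import pandas as pd
import pytest

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank, multivariate_logrank_test

from psmaburden import survival as surv


def sim_cox_cohort(n, beta, seed, censor=None):
    """Exponential PH cohort: hazard = 0.06 * exp(beta * log2 x), x lognormal."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=3.0, sigma=1.2, size=n)
    hazard = 0.06 * np.exp(beta * (np.log2(x) - np.median(np.log2(x))))
    t = rng.exponential(1.0 / hazard)
    if censor is None:
        time, event = t, np.ones(n)
    else:
        c = rng.uniform(*censor, size=n)
        time, event = np.minimum(t, c), (t <= c).astype(float)
    return pd.DataFrame({"time_months": time, "event": event, "x": x,
                         "x_log2": np.log2(x)})


# ---------------------------------------------------------------------------
# log2 transform
# ---------------------------------------------------------------------------

def test_log2_covariates_examples_and_errors():
    table = pd.DataFrame({"patient_id": ["a", "b"], "tv": [8.0, 1.0],
                          "time_months": [1, 2], "event": [1, 0]})
    out = surv.log2_covariates(table, ["tv"])
    assert list(out["tv_log2"]) == [3.0, 0.0]
    bad = table.assign(tv=[8.0, 0.0])
    with pytest.raises(surv.TransformError, match="b"):
        surv.log2_covariates(bad, ["tv"])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def test_cox_recovers_known_hazard_ratio():
    table = sim_cox_cohort(n=500, beta=math.log(1.30), seed=7)
    fit = surv.fit_cox(table, ["x_log2"])
    assert 1.20 <= fit.hazard_ratio("x_log2") <= 1.41
    c = fit.coefficients.iloc[0]
    assert c["ci_low"] <= c["hr"] <= c["ci_high"]
    assert c["hr"] == pytest.approx(math.exp(c["coef"]))


def test_cox_null_covariate_small_effect():
    """Under beta=0 the Wald z is approximately standard normal, not inflated."""
    zs = []
    for seed in range(10):
        table = sim_cox_cohort(n=500, beta=0.0, seed=seed)
        c = surv.fit_cox(table, ["x_log2"]).coefficients.iloc[0]
        zs.append(c["coef"] / c["se"])
    zs = np.asarray(zs)
    assert np.sum(np.abs(zs) < 2.5) >= 9
    assert abs(zs.mean()) < 0.75  # no systematic bias


def test_cox_collinear_covariates_rejected():
    table = sim_cox_cohort(n=100, beta=0.3, seed=3)
    table["x2_log2"] = table["x_log2"]
    with pytest.raises(surv.FitError, match="collinear"):
        surv.fit_cox(table, ["x_log2", "x2_log2"])


def test_cox_requires_two_events():
    table = sim_cox_cohort(n=20, beta=0.0, seed=1)
    table["event"] = 0
    table.loc[0, "event"] = 1
    with pytest.raises(surv.FitError, match="events"):
        surv.fit_cox(table, ["x_log2"])


def test_cox_matches_lifelines_oracle():
    from lifelines import CoxPHFitter

    table = sim_cox_cohort(n=300, beta=0.4, seed=5, censor=(1.0, 40.0))
    fit = surv.fit_cox(table, ["x_log2"], ties="efron")  # lifelines uses Efron
    cph = CoxPHFitter().fit(table[["time_months", "event", "x_log2"]],
                            duration_col="time_months", event_col="event")
    assert fit.coefficients.loc["x_log2", "coef"] == pytest.approx(
        cph.params_["x_log2"], rel=1e-4
    )


# ---------------------------------------------------------------------------
# stepwise backward elimination
# ---------------------------------------------------------------------------

def sim_driver_proxy(n, seed, beta=math.log(1.6), rho=0.6):
    """Driver A with hazard effect; proxy B rank-correlated with A, no effect."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    a_log2 = 1.2 * z
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    b_log2 = r * z + math.sqrt(1 - r**2) * rng.normal(size=n)
    hazard = 0.06 * np.exp(beta * a_log2)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(5.0, 60.0, size=n)
    return pd.DataFrame(
        {
            "time_months": np.minimum(t, c),
            "event": (t <= c).astype(float),
            "a_log2": a_log2,
            "b_log2": b_log2,
        }
    )


def test_stepwise_removes_correlated_proxy_keeps_driver():
    table = sim_driver_proxy(n=800, seed=42)
    res = surv.stepwise_backward_lr(table, ["a_log2", "b_log2"])
    assert res.final.covariate_names == ["a_log2"]
    assert res.removal_trace[0][0] == "b_log2"
    assert res.removal_trace[0][1] >= 0.10


def test_stepwise_single_strong_covariate_retained_with_empty_trace():
    table = sim_cox_cohort(n=400, beta=0.5, seed=9)
    res = surv.stepwise_backward_lr(table, ["x_log2"])
    assert res.final.covariate_names == ["x_log2"]
    assert res.removal_trace == ()


def test_stepwise_all_noise_empties_model():
    rng = np.random.default_rng(17)
    n = 300
    table = pd.DataFrame(
        {
            "time_months": rng.exponential(10.0, n),
            "event": np.ones(n),
            "u_log2": rng.normal(size=n),
            "v_log2": rng.normal(size=n),
        }
    )
    res = surv.stepwise_backward_lr(table, ["u_log2", "v_log2"])
    assert res.final.covariate_names == []
    assert len(res.removal_trace) == 2


def test_stepwise_trace_is_reproducible():
    table = sim_driver_proxy(n=400, seed=3)
    r1 = surv.stepwise_backward_lr(table, ["a_log2", "b_log2"])
    r2 = surv.stepwise_backward_lr(table, ["a_log2", "b_log2"])
    assert r1.removal_trace == r2.removal_trace
    assert r1.final.covariate_names == r2.final.covariate_names


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_product_limit_no_censoring():
    km = surv.km_estimate(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]))
    assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
    assert km.median == 2.0
    assert np.array_equal(km.at_risk, [4, 3, 2, 1])


def test_km_hand_product_limit_with_censoring():
    # times 1,2+,3,4 (2 censored): S = 3/4, then 3/4*(1/2)=0.375, then 0
    km = surv.km_estimate(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 1]))
    assert np.allclose(km.survival, [0.75, 0.375, 0.0])
    assert km.median == 3.0


def test_km_all_censored_median_not_reached():
    km = surv.km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
    assert km.times.size == 0
    assert not km.median_is_reached
    assert km.median_ci == (float("inf"), float("inf"))


def test_km_median_matches_exponential_closed_form():
    rng = np.random.default_rng(23)
    lam = 0.08
    t = rng.exponential(1 / lam, size=2000)
    km = surv.km_estimate(t, np.ones(2000))
    assert km.median == pytest.approx(math.log(2) / lam, rel=0.05)


def test_km_matches_lifelines_loglog_ci():
    rng = np.random.default_rng(4)
    t = rng.exponential(12.0, 80)
    e = rng.integers(0, 2, 80)
    e[0] = 1
    km = surv.km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    ours = pd.Series(km.survival, index=km.times)
    theirs = kmf.survival_function_["KM_estimate"].reindex(ours.index)
    assert np.allclose(ours.to_numpy(), theirs.to_numpy())
    ci = kmf.confidence_interval_.reindex(ours.index)  # lifelines default is log-log
    assert np.allclose(km.ci_low, ci.iloc[:, 0].to_numpy(), atol=1e-8)
    assert np.allclose(km.ci_high, ci.iloc[:, 1].to_numpy(), atol=1e-8)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = np.array([1.0, 3.0, 5.0, 7.0])
    e = np.array([1, 1, 0, 1])
    res = surv.logrank_test((t, e), (t, e))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_hand_computed_two_group():
    # groups {1,2} vs {3,4}, all events: chi2 = 49/17
    res = surv.logrank_test((np.array([1.0, 2.0]), np.array([1, 1])),
                            (np.array([3.0, 4.0]), np.array([1, 1])))
    assert res.chi2 == pytest.approx(49.0 / 17.0, rel=1e-12)
    assert res.df == 1


@pytest.mark.parametrize("k", [2, 3])
def test_logrank_matches_lifelines(k):
    rng = np.random.default_rng(31)
    times = [rng.exponential(10.0 * (i + 1), 60) for i in range(k)]
    events = [rng.integers(0, 2, 60) for _ in range(k)]
    res = surv.logrank_test(*[(t, e) for t, e in zip(times, events)])
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    g_all = np.concatenate([np.full(60, i) for i in range(k)])
    ref = multivariate_logrank_test(t_all, g_all, e_all)
    assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_separated_groups_significant():
    rng = np.random.default_rng(2)
    a = rng.exponential(30.0, 200)
    b = rng.exponential(10.0, 200)  # hazard ratio 3
    res = surv.logrank_test((a, np.ones(200)), (b, np.ones(200)))
    assert res.p < 0.001


# ---------------------------------------------------------------------------
# stratification and cutoffs
# ---------------------------------------------------------------------------

def test_quartile_stratify_exact_split():
    labels = surv.quantile_stratify(np.arange(1, 9), "quartiles")
    _, counts = np.unique(labels, return_counts=True)
    assert list(counts) == [2, 2, 2, 2]


def test_pooled_quintile_scheme_sizes():
    labels = surv.quantile_stratify(np.arange(1, 11), "quintile_1_24_5")
    assert list(labels).count("Q1") == 2
    assert list(labels).count("Q2-4") == 6
    assert list(labels).count("Q5") == 2


def test_degenerate_stratification_warns_single_group():
    with pytest.warns(UserWarning, match="degenerate"):
        labels = surv.quantile_stratify(np.full(20, 3.0), "quartiles")
    assert len(np.unique(labels)) == 1


def test_cutoff_finder_equals_brute_force_oracle():
    rng = np.random.default_rng(8)
    n = 50
    x = rng.lognormal(1.0, 0.8, n)
    t = rng.exponential(10.0 / (1 + x / np.median(x)), n)
    e = rng.integers(0, 2, n)
    e[:5] = 1
    table = pd.DataFrame({"time_months": t, "event": e, "x": x})
    res = surv.find_ideal_cutoff(table, "x", min_group_fraction=0.10)

    distinct = np.unique(x)
    best_p, best_cut = None, None
    n_admissible = 0
    for cut in (distinct[:-1] + distinct[1:]) / 2:
        above = x > cut
        if above.sum() < 0.10 * n or (~above).sum() < 0.10 * n:
            continue
        n_admissible += 1
        p = ll_logrank(t[above], t[~above], e[above], e[~above]).p_value
        if best_p is None or p < best_p:
            best_p, best_cut = p, cut
    assert res.cutoff == pytest.approx(best_cut)
    assert res.p == pytest.approx(best_p, rel=1e-9)
    assert res.n_candidates == n_admissible


def test_cutoff_finder_recovers_separating_threshold():
    rng = np.random.default_rng(5)
    n_half = 60
    x = np.concatenate([rng.uniform(1.0, 3.0, n_half), rng.uniform(6.0, 9.0, n_half)])
    t = np.concatenate([rng.exponential(30.0, n_half), rng.exponential(6.0, n_half)])
    table = pd.DataFrame({"time_months": t, "event": np.ones(2 * n_half), "x": x})
    res = surv.find_ideal_cutoff(table, "x")
    # cutoff separates the two latent populations (x supports [1,3] and [6,9])
    truth = x >= 6.0
    agreement = np.mean((x > res.cutoff) == truth)
    assert agreement >= 0.95
    assert res.p < 1e-6
    assert res.median_below > res.median_above


def test_relaxing_group_fraction_never_raises_min_p():
    rng = np.random.default_rng(13)
    n = 80
    x = rng.lognormal(0.0, 1.0, n)
    t = rng.exponential(10.0, n)
    table = pd.DataFrame({"time_months": t, "event": np.ones(n), "x": x})
    p_strict = surv.find_ideal_cutoff(table, "x", min_group_fraction=0.25).p
    p_loose = surv.find_ideal_cutoff(table, "x", min_group_fraction=0.05).p
    assert p_loose <= p_strict + 1e-12


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def brute_force_spearman(x, y):
    """Rank by enumeration (average ranks), then Pearson on ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        return np.array([(np.sum(v < vi) + 1 + np.sum(v <= vi)) / 2.0 for vi in v])

    rx, ry = ranks(x), ranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def test_spearman_monotone_invariance_and_reversal():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert surv.spearman_correlation(x, x**2)[0] == pytest.approx(1.0)
    assert surv.spearman_correlation(x, -x)[0] == pytest.approx(-1.0)


@pytest.mark.parametrize("seed", range(5))
def test_spearman_matches_enumeration_oracle_small_n(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 4, 5).astype(float)  # ties included
    y = rng.integers(0, 4, 5).astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    rho, _ = surv.spearman_correlation(x, y)
    assert rho == pytest.approx(brute_force_spearman(x, y), rel=1e-12)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        surv.spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_mann_whitney_exact_enumeration():
    u, p = surv.mann_whitney_u([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements this extreme


def test_mann_whitney_identical_samples_nonsignificant():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    _, p = surv.mann_whitney_u(a, a)
    assert p > 0.99


def test_mann_whitney_large_shift_significant():
    rng = np.random.default_rng(6)
    a = rng.normal(0.0, 1.0, 50)
    b = rng.normal(2.0, 1.0, 50)  # shift of 2 sd
    _, p = surv.mann_whitney_u(a, b)
    assert p < 0.001
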