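import numpy as np
import pytest

from krassig import (
    SurvivalTable,
    cox_fit,
    km_estimate,
    logrank_test,
    simulate_survival,
    stratify_by_score,
)
from krassig.survival import SurvivalError


def _table(times, events, **kwargs):
    return SurvivalTable(
        sample_ids=[f"p{i}" for i in range(len(times))],
        time=np.asarray(times, float),
        event=np.asarray(events, int),
        **kwargs,
    )


# -- Kaplan-Meier -----------------------------------------------------------


def test_km_all_censored_stays_at_one():
    km = km_estimate(_table([5, 6, 7], [0, 0, 0]))
    assert km.survival_at(100) == 1.0


def test_km_no_censoring_is_empirical_survival():
    km = km_estimate(_table([1, 2, 3], [1, 1, 1]))
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
    np.testing.assert_array_equal(km.n_at_risk, [3, 2, 1])


def test_km_hand_product_with_censoring():
    # events at 1 (n=5) and 4 (n=2): S = 4/5 * 1/2
    km = km_estimate(_table([1, 2, 3, 4, 5], [1, 0, 0, 1, 0]))
    assert km.survival_at(1) == pytest.approx(4 / 5)
    assert km.survival_at(4) == pytest.approx(4 / 5 * 1 / 2)
    assert np.all(np.diff(km.survival) <= 0)  # non-increasing step function


# -- log-rank ---------------------------------------------------------------


def test_logrank_identical_groups_is_null():
    table = _table([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
    res = logrank_test(table, ["a", "a", "a", "b", "b", "b"])
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_computed_hypergeometric_sums():
    # 6 patients, group B dies earlier
    table = _table([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1])
    group = np.array(["A", "A", "A", "B", "B", "B"])
    # hand computation over event times 1,2,3,4,6
    O1 = E1 = V = 0.0
    times, events, g1 = table.time, table.event, group == "B"
    for t in sorted(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    expected_chi2 = (O1 - E1) ** 2 / V
    res = logrank_test(table, group)
    assert res.chi_square == pytest.approx(expected_chi2, rel=1e-12)
    assert res.observed[1] == O1 and res.expected[1] == pytest.approx(E1)


def test_logrank_agrees_with_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(5)
    times = rng.exponential(10, size=60)
    events = (rng.random(60) < 0.8).astype(int)
    group = np.array(["a"] * 30 + ["b"] * 30)
    times[group == "b"] *= 0.6
    res = logrank_test(_table(times, events), group)
    ll = ll_logrank(times[:30], times[30:], events[:30], events[30:])
    assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)


def test_logrank_requires_two_groups_and_events():
    with pytest.raises(SurvivalError):
        logrank_test(_table([1, 2], [1, 1]), ["a", "a"])
    with pytest.raises(SurvivalError, match="no events"):
        logrank_test(_table([1, 2], [0, 0]), ["a", "b"])


def test_logrank_power_on_simulated_group_effect():
    hits = 0
    for rep in range(30):
        group = np.repeat([0.0, 1.0], 150)
        table = simulate_survival(group, beta=1.0, censor_rate=0.01, seed=900 + rep)
        res = logrank_test(table, np.where(group > 0, "hi", "lo"))
        hits += res.p_value < 0.001
    assert hits >= 28  # p<0.001 in nearly every replicate at n=300


# -- Cox --------------------------------------------------------------------


def test_cox_null_and_signal_recovery():
    rng = np.random.default_rng(21)
    scores = rng.normal(size=500)
    null = simulate_survival(scores, beta=0.0, censor_rate=0.01, seed=1)
    fit0 = cox_fit(null, ["score"])
    assert abs(fit0.beta[0]) < 0.15
    betas = []
    for rep in range(20):
        s = np.random.default_rng(300 + rep).normal(size=500)
        table = simulate_survival(s, beta=0.7, censor_rate=0.005, seed=400 + rep)
        betas.append(cox_fit(table, ["score"]).beta[0])
    assert np.mean(betas) == pytest.approx(0.7, abs=0.1)


def test_cox_ci_contains_hr_and_requires_usable_covariates():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=200)
    table = simulate_survival(scores, beta=0.5, censor_rate=0.01, seed=3)
    fit = cox_fit(table, ["score"])
    assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]
    assert fit.hr[0] > 0
    with pytest.raises(SurvivalError, match="constant"):
        cox_fit(_table([1, 2, 3], [1, 1, 1], score=np.ones(3)), ["score"])
    with pytest.raises(SurvivalError, match="absent"):
        cox_fit(_table([1, 2, 3], [1, 1, 1]), ["age"])


def test_efron_and_breslow_agree_without_ties():
    """Cross-fit lifelines (Efron) vs scikit-survival (Breslow) on tie-free data."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    rng = np.random.default_rng(17)
    scores = rng.normal(size=120)
    table = simulate_survival(scores, beta=0.6, censor_rate=0.02, seed=18)
    assert len(np.unique(table.time)) == len(table.time)  # continuous: no ties
    fit = cox_fit(table, ["score"])
    y = np.array(
        [(bool(e), t) for e, t in zip(table.event, table.time)],
        dtype=[("event", bool), ("time", float)],
    )
    sk = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200)
    sk.fit(table.score.reshape(-1, 1), y)
    assert fit.beta[0] == pytest.approx(sk.coef_[0], abs=1e-6)


def test_cox_score_test_matches_logrank_for_binary_covariate():
    """Classical equivalence: the one-covariate Cox score test IS the log-rank test."""
    rng = np.random.default_rng(9)
    group = np.repeat([0.0, 1.0], 40)
    table = simulate_survival(group, beta=0.8, censor_rate=0.02, seed=10)
    lr = logrank_test(table, np.where(group > 0, "hi", "lo"))
    # score statistic U(0)^2 / I(0) computed from the partial likelihood at beta=0
    order = np.argsort(table.time)
    t, e, x = table.time[order], table.event[order], group[order]
    U = I = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        xbar = x[risk].mean()
        U += x[i] - xbar
        I += (x[risk] ** 2).mean() - xbar**2
    assert U**2 / I == pytest.approx(lr.chi_square, abs=1e-6)


# -- stratification ---------------------------------------------------------


def test_median_split_assigns_ties_to_low():
    table = _table(np.ones(10), np.ones(10), score=np.arange(1.0, 11.0))
    labels = stratify_by_score(table, quantile=0.5)
    assert list(labels) == ["low"] * 5 + ["high"] * 5


def test_constant_scores_cannot_stratify():
    table = _table([1, 2], [1, 1], score=np.array([3.0, 3.0]))
    with pytest.raises(SurvivalError, match="cannot stratify"):
        stratify_by_score(table)


def test_within_status_thresholds_are_per_stratum():
    score = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
    status = np.array(["wt"] * 4 + ["mut"] * 4, dtype=object)
    table = _table(np.ones(8), np.ones(8), score=score, status=status)
    labels = stratify_by_score(table, within_status=True)
    # each stratum splits at its own median: two high per stratum
    assert list(labels) == ["low", "low", "high", "high"] * 2


def test_mutant_high_stratum_has_worst_survival_when_hazard_is_mutant_linked():
    """Qualitative genotype x signature pattern: score raises hazard only in mutants."""
    rng = np.random.default_rng(77)
    n = 400
    status = np.array(["mut"] * (n // 2) + ["wt"] * (n // 2), dtype=object)
    score = rng.normal(size=n) + (status == "mut") * 1.0
    mut = status == "mut"
    t_mut = simulate_survival(score[mut], beta=1.2, censor_rate=0.01, seed=1)
    t_wt = simulate_survival(score[~mut], beta=0.0, censor_rate=0.01, seed=2)
    table = _table(
        np.concatenate([t_mut.time, t_wt.time]),
        np.concatenate([t_mut.event, t_wt.event]),
        score=score[np.concatenate([np.flatnonzero(mut), np.flatnonzero(~mut)])],
        status=status[np.concatenate([np.flatnonzero(mut), np.flatnonzero(~mut)])],
    )
    labels = stratify_by_score(table, within_status=True)
    horizon = float(np.quantile(table.time, 0.8))
    rmst = {}
    for s in ("mut", "wt"):
        for lv in ("high", "low"):
            mask = (table.status == s) & (labels == lv)
            km = km_estimate(
                _table(table.time[mask], table.event[mask])
            )
            rmst[(s, lv)] = km.restricted_mean(horizon)
    assert rmst[("mut", "high")] == min(rmst.values())
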