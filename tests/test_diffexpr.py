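import numpy as np
import pytest
from scipy import special, stats

from krassig import (
    filter_low_expression,
    moderated_de,
    select_cross_system_candidates,
    select_knockdown_signature,
)
from krassig.diffexpr import DEResult, DegenerateFitError
from tests.conftest import two_group_matrix


# ---------------------------------------------------------------------------
# expression floor filter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,floor,frac,kept",
    [
        ([4, 4, 6, 6], 5.0, 0.5, True),       # exactly 50% low: "more than" is strict
        ([1, 1, 1, 9], 5.0, 0.5, False),      # 75% low
        ([3.9, 3.9, 3.9, 8], 4.0, 0.5, False),  # knockdown-config floor of 4
        ([6, 6, 6, 6], 5.0, 0.5, True),
    ],
)
def test_floor_filter_boundary(values, floor, frac, kept):
    matrix = two_group_matrix(np.array([values], dtype=float))
    filtered = filter_low_expression(matrix, floor=floor, max_low_fraction=frac)
    assert (len(filtered.gene_ids) == 1) == kept


def test_floor_filter_preserves_order_and_handles_empty():
    values = np.vstack([[9, 9, 9, 9], [1, 1, 1, 1], [8, 8, 8, 8]]).astype(float)
    matrix = two_group_matrix(values)
    filtered = filter_low_expression(matrix)
    assert filtered.gene_ids == ["g0", "g2"]
    empty = filter_low_expression(two_group_matrix(np.ones((2, 4))))
    assert empty.n_genes == 0  # status propagated as empty matrix, not an exception


# ---------------------------------------------------------------------------
# moderated DE
# ---------------------------------------------------------------------------


def _toy_heteroscedastic(seed=3, n_genes=50, n=6):
    rng = np.random.default_rng(seed)
    sds = rng.uniform(0.2, 1.5, size=n_genes)
    values = 8.0 + rng.normal(size=(n_genes, 2 * n)) * sds[:, None]
    values[:5, :n] += 2.0
    return two_group_matrix(values)


def test_d0_zero_recovers_ordinary_pooled_t():
    matrix = _toy_heteroscedastic()
    res = moderated_de(matrix, "KRAS_mut", "KRAS_wt", d0_override=0.0)
    a = matrix.values[:, :6]
    b = matrix.values[:, 6:]
    t_plain, _ = stats.ttest_ind(a, b, axis=1, equal_var=True)
    np.testing.assert_allclose(res.t_mod, t_plain, atol=1e-10)


def test_d0_infinite_ranks_by_logfc():
    matrix = _toy_heteroscedastic()
    res = moderated_de(matrix, "KRAS_mut", "KRAS_wt", d0_override=np.inf)
    by_t = np.argsort(-np.abs(res.t_mod))
    by_fc = np.argsort(-np.abs(res.log2fc))
    np.testing.assert_array_equal(by_t, by_fc)


def test_moderated_statistics_match_independent_formula_evaluation():
    """Direct closed-form re-computation of logFC, s2, shrinkage, t, p and B."""
    matrix = _toy_heteroscedastic(seed=3)
    res = moderated_de(matrix, "KRAS_mut", "KRAS_wt", p_prior=0.01)
    a, b = matrix.values[:, :6], matrix.values[:, 6:]
    na = nb = 6
    d = na + nb - 2
    logfc = a.mean(1) - b.mean(1)
    s2 = ((na - 1) * a.var(1, ddof=1) + (nb - 1) * b.var(1, ddof=1)) / d
    # moment matching on log s2
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    excess = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    assert excess > 0  # heteroscedastic by construction
    from scipy.optimize import brentq

    d0 = 2 * brentq(lambda y: special.polygamma(1, y) - excess, 1e-3, 1e6)
    s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    s2_post = (d0 * s0 + d * s2) / (d0 + d)
    v = 1 / na + 1 / nb
    t_mod = logfc / np.sqrt(s2_post * v)
    p = 2 * stats.t.sf(np.abs(t_mod), d0 + d)
    np.testing.assert_allclose(res.log2fc, logfc, atol=1e-10)
    np.testing.assert_allclose(res.hyperparams["d0"], d0, rtol=1e-6)
    np.testing.assert_allclose(res.t_mod, t_mod, rtol=1e-6)
    np.testing.assert_allclose(res.p_value, p, rtol=1e-6)
    # B from the same hyperparameters the fit reports
    v0 = res.hyperparams["v0"]
    r = (v + v0) / v
    df = res.df_total
    kernel = (1 + df) / 2 * np.log((t_mod**2 + df) / (t_mod**2 / r + df))
    b_expected = np.log(0.01 / 0.99) - 0.5 * np.log(r) + kernel
    np.testing.assert_allclose(res.b_stat, b_expected, rtol=1e-6)


def test_location_invariance_and_monotonicity():
    matrix = _toy_heteroscedastic(seed=5)
    res = moderated_de(matrix, "KRAS_mut", "KRAS_wt")
    shifted = two_group_matrix(matrix.values + 3.25)
    res_shift = moderated_de(shifted, "KRAS_mut", "KRAS_wt")
    np.testing.assert_allclose(res.log2fc, res_shift.log2fc, atol=1e-10)
    np.testing.assert_allclose(res.t_mod, res_shift.t_mod, atol=1e-8)
    np.testing.assert_allclose(res.b_stat, res_shift.b_stat, atol=1e-6)
    # increasing a gene's mean difference at fixed variance raises |t_mod|
    boosted = matrix.values.copy()
    boosted[0, :6] += 1.0
    res_boost = moderated_de(two_group_matrix(boosted), "KRAS_mut", "KRAS_wt", d0_override=0.0)
    assert abs(res_boost.t_mod[0]) >= abs(
        moderated_de(matrix, "KRAS_mut", "KRAS_wt", d0_override=0.0).t_mod[0]
    )


def test_b_stat_sign_is_log_posterior_odds():
    """B > 0 exactly when the posterior odds under the fitted prior exceed 1."""
    matrix = _toy_heteroscedastic(seed=9)
    res = moderated_de(matrix, "KRAS_mut", "KRAS_wt")
    odds = np.exp(res.b_stat)
    assert np.all((res.b_stat > 0) == (odds > 1))
    assert np.all(np.isfinite(res.b_stat))


def test_all_zero_variance_is_degenerate():
    matrix = two_group_matrix(np.ones((5, 6)))
    with pytest.raises(DegenerateFitError):
        moderated_de(matrix, "KRAS_mut", "KRAS_wt")


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------


def _de(genes, logfc, b):
    n = len(genes)
    return DEResult(
        genes=list(genes),
        log2fc=np.asarray(logfc, float),
        t_mod=np.zeros(n),
        df_total=10.0,
        p_value=np.ones(n),
        b_stat=np.asarray(b, float),
        hyperparams={},
    )


def test_cross_system_rule_counts_systems_and_strict_boundaries():
    r1 = _de(["A", "B", "C"], [1.5, 1.0, 2.0], [1.0, 1.0, 1.0])  # B at exactly logFC=1 fails
    r2 = _de(["A", "B"], [0.2, 1.4], [1.0, 1.0])
    r3 = _de(["A", "C"], [1.2, 1.8], [0.5, -1.0])                # C fails on B<=0 here
    sets = select_cross_system_candidates([r1, r2, r3], min_systems=2)
    assert sets.genes("candidates") == ["A"]  # passes in systems 1 and 3
    # gene absent from a system counts as not passing there
    sets2 = select_cross_system_candidates([r1, r2], min_systems=2)
    assert "candidates" not in sets2 or "C" not in sets2.genes("candidates")


def test_knockdown_rule_uses_linear_fold_change():
    res = _de(["DOWN", "WEAK", "UPREG"], [-1.1, -0.9, 1.0], [0.2, 5.0, 5.0])
    sig = select_knockdown_signature(res)  # FC<0.5 means log2fc < -1
    assert sig.genes("knockdown_signature") == ["DOWN"]


def test_candidate_rule_recovers_planted_genes(default_simulation):
    params, systems, _, truth = default_simulation
    results = [moderated_de(s, "KRAS_mut", "KRAS_wt") for s in systems]
    sets = select_cross_system_candidates(results)
    selected = set(sets.genes("candidates"))
    recovered = len(selected & set(truth)) / len(truth)
    false_pos = len(selected - set(truth)) / (params.n_genes - params.n_planted)
    assert recovered >= 0.8
    assert false_pos <= 0.01
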