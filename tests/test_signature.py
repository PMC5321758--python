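import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krassig import (
    fit_status_classifier,
    geometric_mean_score,
    roc_auc,
    score_group_ttest,
    zsum_score,
)
from krassig.signature import ScoreTable, SignatureError
from tests.conftest import two_group_matrix


def _labels(n, positive_first=True):
    ids = [f"s{i}" for i in range(n)]
    half = n // 2
    return {s: ("pos" if (i < half) == positive_first else "neg") for i, s in enumerate(ids)}


def _score_table(values):
    return ScoreTable(
        scores={f"s{i}": float(v) for i, v in enumerate(values)},
        method="zsum",
        signature_name="sig",
        genes_used=["g"],
    )


# -- geometric mean ---------------------------------------------------------


def test_geometric_mean_constant_and_pairwise_cases():
    matrix = two_group_matrix(np.full((8, 4), 6.0))
    table = geometric_mean_score(matrix, list(matrix.gene_ids))
    assert all(v == pytest.approx(2.0**6.0) for v in table.scores.values())
    # two genes with linear values 2 and 8 -> geometric mean 4
    matrix2 = two_group_matrix(np.array([[1.0] * 4, [3.0] * 4]))  # log2(2), log2(8)
    table2 = geometric_mean_score(matrix2, ["g0", "g1"])
    assert all(v == pytest.approx(4.0) for v in table2.scores.values())


@given(c=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=25, deadline=None)
def test_geometric_mean_scales_as_c_to_one_over_k(c):
    """Multiplying one of k genes' linear values by c scales the score by c^(1/k)."""
    base = np.arange(12, dtype=float).reshape(3, 4) / 4 + 5
    matrix = two_group_matrix(base)
    scaled = base.copy()
    scaled[0] += np.log2(c)
    matrix_c = two_group_matrix(scaled)
    genes = ["g0", "g1", "g2"]
    s0 = geometric_mean_score(matrix, genes).scores
    s1 = geometric_mean_score(matrix_c, genes).scores
    for sid in s0:
        assert s1[sid] == pytest.approx(s0[sid] * c ** (1 / 3), rel=1e-9)


def test_geometric_mean_renormalizes_missing_genes_and_ignores_order():
    base = np.arange(8, dtype=float).reshape(2, 4) + 5
    matrix = two_group_matrix(base)
    with_missing = geometric_mean_score(matrix, ["g0", "g1", "ABSENT"], min_coverage=0.5)
    assert with_missing.genes_used == ["g0", "g1"]
    reordered = geometric_mean_score(matrix, ["g1", "g0"])
    assert with_missing.scores == pytest.approx(reordered.scores)
    with pytest.raises(SignatureError):
        geometric_mean_score(matrix, ["NOPE"])


# -- z-sum ------------------------------------------------------------------


def test_zsum_single_gene_equals_z_scores_and_sums_to_zero():
    rng = np.random.default_rng(1)
    values = rng.normal(8, 1, size=(4, 10))
    matrix = two_group_matrix(values)
    table = zsum_score(matrix, ["g2"])
    expected = (values[2] - values[2].mean()) / values[2].std(ddof=1)
    np.testing.assert_allclose(
        [table.scores[s] for s in matrix.sample_ids], expected, atol=1e-12
    )
    full = zsum_score(matrix, list(matrix.gene_ids))
    assert sum(full.scores.values()) == pytest.approx(0.0, abs=1e-9)


def test_zsum_and_geometric_mean_agree_monotonically(default_simulation):
    _, _, cohorts, truth = default_simulation
    cohort = cohorts[0]
    z = zsum_score(cohort, truth)
    g = geometric_mean_score(cohort, truth)
    from scipy.stats import spearmanr

    rho = spearmanr(
        [z.scores[s] for s in cohort.sample_ids],
        [g.scores[s] for s in cohort.sample_ids],
    ).statistic
    assert rho > 0.8


# -- group t-test -----------------------------------------------------------


def test_ttest_identical_groups_and_formula_oracle():
    table = _score_table([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    labels = _labels(6)
    t, p, means = score_group_ttest(table, labels)
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    # textbook pooled-variance instance
    a, b = np.array([5.1, 4.9, 5.3, 5.2]), np.array([4.2, 4.5, 4.1, 4.4])
    table2 = _score_table(np.concatenate([b, a]))  # labels sort: neg first group
    t2, p2, _ = score_group_ttest(table2, _labels(8, positive_first=False))
    sp = np.sqrt((a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6)
    t_expected = (a.mean() - b.mean()) / (sp * np.sqrt(0.5))
    from scipy import stats

    assert abs(t2) == pytest.approx(abs(t_expected), rel=1e-12)
    assert p2 == pytest.approx(2 * stats.t.sf(abs(t_expected), 6), rel=1e-12)


def test_planted_cohort_scores_separate_groups(default_simulation):
    _, _, cohorts, truth = default_simulation
    cohort = cohorts[0]
    scores = zsum_score(cohort, truth)
    _, p, means = score_group_ttest(scores, cohort.phenotype)
    assert p < 0.01
    assert means["KRAS_mut"] > means["KRAS_wt"]


# -- logistic classifier ----------------------------------------------------


def test_classifier_null_slope_is_rarely_significant():
    rng = np.random.default_rng(0)
    hits = 0
    for rep in range(100):
        x = rng.normal(size=200)
        labels = {f"s{i}": ("pos" if rng.random() < 0.5 else "neg") for i in range(200)}
        fit = fit_status_classifier(_score_table(x), labels)
        if not np.isnan(fit.wald_p) and fit.wald_p <= 0.05:
            hits += 1
    assert hits <= 10  # Wald p > 0.05 in >= 90% of null replicates


def test_classifier_flags_complete_separation():
    x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
    fit = fit_status_classifier(_score_table(x), _labels(6, positive_first=False))
    assert fit.separated


def test_classifier_symmetry_under_label_flip():
    x = np.array([-1.0, -0.5, 0.6, -0.6, 0.5, 1.0])  # overlapping: no separation
    labels = _labels(6, positive_first=False)
    fit_pos = fit_status_classifier(_score_table(x), labels, positive_label="pos")
    fit_neg = fit_status_classifier(_score_table(x), labels, positive_label="neg")
    assert fit_pos.slope == pytest.approx(-fit_neg.slope, rel=1e-6)


def test_classifier_slope_positive_when_auc_above_half(default_simulation):
    _, _, cohorts, truth = default_simulation
    cohort = cohorts[1]
    scores = zsum_score(cohort, truth)
    auc, _ = roc_auc(scores, cohort.phenotype, positive_label="KRAS_mut")
    fit = fit_status_classifier(scores, cohort.phenotype, positive_label="KRAS_mut")
    assert auc > 0.5
    assert fit.separated or fit.slope > 0


# -- ROC / AUC --------------------------------------------------------------


def test_auc_perfect_ties_and_pair_counting_oracle():
    x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    labels = _labels(6, positive_first=False)
    auc, _ = roc_auc(_score_table(x), labels, positive_label="pos")
    assert auc == 1.0
    auc_tied, _ = roc_auc(_score_table(np.zeros(6)), labels)
    assert auc_tied == 0.5
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    y = rng.random(30) < 0.5
    labels = {f"s{i}": ("pos" if y[i] else "neg") for i in range(30)}
    auc, _ = roc_auc(_score_table(x), labels, positive_label="pos")
    pos, neg = x[y], x[~y]
    concordant = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert auc == pytest.approx(concordant / (len(pos) * len(neg)), abs=1e-12)


def test_auc_complement_identity():
    rng = np.random.default_rng(11)
    x = rng.normal(size=25)
    labels = {f"s{i}": ("pos" if rng.random() < 0.4 else "neg") for i in range(25)}
    auc_fwd, _ = roc_auc(_score_table(x), labels, positive_label="pos")
    auc_rev, _ = roc_auc(_score_table(-x), labels, positive_label="pos")
    assert auc_fwd + auc_rev == pytest.approx(1.0, abs=1e-12)
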