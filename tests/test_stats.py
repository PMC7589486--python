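"""Cohort statistics: rank tests, correlation, logistic fits, ROC/Youden, power."""

import itertools

import numpy as np
import pandas as pd
import pytest

from uwfchoroid.stats import (chi_square, logistic_fit, mann_whitney, pearson_corr,
                              roc_with_cutoff, sample_size_normal_approx,
                              sample_size_two_group, two_sample_t_power, youden)


# -------------------------------------------------------------- Mann-Whitney

def test_mann_whitney_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    _, p = mann_whitney(a, a)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_mann_whitney_u_complete_separation():
    u, _ = mann_whitney([1, 2], [3, 4])
    assert u == 0.0


def test_mann_whitney_p_vs_permutation_oracle(rng):
    """Exact p agrees with the full permutation distribution of U at n = 5+5."""
    a = rng.normal(0, 1, 5)
    b = rng.normal(1, 1, 5)
    u_obs, p = mann_whitney(a, b)

    pooled = np.concatenate([a, b])
    count = 0
    total = 0
    for idx in itertools.combinations(range(10), 5):
        pa = pooled[list(idx)]
        pb = pooled[[i for i in range(10) if i not in idx]]
        u = sum((x > y) + 0.5 * (x == y) for x in pa for y in pb)
        # two-sided: as extreme in either direction
        if min(u, 25 - u) <= min(u_obs, 25 - u_obs):
            count += 1
        total += 1
    assert p == pytest.approx(count / total, abs=1e-12)


def test_mann_whitney_empty_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# -------------------------------------------------------------- chi-square

def test_chi_square_identical_proportions():
    stat, p = chi_square([[10, 10], [10, 10]])
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_chi_square_direct_formula(rng):
    table = rng.integers(5, 40, size=(2, 2)).astype(float)
    stat, _ = chi_square(table)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())


def test_chi_square_zero_expected_errors():
    with pytest.raises(ValueError):
        chi_square([[0, 0], [5, 5]])


# -------------------------------------------------------------- Pearson

def test_pearson_perfect_correlation():
    x = np.arange(10.0)
    assert pearson_corr(x, x)[0] == pytest.approx(1.0)
    assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_corr(x, np.zeros(10))


def test_pearson_simulation_recovery():
    """Mean sample R over repeated bivariate-normal draws with true rho = 0.45
    lands within 0.05 of the truth (the magnitude of the reported
    density-thickness correlations)."""
    rho, n = 0.45, 60
    rng = np.random.default_rng(123)
    rs = []
    for _ in range(500):
        z = rng.standard_normal((n, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        rs.append(pearson_corr(x, y)[0])
    assert np.mean(rs) == pytest.approx(rho, abs=0.05)


# -------------------------------------------------------------- logistic

def test_logistic_single_binary_predictor_equals_cross_product_ratio():
    # 2x2 layout: y=1 for 30/100 at x=0 and 70/100 at x=1 -> OR = 70*70/(30*30)
    x = np.repeat([0.0, 1.0], 100)
    y = np.concatenate([np.r_[np.ones(30), np.zeros(70)],
                        np.r_[np.ones(70), np.zeros(30)]])
    fit = logistic_fit(y, pd.DataFrame({"x": x}))
    assert fit.loc["x", "odds_ratio"] == pytest.approx(70 * 70 / (30 * 30), rel=1e-4)


def test_logistic_rescaling_invariance(rng):
    x = rng.normal(0, 1, 150)
    y = (x + rng.normal(0, 1, 150) > 0).astype(float)
    f1 = logistic_fit(y, pd.DataFrame({"x": x}))
    f2 = logistic_fit(y, pd.DataFrame({"x": 2 * x}))
    assert f2.loc["x", "coef"] == pytest.approx(f1.loc["x", "coef"] / 2, rel=1e-4)
    assert f2.loc["x", "p"] == pytest.approx(f1.loc["x", "p"], rel=1e-3)


def test_logistic_null_predictor_rarely_significant():
    """Permuted labels: OR near 1 and p > 0.05 in at least 90 of 100 seeds."""
    n_sig = 0
    ors = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 200)
        y = rng.integers(0, 2, 200).astype(float)
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        ors.append(fit.loc["x", "odds_ratio"])
        n_sig += fit.loc["x", "p"] < 0.05
    assert n_sig <= 10
    assert np.mean(ors) == pytest.approx(1.0, abs=0.1)


def test_logistic_separation_errors():
    x = np.concatenate([np.zeros(20), np.ones(20)])
    y = x.copy()
    with pytest.raises(ValueError):
        logistic_fit(y, pd.DataFrame({"x": x}))


# -------------------------------------------------------------- ROC / Youden

def test_youden_values():
    assert youden(0.8636, 0.8000) == pytest.approx(0.6636)
    assert youden(1.0, 1.0) == 1.0
    assert youden(0.3, 0.7) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        youden(1.2, 0.5)


def test_roc_perfect_and_chance():
    scores = np.concatenate([np.zeros(10), np.ones(10)])
    labels = scores > 0.5
    res = roc_with_cutoff(scores, labels)
    assert res.auc == pytest.approx(1.0)
    assert res.optimal_j == pytest.approx(1.0)

    rng = np.random.default_rng(5)
    s = rng.normal(size=4000)
    y = rng.random(4000) < 0.5
    assert roc_with_cutoff(s, y).auc == pytest.approx(0.5, abs=0.05)


def test_roc_exhaustive_threshold_oracle(rng):
    """sens/spec/J at every cutoff, and the chosen optimum, match a plain
    double-loop enumeration on an 8-point toy set (with ties)."""
    scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0])
    labels = np.array([0, 0, 1, 0, 1, 1, 0, 1], bool)
    res = roc_with_cutoff(scores, labels)
    best_j, best_cut = -2.0, None
    for t in np.unique(scores):
        sens = np.mean(scores[labels] >= t)
        spec = np.mean(scores[~labels] < t)
        i = np.searchsorted(res.thresholds, t)
        assert res.sens[i] == pytest.approx(sens)
        assert res.spec[i] == pytest.approx(spec)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_cut = j, t
    assert res.optimal_j == pytest.approx(best_j)
    assert res.optimal_cutoff == best_cut


def test_roc_tie_break_lowest_cutoff():
    # two cutoffs share the max J; the lower one is reported
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 0, 1, 1], bool)
    res = roc_with_cutoff(scores, labels)
    assert res.optimal_cutoff == res.optimal_cutoffs.min()


def test_auc_equals_u_statistic(rng):
    """Trapezoid AUC equals Mann-Whitney U/(n1 n2), including under ties."""
    scores = np.round(rng.normal(0, 1, 60), 1)  # rounding forces ties
    labels = rng.random(60) < 0.4
    res = roc_with_cutoff(scores, labels)
    u, _ = mann_whitney(scores[labels], scores[~labels])
    assert res.auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_with_cutoff(np.arange(5.0), np.ones(5, bool))


# -------------------------------------------------------------- sample size

def test_sample_size_noncentral_t():
    assert sample_size_two_group(0.8, 0.05, 0.80) == 26


def test_sample_size_normal_approximation_undershoots():
    """The z-based closed form gives 25; the extra subject comes from the
    heavier noncentral-t tails at df = 2n - 2."""
    assert sample_size_normal_approx(0.8, 0.05, 0.80) == 25


def test_power_monotonicity_grid():
    for d1, d2 in [(0.5, 0.8), (0.8, 1.2)]:
        assert sample_size_two_group(d1) >= sample_size_two_group(d2)
    for p1, p2 in [(0.7, 0.8), (0.8, 0.9)]:
        assert sample_size_two_group(0.8, power=p1) <= sample_size_two_group(0.8, power=p2)
    # returned n is minimal
    n = sample_size_two_group(0.8, 0.05, 0.80)
    assert two_sample_t_power(n, 0.8) >= 0.80
    assert two_sample_t_power(n - 1, 0.8) < 0.80


def test_sample_size_validation():
    with pytest.raises(ValueError):
        sample_size_two_group(-0.1)
    with pytest.raises(ValueError):
        sample_size_two_group(0.8, alpha=1.5)


def test_roc_auc_against_sklearn(rng):
    """Independent cross-check: trapezoid AUC equals scikit-learn's."""
    from sklearn.metrics import roc_auc_score
    scores = np.round(rng.normal(27, 2, 80), 1)
    labels = rng.random(80) < 0.35
    res = roc_with_cutoff(scores, labels)
    assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
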