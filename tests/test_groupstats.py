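"""Kruskal-Wallis / epsilon-squared, Dunn post hoc, Pearson, normality."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import exerscreen as ex
from exerscreen.groupstats import DegenerateDataError


def kw_h_oracle(groups):
    """Direct rank-sum formula 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1),
    without tie correction (oracle for tie-free data)."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    return 12.0 / (N * (N + 1)) * h - 3 * (N + 1)


def test_worked_three_group_example():
    res = ex.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
    assert res.H == pytest.approx(7.2)
    assert res.df == 2
    assert res.epsilon_sq == pytest.approx(0.9)
    assert res.H == pytest.approx(kw_h_oracle([[1, 2, 3], [4, 5, 6], [7, 8, 9]]))


def test_identical_observations_give_null_result():
    res = ex.kruskal_wallis({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
    assert res.H == 0.0 and res.p == 1.0 and res.epsilon_sq == 0.0


def test_empty_group_rejected():
    with pytest.raises(DegenerateDataError):
        ex.kruskal_wallis({"a": [1, 2], "b": []})
    with pytest.raises(DegenerateDataError):
        ex.kruskal_wallis({"a": [1, 2]})


def test_h_matches_rank_formula_on_random_tie_free_data(rng):
    for _ in range(50):
        sizes = rng.integers(3, 12, size=3)
        groups = [rng.permutation(100)[:n].astype(float) + rng.random() for n in sizes]
        # distinct values within each draw -> no ties across the pool
        pooled = np.concatenate(groups)
        if len(np.unique(pooled)) < len(pooled):
            continue
        res = ex.kruskal_wallis({f"g{i}": g for i, g in enumerate(groups)})
        assert res.H == pytest.approx(kw_h_oracle(groups), abs=1e-9)


def test_two_group_h_equals_squared_mann_whitney_z(rng):
    """Tie-corrected two-group H equals the square of the tie-corrected
    Mann-Whitney normal statistic."""
    for _ in range(20):
        x = rng.integers(0, 6, rng.integers(4, 9)).astype(float)
        y = rng.integers(0, 6, rng.integers(4, 9)).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            continue
        res = ex.kruskal_wallis({"x": x, "y": y})
        n1, n2 = len(x), len(y)
        N = n1 + n2
        ranks = stats.rankdata(np.concatenate([x, y]))
        U = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        _, cnt = np.unique(np.concatenate([x, y]), return_counts=True)
        ties = np.sum(cnt**3 - cnt)
        var_u = n1 * n2 / 12 * ((N + 1) - ties / (N * (N - 1)))
        z = (U - n1 * n2 / 2) / np.sqrt(var_u)
        assert res.H == pytest.approx(z * z, abs=1e-9)


def test_two_group_permutation_oracle(rng):
    """Exhaustive-permutation p of H orders identically to the exact
    Mann-Whitney permutation p on small samples."""
    for _ in range(5):
        x = rng.integers(0, 8, 4).astype(float)
        y = rng.integers(0, 8, 4).astype(float)
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            continue
        h_obs = ex.kruskal_wallis({"x": x, "y": y}).H
        u_obs = abs(stats.rankdata(pooled)[:4].sum() - 4 * 5 / 2 - 8.0)
        h_ge = u_ge = total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            ranks = stats.rankdata(pooled)
            h = ex.kruskal_wallis({"x": pooled[mask], "y": pooled[~mask]}).H
            u = abs(ranks[mask].sum() - 4 * 5 / 2 - 8.0)
            h_ge += h >= h_obs - 1e-9
            u_ge += u >= u_obs - 1e-9
            total += 1
        assert h_ge / total == pytest.approx(u_ge / total)


def test_epsilon_squared_reaches_one_for_perfect_separation():
    n = 9
    res = ex.kruskal_wallis({"a": range(n), "b": range(n, 2 * n), "c": range(2 * n, 3 * n)})
    assert res.epsilon_sq == pytest.approx(res.H / (3 * n - 1))
    assert 0.0 <= res.epsilon_sq <= 1.0


# ---------------------------------------------------------------- post hoc

def test_dunn_extreme_pair_significant_at_n5():
    groups = {"a": [1, 2, 3, 4, 5], "b": [6, 7, 8, 9, 10], "c": [11, 12, 13, 14, 15]}
    p = ex.pairwise_posthoc(groups)
    assert p[("a", "c")] < 0.05
    # adjacent separated groups at n=5: z = 5/sqrt(8), adjusted p ~ 0.23
    assert p[("a", "b")] == pytest.approx(
        min(1.0, 3 * 2 * stats.norm.sf(5 / np.sqrt(8))), abs=1e-9
    )


def test_dunn_all_pairs_significant_at_n9():
    n = 9
    groups = {"a": range(n), "b": range(n, 2 * n), "c": range(2 * n, 3 * n)}
    p = ex.pairwise_posthoc(groups)
    assert all(v < 0.05 for v in p.values())


def test_dunn_identical_groups_give_p_one():
    p = ex.pairwise_posthoc({"a": [1.0] * 5, "b": [1.0] * 5, "c": [1.0] * 5})
    assert all(v == 1.0 for v in p.values())


def test_bonferroni_multiplies_and_caps(rng):
    groups = {g: rng.normal(size=10) for g in ("a", "b", "c")}
    adjusted = ex.pairwise_posthoc(groups)
    # recompute raw Dunn p and compare: adjusted = min(1, 3 * raw)
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    base_var = len(pooled) * (len(pooled) + 1) / 12
    mean_ranks = {g: ranks[i * 10:(i + 1) * 10].mean() for i, g in enumerate(groups)}
    for (a, b), padj in adjusted.items():
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(base_var * 0.2)
        raw = 2 * stats.norm.sf(abs(z))
        assert padj == pytest.approx(min(1.0, 3 * raw))
        assert padj >= raw


# ---------------------------------------------------------------- Pearson

def test_pearson_perfect_lines():
    x = np.arange(10.0)
    assert ex.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
    assert ex.pearson_corr(x, -x).r == pytest.approx(-1.0)


def test_pearson_worked_example():
    res = ex.pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.r == pytest.approx(0.6)
    assert res.n == 4


def test_pearson_degenerate_inputs():
    with pytest.raises(DegenerateDataError):
        ex.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateDataError):
        ex.pearson_corr([1.0, 2.0], [1.0, 2.0])


def test_pearson_affine_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r0 = ex.pearson_corr(x, y).r
    assert ex.pearson_corr(3 * x + 7, y).r == pytest.approx(r0)
    assert ex.pearson_corr(x, 0.5 * y - 2).r == pytest.approx(r0)


# ---------------------------------------------------------------- normality

def test_shapiro_keeps_normal_draws(rng):
    keep = sum(
        ex.normality_check(rng.normal(size=500), "shapiro_wilk")[1] > 0.05
        for _ in range(60)
    )
    assert keep >= 0.9 * 60


def test_lilliefors_rejects_exponential_draws(rng):
    reject = sum(
        ex.normality_check(rng.exponential(size=500), "kolmogorov_smirnov")[1] < 0.05
        for _ in range(60)
    )
    assert reject >= 0.9 * 60


def test_normality_degenerate_input():
    with pytest.raises(DegenerateDataError):
        ex.normality_check([3.0, 3.0, 3.0])
    with pytest.raises(DegenerateDataError):
        ex.normality_check([1.0, 2.0])


# ---------------------------------------------------------------- pipeline

def test_feature_screen_shape_and_ordering(study):
    kw = ex.screen_features(study.features)
    assert (kw.p.diff().dropna() >= 0).all()
    assert kw.epsilon_sq.between(0, 1).all()
    assert {"p_CN_MCI", "p_CN_MD", "p_MCI_MD"} <= set(kw.columns)
    # HRMG separates groups strongly under the default calibration
    top10 = set(kw.head(10).feature)
    assert any(f.startswith("HRMG Mean") for f in top10)


def test_hrmg_neuropsych_correlation_signs(study):
    corr = ex.neuropsych_correlations(study.features, study.participants)
    r = dict(zip(corr.y, corr.r))
    assert r["mmse"] > 0 and r["moca"] > 0
    assert r["tmt_a_s"] < 0 and r["tmt_b_s"] < 0
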