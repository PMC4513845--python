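import numpy as np
import pytest

from comod import ExpressionMatrix
from comod.expression import EPS, condition_scores, row_expression_scores
from comod.membership import MembershipState


def _state(expr, gene_members, cond_members):
    G = np.asarray(gene_members, dtype=bool)
    C = np.asarray(cond_members, dtype=bool)
    return MembershipState(expr.gene_ids, expr.condition_ids, G, C)


def _brute_force_R(expr, state):
    """Direct evaluation of log(mean squared deviation from cluster mean)."""
    X = expr.values
    k = state.k
    out = np.full((X.shape[0], k), np.nan)
    for j in range(k):
        genes = np.flatnonzero(state.gene_membership[:, j])
        conds = np.flatnonzero(state.cond_membership[:, j])
        if len(genes) < 2 or len(conds) < 2:
            continue
        for i in range(X.shape[0]):
            devs = []
            for c in conds:
                vals = [X[g, c] for g in genes if np.isfinite(X[g, c])]
                if not vals or not np.isfinite(X[i, c]):
                    continue
                devs.append((X[i, c] - np.mean(vals)) ** 2)
            if devs:
                out[i, j] = np.log(np.mean(devs) + EPS)
    return out


def test_gene_identical_to_cluster_mean_scores_minimum():
    # two identical member genes: a third identical gene deviates by zero
    X = np.array([[1.0, 2.0, 3.0],
                  [1.0, 2.0, 3.0],
                  [1.0, 2.0, 3.0],
                  [5.0, -1.0, 0.0]])
    expr = ExpressionMatrix(list("abcd"), ["c1", "c2", "c3"], X)
    state = _state(expr, [[1], [1], [0], [0]], [[1], [1], [1]])
    R = row_expression_scores(expr, state)
    assert R.values[2, 0] == pytest.approx(np.log(EPS))
    assert R.values[3, 0] > R.values[2, 0]


def test_matching_profile_beats_deviating_profile():
    rng = np.random.default_rng(0)
    profile1 = rng.normal(size=6)
    profile2 = profile1 + 5.0
    X = np.vstack([profile1, profile1, profile2, profile2,
                   profile1 + rng.normal(0, 0.01, 6)])
    expr = ExpressionMatrix(list("abcde"), [f"c{i}" for i in range(6)], X)
    state = _state(expr,
                   [[1, 0], [1, 0], [0, 1], [0, 1], [0, 0]],
                   [[1, 1]] * 6)
    R = row_expression_scores(expr, state)
    assert R.values[4, 0] < R.values[4, 1]


def test_row_scores_match_brute_force_oracle(tiny_expr):
    state = _state(tiny_expr,
                   [[1, 0], [1, 1], [0, 1], [1, 0]],
                   [[1, 1], [1, 0], [0, 1]])
    R = row_expression_scores(tiny_expr, state)
    expected = _brute_force_R(tiny_expr, state)
    np.testing.assert_allclose(R.values, expected, rtol=1e-9, equal_nan=True)


def test_shift_invariance(tiny_expr):
    state = _state(tiny_expr,
                   [[1, 0], [1, 1], [0, 1], [1, 0]],
                   [[1, 1], [1, 0], [0, 1]])
    R1 = row_expression_scores(tiny_expr, state).values
    shifted = ExpressionMatrix(tiny_expr.gene_ids, tiny_expr.condition_ids,
                               tiny_expr.values + 7.5)
    R2 = row_expression_scores(shifted, state).values
    np.testing.assert_allclose(R1, R2, rtol=1e-7, equal_nan=True)


def test_scores_improve_as_cluster_noise_shrinks():
    rng = np.random.default_rng(1)
    profile = rng.normal(size=8)
    conds = [f"c{i}" for i in range(8)]
    prev = None
    for sd in (1.0, 0.3, 0.05):
        X = profile[None, :] + rng.normal(0, sd, size=(6, 8))
        expr = ExpressionMatrix([f"g{i}" for i in range(6)], conds, X)
        state = _state(expr, [[1]] * 6, [[1]] * 8)
        mean_R = row_expression_scores(expr, state).values.mean()
        if prev is not None:
            assert mean_R < prev
        prev = mean_R


def test_small_cluster_column_unscorable():
    X = np.arange(12, dtype=float).reshape(4, 3)
    expr = ExpressionMatrix(list("abcd"), ["c1", "c2", "c3"], X)
    # cluster 0 has a single condition -> unscorable column
    state = _state(expr, [[1, 1], [1, 1], [0, 0], [0, 0]],
                   [[1, 1], [0, 1], [0, 1]])
    R = row_expression_scores(expr, state)
    assert np.isnan(R.values[:, 0]).all()
    assert np.isfinite(R.values[:, 1]).all()


class TestConditionScores:
    def test_constant_condition_scores_lowest(self):
        X = np.array([[1.0, 5.0], [1.0, -5.0], [1.0, 0.0], [9.0, 2.0]])
        expr = ExpressionMatrix(list("abcd"), ["c1", "c2"], X)
        state = _state(expr, [[1], [1], [1], [0]], [[1], [1]])
        S = condition_scores(expr, state)
        assert S.values[0, 0] < S.values[1, 0]

    def test_matches_variance_ratio_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        expr = ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"c{j}" for j in range(4)], X)
        members = [[1], [1], [1], [0], [0]]
        state = _state(expr, members, [[1]] * 4)
        S = condition_scores(expr, state)
        sub = X[:3]
        pooled = sub.var()
        for c in range(4):
            expected = np.log((sub[:, c].var() + EPS) / (pooled + EPS))
            assert S.values[c, 0] == pytest.approx(expected, rel=1e-9)

    def test_outlier_gene_worsens_tight_conditions(self):
        from comod.expression import EPS
        rng = np.random.default_rng(3)
        profile = rng.normal(size=5)
        X = np.vstack([profile + rng.normal(0, 0.01, 5) for _ in range(4)])
        X = np.vstack([X, profile + 10.0])   # far-off outlier gene
        expr = ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"c{j}" for j in range(5)], X)
        tight = _state(expr, [[1], [1], [1], [1], [0]], [[1]] * 5)
        loose = _state(expr, [[1], [1], [1], [1], [1]], [[1]] * 5)
        s_tight = condition_scores(expr, tight).values
        s_loose = condition_scores(expr, loose).values
        # recover absolute per-condition variances from the normalized score
        var_tight = np.exp(s_tight[:, 0]) * (X[:4].var() + EPS) - EPS
        var_loose = np.exp(s_loose[:, 0]) * (X[:5].var() + EPS) - EPS
        assert (var_loose > var_tight).all()
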