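import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from comod import ExpressionMatrix
from comod.evaluate import (build_combinatorial_regulons, gpr_from_counts,
                            make_pc1_null_table, mean_squared_residue,
                            overlap_pvalues, pc1_variance_filter,
                            pc1_variance_fraction, regulon_recovery,
                            set_recovery_counts)
from comod.io import GeneSetCollection


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])], values)


class TestMSR:
    def test_constant_submatrix_zero(self):
        expr = _expr(np.full((4, 3), 2.5))
        assert mean_squared_residue(expr, expr.gene_ids, expr.condition_ids) \
            == pytest.approx(0.0, abs=1e-12)

    def test_additive_submatrix_zero(self):
        r = np.array([1.0, -2.0, 0.5, 3.0])
        c = np.array([0.0, 4.0, -1.0])
        expr = _expr(r[:, None] + c[None, :])
        assert mean_squared_residue(expr, expr.gene_ids, expr.condition_ids) \
            == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(size=(4, 3)))
        A = expr.values
        aI = A.mean(axis=1)
        aJ = A.mean(axis=0)
        aIJ = A.mean()
        acc = 0.0
        for i in range(4):
            for j in range(3):
                acc += (A[i, j] - aI[i] - aJ[j] + aIJ) ** 2
        expected = acc / 12
        assert mean_squared_residue(expr, expr.gene_ids, expr.condition_ids) \
            == pytest.approx(expected, rel=1e-12)

    def test_missing_cells_excluded_with_weights(self):
        A = np.array([[1.0, 2.0, np.nan], [2.0, 3.0, 4.0], [0.0, 1.0, 2.0]])
        expr = _expr(A)
        msr = mean_squared_residue(expr, expr.gene_ids, expr.condition_ids)
        assert msr is not None and np.isfinite(msr)
        # purely additive apart from the missing cell -> tiny residue
        assert msr < 0.2

    def test_degenerate_roster_reported_missing(self):
        expr = _expr(np.ones((3, 3)))
        assert mean_squared_residue(expr, ["g0"], expr.condition_ids) is None
        assert mean_squared_residue(expr, expr.gene_ids, ["c0"]) is None


class TestCombinatorialRegulons:
    def test_identical_targets_one_regulon(self):
        out = build_combinatorial_regulons({"A": {"g1", "g2"},
                                            "B": {"g1", "g2"}})
        assert out == {"A+B": {"g1", "g2"}}

    def test_signature_enumeration(self):
        out = build_combinatorial_regulons({"A": {"g1", "g2", "g3"},
                                            "B": {"g2", "g3", "g4"}})
        assert out == {"A": {"g1"}, "A+B": {"g2", "g3"}, "B": {"g4"}}

    def test_unregulated_genes_excluded(self):
        out = build_combinatorial_regulons({"A": {"g1"}})
        assert "g2" not in set().union(*out.values())


class TestRegulonRecovery:
    def test_perfect_clustering(self):
        universe = {f"g{i}" for i in range(40)}
        regulons = {"A": {f"g{i}" for i in range(6)},
                    "B": {f"g{i}" for i in range(20, 26)}}
        clusters = [set(regulons["A"]), set(regulons["B"])]
        rep = regulon_recovery(clusters, regulons, universe)
        assert rep.precision == rep.recall == rep.g_measure == rep.f1 == 1.0

    def test_two_gene_overlap_never_matches(self):
        # overlap of exactly 2 genes is excluded regardless of significance
        universe = {f"g{i}" for i in range(12)}
        regulons = {"A": {"g0", "g1"}}
        clusters = [{"g0", "g1"}]
        rep = regulon_recovery(clusters, regulons, universe)
        assert rep.n_matched_clusters == 0
        assert rep.precision == 0.0

    def test_eqn_arithmetic_from_counts(self):
        P, R, G, F1 = gpr_from_counts(tp=8, fp=2, fn=8)
        assert P == pytest.approx(0.8)
        assert R == pytest.approx(0.5)
        assert G == pytest.approx(np.sqrt(0.40))
        assert F1 == pytest.approx(2 * 0.8 * 0.5 / 1.3)

    def test_g_at_least_f1(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 20, size=3)
            P, R, G, F1 = gpr_from_counts(int(tp), int(fp), int(fn))
            assert 0.0 <= G <= 1.0 and 0.0 <= F1 <= 1.0
            if P + R > 0:
                assert G >= F1 - 1e-12

    def test_label_permutation_invariance(self):
        universe = {f"g{i}" for i in range(30)}
        regulons = {"A": {f"g{i}" for i in range(5)},
                    "B": {f"g{i}" for i in range(10, 16)}}
        clusters = [{f"g{i}" for i in range(5)},
                    {f"g{i}" for i in range(10, 14)},
                    {f"g{i}" for i in range(20, 25)}]
        r1 = regulon_recovery(clusters, regulons, universe)
        r2 = regulon_recovery(clusters[::-1], regulons, universe)
        assert (r1.precision, r1.recall) == (r2.precision, r2.recall)


class TestBH:
    def test_bh_matches_sorted_p_oracle(self):
        # brute-force BH on <= 20 hypotheses: largest i with p_(i) <= i/m * q
        rng = np.random.default_rng(2)
        pvals = np.concatenate([rng.uniform(0, 0.002, 4),
                                rng.uniform(0.2, 1, 12)])
        q = 0.05
        m = len(pvals)
        order = np.argsort(pvals)
        srt = pvals[order]
        cutoff = 0
        for i in range(m, 0, -1):
            if srt[i - 1] <= i / m * q:
                cutoff = i
                break
        expected = np.zeros(m, dtype=bool)
        expected[order[:cutoff]] = True
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        np.testing.assert_array_equal(reject, expected)


class TestSetRecovery:
    def _sets(self, members):
        universe = [f"g{i}" for i in range(40)]
        return GeneSetCollection({k: set(v) for k, v in members.items()},
                                 universe)

    def test_disjoint_all_zero(self):
        sets = self._sets({"s1": [f"g{i}" for i in range(5)]})
        clusters = [{f"g{i}" for i in range(20, 28)}]
        assert set_recovery_counts(clusters, sets) == (0, 0, 0, 0)

    def test_identical_cluster_and_set(self):
        sets = self._sets({"s1": [f"g{i}" for i in range(8)]})
        clusters = [{f"g{i}" for i in range(8)}]
        assert set_recovery_counts(clusters, sets) == (1, 1, 1, 1)

    def test_toy_instance_matches_fisher_bh_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        sets = self._sets({
            "s1": universe[:8], "s2": universe[8:16], "s3": universe[30:36]})
        clusters = [set(universe[:7]) | {universe[20]},
                    set(universe[8:14]),
                    set(rng.choice(universe, 6, replace=False)),
                    set(universe[30:34]),
                    set(universe[16:22])]
        got = set_recovery_counts(clusters, sets, alpha=0.01)
        P = np.ones((5, 3))
        ref = [set(universe[:8]), set(universe[8:16]), set(universe[30:36])]
        for i, cl in enumerate(clusters):
            for j, s in enumerate(ref):
                a = len(cl & s)
                if a:
                    P[i, j] = hypergeom.sf(a - 1, 40, len(s), len(cl))
        reject, _, _, _ = multipletests(P.ravel(), alpha=0.01, method="fdr_bh")
        sig = reject.reshape(5, 3)
        expected = (int(sig.any(axis=1).sum()), int(sig.any(axis=0).sum()),
                    int((sig.sum(axis=1) == 1).sum()),
                    int((sig.sum(axis=0) == 1).sum()))
        assert got == expected


class TestPC1Filter:
    def test_rank_one_submatrix_passes(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=10)
        X = np.vstack([a * base for a in (1.0, 2.0, -1.5, 0.5, 3.0)])
        X = np.vstack([X, rng.normal(size=(45, 10))])
        expr = _expr(X)
        assert pc1_variance_fraction(X[:5]) > 0.99
        assert pc1_variance_filter(expr, expr.gene_ids[:5],
                                   np.random.default_rng(0), n_random=200)

    def test_random_roster_fails(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(size=(60, 12)))
        picks = [f"g{i}" for i in rng.choice(60, 8, replace=False)]
        fails = sum(
            not pc1_variance_filter(expr, picks, np.random.default_rng(s),
                                    n_random=200)
            for s in range(3))
        assert fails >= 2

    def test_pc1_fraction_matches_eigendecomposition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 6))
        Xc = X - X.mean(axis=0, keepdims=True)
        eigvals = np.linalg.eigvalsh(Xc.T @ Xc)
        expected = eigvals.max() / eigvals.sum()
        assert pc1_variance_fraction(X) == pytest.approx(expected, rel=1e-9)

    def test_null_table_nearest_size_lookup(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.normal(size=(80, 10)))
        table = make_pc1_null_table(expr, rng, sizes=(5, 10), n_random=50)
        assert set(table) == {5, 10}
        # size-7 roster uses nearest table entry without error
        roster = expr.gene_ids[:7]
        out = pc1_variance_filter(expr, roster, rng, null_table=table)
        assert out in (True, False)
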