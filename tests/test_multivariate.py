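"""Dependence measures, FDR correlations, variable clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermflow.multivariate import (
    cluster_observations_on_pcs,
    cluster_variables,
    component_contribution,
    correlation_matrix,
    hoeffding_d,
    principal_components,
)


def brute_force_hoeffding(x, y):
    """Direct evaluation of the counting definition of Hoeffding's D
    (explicit loops; midranks and bivariate ranks counted pair by pair)."""
    n = len(x)

    def u(a, b):  # 1 if a > b, half credit on ties
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    r = [sum(u(x[i], x[j]) for j in range(n) if j != i) + 1.0 for i in range(n)]
    s = [sum(u(y[i], y[j]) for j in range(n) if j != i) + 1.0 for i in range(n)]
    q = [
        1.0 + sum(u(x[i], x[j]) * u(y[i], y[j]) for j in range(n) if j != i)
        for i in range(n)
    ]
    d1 = sum((qq - 1) * (qq - 2) for qq in q)
    d2 = sum((rr - 1) * (rr - 2) * (ss - 1) * (ss - 2) for rr, ss in zip(r, s))
    d3 = sum((rr - 2) * (ss - 2) * (qq - 1) for rr, ss, qq in zip(r, s, q))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


class TestHoeffdingD:
    def test_perfect_monotone_dependence(self):
        x = np.arange(1.0, 6.0)
        assert hoeffding_d(x, x) == pytest.approx(1.0)

    def test_direction_free(self):
        x = np.arange(1.0, 6.0)
        assert hoeffding_d(x, x[::-1]) == pytest.approx(1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hoeffding_d(np.arange(4.0), np.arange(4.0))

    def test_constant_input_undefined(self):
        assert np.isnan(hoeffding_d(np.ones(10), np.arange(10.0)))

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 9), st.integers(0, 9)),
            min_size=5, max_size=30,
        )
    )
    @settings(max_examples=200)
    def test_matches_brute_force_counting(self, data):
        """Vectorised implementation agrees with a literal loop evaluation
        of the counting formula, ties included."""
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert hoeffding_d(x, y) == pytest.approx(
            brute_force_hoeffding(x, y), abs=1e-12
        )

    def test_independence_mean_near_zero(self):
        rng = np.random.default_rng(42)
        base = np.arange(200.0)
        ds = [
            hoeffding_d(rng.permutation(base), rng.permutation(base))
            for _ in range(500)
        ]
        assert abs(np.mean(ds)) < 0.005


class TestCorrelationMatrix:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": rng.normal(size=30)})
        cm = correlation_matrix(df)
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.significant.loc["x", "y"]
        assert cm.r.loc["x", "x"] == 1.0
        assert np.isnan(cm.p_raw.loc["x", "x"])  # diagonal never tested

    def test_bh_adjustment_matches_hand_computation(self):
        """BH: adjusted = p * m / rank with downward monotonicity from the
        largest p; verified on a 10-p-value set fed through 5 variables."""
        raw = np.array(
            [0.001, 0.02, 0.04, 0.2, 0.5, 0.8, 0.003, 0.06, 0.3, 0.9]
        )
        m = len(raw)
        order = np.argsort(raw)
        hand = np.empty(m)
        prev = 1.0
        for rank_rev, idx in enumerate(order[::-1]):
            rank = m - rank_rev
            val = min(prev, raw[idx] * m / rank)
            hand[idx] = val
            prev = val
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        np.testing.assert_allclose(adj, hand, rtol=1e-12)

    def test_adjustment_never_gains_significance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        cm = correlation_matrix(df, alpha=0.05)
        tri = np.triu_indices(6, k=1)
        n_sig_adj = int(cm.significant.to_numpy()[tri].sum())
        n_sig_raw = int((cm.p_raw.to_numpy()[tri] <= 0.05).sum())
        assert n_sig_adj <= n_sig_raw
        assert np.all(
            cm.p_adjusted.to_numpy()[tri] >= cm.p_raw.to_numpy()[tri] - 1e-12
        )

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"a": np.arange(10.0), "c": np.ones(10)})
        cm = correlation_matrix(df)
        assert any("constant_variable:c" in f for f in cm.flags)
        assert np.isnan(cm.r.loc["a", "c"])


class TestVariableClustering:
    def test_duplicated_variables_merge_first(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        df = pd.DataFrame(
            {"a": x, "b": x.copy(), "c": rng.normal(size=40)}
        )
        tree = cluster_variables(df)
        first = tree.linkage_matrix[0]
        merged = {int(first[0]), int(first[1])}
        assert merged == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_leaf_count_equals_variable_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        tree = cluster_variables(df)
        assert tree.n_leaves == 5
        assert sorted(tree.order) == list("abcde")

    def test_independent_variables_merge_high(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        tree = cluster_variables(df)
        # independent variables: all merges near distance 1 (similarity ~ 0)
        assert np.all(tree.linkage_matrix[:, 2] > 0.9)
        assert np.ptp(tree.linkage_matrix[:, 2]) < 0.1

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            cluster_variables(pd.DataFrame({"a": np.arange(10.0)}))


class TestPCA:
    def make_table(self, n=60, p=5, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 2))
        cols = {}
        for j in range(p):
            w = rng.normal(size=2)
            cols[f"v{j}"] = base @ w + 0.5 * rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_standardized_identities(self):
        df = self.make_table()
        res = principal_components(df)
        p = df.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
        np.testing.assert_allclose(
            res.contributions.sum(axis=0), 100.0, atol=1e-8
        )
        np.testing.assert_allclose(
            (res.loadings**2).sum(axis=0), res.eigenvalues, atol=1e-8
        )

    def test_loadings_are_variable_component_correlations(self):
        df = self.make_table()
        res = principal_components(df)
        z = (df - df.mean()) / df.std(ddof=1)
        for j in range(2):
            for v in df.columns:
                r = np.corrcoef(z[v], res.scores.iloc[:, j])[0, 1]
                assert res.loadings.loc[v, f"PC{j + 1}"] == pytest.approx(
                    r, abs=1e-8
                )

    def test_sign_convention(self):
        df = self.make_table(seed=5)
        res = principal_components(df)
        for j in range(df.shape[1]):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] >= 0

    def test_contribution_formula(self):
        assert component_contribution(0.5, 2.0) == pytest.approx(12.5)
        with pytest.raises(ValueError):
            component_contribution(0.5, 0.0)

    def test_independent_variables_give_unit_eigenvalues(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.normal(size=(10000, 6)), columns=list("abcdef")
        )
        res = principal_components(df)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.1)

    def test_underdetermined_input_rejected(self):
        df = self.make_table(n=4, p=5)
        with pytest.raises(ValueError):
            principal_components(df)


class TestObservationClustering:
    def test_two_blobs_along_pc1(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(30, 4))
        b = rng.normal(8, 1, size=(30, 4))
        df = pd.DataFrame(np.vstack([a, b]), columns=list("wxyz"))
        res = principal_components(df)
        labels = cluster_observations_on_pcs(res, n_pcs=2, k=2)
        assert len(np.unique(labels[:30])) == 1
        assert len(np.unique(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equal_n_gives_singletons(self):
        df = self.blob_table()
        res = principal_components(df)
        labels = cluster_observations_on_pcs(res, n_pcs=2, k=len(df))
        assert len(np.unique(labels)) == len(df)

    def test_k_exceeding_n_rejected(self):
        df = self.blob_table()
        res = principal_components(df)
        with pytest.raises(ValueError):
            cluster_observations_on_pcs(res, k=len(df) + 1)

    def test_duplicate_observations_share_labels(self):
        df = self.blob_table()
        df2 = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        res = principal_components(df2)
        labels = cluster_observations_on_pcs(res, n_pcs=2, k=3)
        assert labels[0] == labels[len(df2) - 1]

    @staticmethod
    def blob_table():
        rng = np.random.default_rng(8)
        return pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
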