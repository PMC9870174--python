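"""Graph inference: kNN/CT/MB/glasso contracts and minimum-density scans."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cohortnet.graph_infer import (
    ct_graph,
    glasso_graph,
    knn_graph,
    mb_graph,
    min_k_connected,
    soft_threshold,
    sparsest_connected,
    subject_correlation,
    subset_positive,
)
from cohortnet.preprocess import FeatureMatrix
from cohortnet.synthetic import generate_gaussian_precision
from oracles import lasso_coordinate_descent


def _frame(points, ids=None) -> pd.DataFrame:
    points = np.atleast_2d(np.asarray(points, dtype=float)).T if np.ndim(points) == 1 else np.asarray(points, dtype=float)
    ids = ids or [f"S{i}" for i in range(len(points))]
    return pd.DataFrame(points, index=ids)


class TestSubsetPositive:
    def _matrix(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "t": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
                "a": rng.integers(0, 2, 10),
                "b": rng.integers(0, 2, 10),
            },
            index=[f"S{i}" for i in range(10)],
        )
        return FeatureMatrix(data=frame)

    def test_positive_rows_kept_target_column_removed(self):
        out = subset_positive(self._matrix(), "t")
        assert len(out.data) == 4
        assert "t" not in out.data.columns

    def test_all_positive_target_is_row_identity(self):
        m = self._matrix()
        m.data["u"] = 1
        out = subset_positive(m, "u")
        assert list(out.data.index) == list(m.data.index)

    def test_too_few_positives_rejected(self):
        m = self._matrix()
        m.data["rare"] = [1, 1] + [0] * 8
        with pytest.raises(ValueError, match="positive"):
            subset_positive(m, "rare")


class TestKnn:
    def test_one_dimensional_toy_nearest_neighbor_edges(self):
        g = knn_graph(_frame([0.0, 1.0, 10.0, 11.0]), k=1)
        assert set(map(frozenset, g.edges)) == {
            frozenset({"S0", "S1"}),
            frozenset({"S2", "S3"}),
        }
        assert not nx.is_connected(g)

    def test_k_equals_n_minus_one_is_complete(self):
        g = knn_graph(_frame([0.0, 1.0, 2.0, 5.0]), k=3)
        assert g.number_of_edges() == 6

    def test_structural_bounds_and_simplicity(self):
        rng = np.random.default_rng(0)
        frame = _frame(rng.random((30, 4)))
        for k in (1, 3, 7):
            g = knn_graph(frame, k)
            assert g.number_of_edges() <= 30 * k
            assert min(dict(g.degree()).values()) >= 1
            assert nx.number_of_selfloops(g) == 0

    def test_min_k_on_toy_is_two(self):
        g = min_k_connected(_frame([0.0, 1.0, 10.0, 11.0]))
        assert g.graph["parameter"] == 2
        assert nx.is_connected(g)
        assert not nx.is_connected(knn_graph(_frame([0.0, 1.0, 10.0, 11.0]), 1))

    def test_min_k_minimality_with_duplicate_rows(self):
        frame = _frame([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]])
        g = min_k_connected(frame)
        k = g.graph["parameter"]
        assert nx.is_connected(g)
        if k > 1:
            assert not nx.is_connected(knn_graph(frame, k - 1))

    def test_two_subjects_connect_at_k_one(self):
        g = min_k_connected(_frame([0.0, 5.0]))
        assert g.graph["parameter"] == 1
        assert g.number_of_edges() == 1


class TestSubjectCorrelation:
    def test_identical_subjects_fully_correlated(self):
        frame = _frame([[1, 0, 1, 0, 1], [1, 0, 1, 0, 1]])
        corr = subject_correlation(frame)
        assert corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_hand_computed_pair(self):
        u = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        v = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        expected = (
            ((u - u.mean()) * (v - v.mean())).sum()
            / np.sqrt(((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
        )
        corr = subject_correlation(_frame([u, v]))
        assert corr[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_subject_gets_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            corr = subject_correlation(_frame([[1, 1, 1], [1, 0, 1]]))
        assert corr[0, 1] == 0.0
        assert corr[0, 0] == 1.0


class TestCtGraph:
    CORR = np.array(
        [
            [1.0, 0.9, 0.2, 0.6],
            [0.9, 1.0, 0.1, 0.3],
            [0.2, 0.1, 1.0, 0.7],
            [0.6, 0.3, 0.7, 1.0],
        ]
    )

    def test_threshold_above_one_gives_empty_graph(self):
        assert ct_graph(self.CORR, 1.0).number_of_edges() == 0

    def test_threshold_below_min_gives_complete_graph(self):
        assert ct_graph(self.CORR, 0.05).number_of_edges() == 6

    def test_hand_enumerated_edges_at_half(self):
        g = ct_graph(self.CORR, 0.5)
        assert set(map(frozenset, g.edges)) == {
            frozenset({0, 1}),
            frozenset({0, 3}),
            frozenset({2, 3}),
        }

    def test_edge_count_non_increasing_in_threshold(self):
        counts = [
            ct_graph(self.CORR, t).number_of_edges()
            for t in np.linspace(0.0, 1.0, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,lam,expected", [(0.5, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.3, 0.1, 0.2)]
    )
    def test_kernel_values(self, z, lam, expected):
        assert soft_threshold(z, lam) == pytest.approx(expected)


class TestMbGraph:
    def test_penalty_above_max_marginal_correlation_gives_null_model(self):
        x, _ = generate_gaussian_precision(200, 5, "chain", seed=0)
        z = (x - x.mean(0)) / x.std(0)
        lam_max = np.abs((z.T @ z) / len(z) - np.eye(5)).max()
        g = mb_graph(x, lam_max + 1e-6)
        assert g.number_of_edges() == 0

    def test_chain_recovered_at_mid_path_penalty(self):
        x, truth = generate_gaussian_precision(500, 5, "chain", seed=1)
        recovered = False
        for lam in np.geomspace(0.5, 0.01, 15):
            g = mb_graph(x, lam)
            edges = frozenset(tuple(sorted(e)) for e in g.edges)
            if edges == truth:
                recovered = True
                break
        assert recovered

    def test_matches_naive_coordinate_descent_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 5))
        x = (x - x.mean(0)) / x.std(0)
        y = x @ np.array([1.0, -0.5, 0.0, 0.0, 0.2]) + 0.3 * rng.standard_normal(60)
        y = (y - y.mean()) / y.std()
        from sklearn.linear_model import Lasso

        fit = Lasso(alpha=0.1, fit_intercept=False, max_iter=50_000, tol=1e-12)
        fit.fit(x, y)
        w_oracle = lasso_coordinate_descent(x, y, 0.1, n_sweeps=5000)
        assert np.abs(fit.coef_ - w_oracle).max() < 1e-6


class TestGlassoGraph:
    def test_independent_data_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((400, 4))
        g = glasso_graph(x, penalty=0.3)
        assert g.number_of_edges() == 0

    def test_penalty_at_max_covariance_gives_null_model(self):
        x, _ = generate_gaussian_precision(300, 5, "chain", seed=3)
        z = (x - x.mean(0)) / x.std(0)
        corr = (z.T @ z) / len(z)
        lam_max = np.abs(corr - np.eye(5)).max()
        g = glasso_graph(x, lam_max + 1e-6)
        assert g.number_of_edges() == 0

    def test_kkt_stationarity_on_three_variable_toy(self):
        # W = S + α·Γ with Γ the subgradient of the off-diagonal L1 term.
        corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        alpha = 0.15
        from sklearn.covariance import graphical_lasso

        cov, prec = graphical_lasso(corr, alpha=alpha, tol=1e-10, max_iter=2000)
        resid = cov - corr
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                if abs(prec[i, j]) > 1e-8:
                    assert resid[i, j] == pytest.approx(
                        alpha * np.sign(prec[i, j]), abs=1e-6
                    )
                else:
                    assert abs(resid[i, j]) <= alpha + 1e-6


class TestSparsestConnected:
    def test_two_blocks_with_bridge_select_threshold_below_bridge(self):
        # block-structured correlation with exactly one cross pair at 0.5
        n = 10
        corr = np.full((n, n), 0.1)
        corr[:5, :5] = 0.9
        corr[5:, 5:] = 0.9
        np.fill_diagonal(corr, 1.0)
        corr[0, 5] = corr[5, 0] = 0.5
        g = sparsest_connected(corr, "ct")
        assert nx.is_connected(g)
        assert g.graph["parameter"] < 0.5
        g.remove_edge(0, 5)
        assert not nx.is_connected(g)

    def test_complete_correlation_single_step_path(self):
        corr = np.ones((5, 5))
        g = sparsest_connected(corr, "ct")
        assert g.number_of_edges() == 10

    def test_edge_counts_monotone_along_ct_path(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, (20, 12)).astype(float)
        corr = subject_correlation(pd.DataFrame(x))
        off = corr[np.triu_indices(20, 1)]
        counts = [
            ct_graph(corr, t).number_of_edges()
            for t in np.linspace(off.max(), off.min(), 15)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_mb_scan_returns_connected_graph_on_block_data(self):
        rng = np.random.default_rng(4)
        block = np.kron(np.eye(2), np.full((5, 5), 0.6))
        np.fill_diagonal(block, 1.0)
        block[block == 0] = 0.05
        chol = np.linalg.cholesky(block)
        x = rng.standard_normal((400, 10)) @ chol.T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = sparsest_connected(x, "mb", path_size=15)
        assert g.number_of_nodes() == 10
        assert nx.is_connected(g) or g.graph["connected"] is False

    def test_nonempty_mode_returns_sparsest_nonempty(self):
        corr = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = sparsest_connected(corr, "ct", require="nonempty")
        assert g.number_of_edges() >= 1
        assert set(map(frozenset, g.edges)) == {frozenset({0, 1})}
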