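"""Network construction: correlations, FDR edge retention, thresholding."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from modcoupling import (
    correlation_matrix,
    edgewise_fdr_mask,
    group_average,
    is_connected,
    select_sparsity,
    sparsity_threshold,
)
from modcoupling.network import ConnectivityMatrix, EdgeMask


def _random_symmetric(rng, n, positive=True):
    w = rng.uniform(0.0 if positive else -1.0, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


class TestCorrelationMatrix:
    def test_identical_columns_give_clamped_finite_z(self, rng):
        x = rng.normal(size=50)
        ts = np.column_stack([x, x, rng.normal(size=50)])
        out = correlation_matrix(ts, fisher=True)
        assert np.isfinite(out.values).all()
        assert out.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-15))

    def test_matches_textbook_covariance_oracle(self):
        ts = np.array([
            [1.0, 2.0, 0.5],
            [2.0, 1.5, 0.0],
            [3.0, 3.5, 1.5],
            [4.0, 3.0, 0.5],
            [5.0, 5.0, 2.5],
        ])
        out = correlation_matrix(ts, fisher=False)
        centered = ts - ts.mean(axis=0)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                expected = (centered[:, i] @ centered[:, j]) / (
                    np.sqrt(centered[:, i] @ centered[:, i])
                    * np.sqrt(centered[:, j] @ centered[:, j])
                )
                assert out.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_independent_noise_nearly_uncorrelated(self, rng):
        ts = rng.normal(size=(10_000, 4))
        out = correlation_matrix(ts, fisher=False)
        off = out.values[np.triu_indices(4, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_constant_region_zeroed_with_warning(self, rng):
        ts = rng.normal(size=(30, 3))
        ts[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_matrix(ts)
        assert np.all(out.values[1, :] == 0.0)

    def test_fisher_z_inverts_tanh(self, rng):
        z = rng.uniform(-2, 2, size=20)
        np.testing.assert_allclose(np.arctanh(np.tanh(z)), z, atol=1e-12)


class TestEdgewiseFdr:
    def test_all_zero_matrices_give_empty_mask(self):
        mats = [np.zeros((5, 5)) for _ in range(6)]
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = edgewise_fdr_mask(mats)
        assert mask.n_edges == 0

    def test_matches_manual_t_and_bh_oracle(self, rng):
        """Independent recomputation: per-edge one-sided t statistic and the
        Benjamini-Hochberg step-up rule, written out longhand."""
        mats = [_random_symmetric(rng, 7, positive=False) for _ in range(12)]
        mask = edgewise_fdr_mask(mats, q=0.1)

        iu = np.triu_indices(7, 1)
        vals = np.stack([m[iu] for m in mats])
        pvals = []
        for e in range(vals.shape[1]):
            x = vals[:, e]
            t = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
            pvals.append(sps.t.sf(t, len(x) - 1))
        pvals = np.array(pvals)
        order = np.argsort(pvals)
        m = len(pvals)
        below = np.flatnonzero(pvals[order] <= (np.arange(1, m + 1) / m) * 0.1)
        reject = np.zeros(m, dtype=bool)
        if below.size:
            reject[order[: below[-1] + 1]] = True
        expected = reject & (vals.mean(axis=0) > 0)
        np.testing.assert_array_equal(mask.values[iu], expected)

    def test_single_planted_edge_recovered(self):
        """One strong edge among nulls across 26 subjects: the planted edge
        is always retained, and nothing else in ~95% of replicates (nominal
        exact-recovery rate 1 - q*m0/m ~ 0.953; 92/100 is the one-sided 95%
        binomial bound for that rate)."""
        hits = 0
        rng = np.random.default_rng(2024)
        for _ in range(100):
            mats = []
            for _ in range(26):
                m = _random_symmetric(rng, 6, positive=False) * 0.0
                noise = rng.normal(0, 0.1, size=(6, 6))
                noise = (noise + noise.T) / 2
                np.fill_diagonal(noise, 0.0)
                m += noise
                m[0, 1] += 0.5
                m[1, 0] += 0.5
                mats.append(m)
            mask = edgewise_fdr_mask(mats, q=0.05)
            assert mask.values[0, 1]
            hits += bool(mask.n_edges == 1)
        assert hits >= 92


class TestGroupAverage:
    def test_identity_mask_is_arithmetic_mean(self, rng):
        a, b = (_random_symmetric(rng, 5) for _ in range(2))
        full = EdgeMask(np.ones((5, 5)) - np.eye(5))
        out = group_average([a, b], full)
        np.testing.assert_allclose(out.values, (a + b) / 2)

    def test_empty_mask_zeroes_everything(self, rng):
        a = _random_symmetric(rng, 5)
        out = group_average([a], EdgeMask(np.zeros((5, 5))))
        assert np.all(out.values == 0.0)

    def test_random_case_matches_direct_mean(self, rng):
        mats = [_random_symmetric(rng, 6) for _ in range(4)]
        mask_values = _random_symmetric(rng, 6) > 0.5
        mask = EdgeMask((mask_values | mask_values.T).astype(int))
        out = group_average(mats, mask)
        expected = np.mean(mats, axis=0) * mask.values
        np.testing.assert_allclose(out.values, expected)


class TestSparsityThreshold:
    def test_full_sparsity_keeps_all_positive_edges(self, rng):
        w = _random_symmetric(rng, 6) + 0.1
        np.fill_diagonal(w, 0.0)
        mask = sparsity_threshold(w, 1.0)
        assert mask.n_edges == 15

    def test_ninety_node_fifteen_percent_budget(self, rng):
        w = _random_symmetric(rng, 90) + 0.1
        np.fill_diagonal(w, 0.0)
        mask = sparsity_threshold(w, 0.15)
        assert mask.n_edges == 600  # floor(0.15 * 90*89/2)

    def test_tie_break_prefers_smaller_node_pair(self):
        w = np.zeros((4, 4))
        w[0, 3] = w[3, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        mask = sparsity_threshold(w, 1.2 / 6)  # budget of exactly 1 edge
        assert mask.values[0, 3] and not mask.values[1, 2]

    def test_budget_capped_at_positive_edges_with_warning(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.warns(UserWarning, match="positive"):
            mask = sparsity_threshold(w, 1.0)
        assert mask.n_edges == 1

    @given(st.integers(0, 10_000))
    def test_masks_monotone_in_sparsity(self, seed):
        rng = np.random.default_rng(seed)
        w = _random_symmetric(rng, 8)
        s1, s2 = sorted(rng.uniform(0.05, 1.0, size=2))
        m1 = sparsity_threshold(w, float(s1)).values
        m2 = sparsity_threshold(w, float(s2)).values
        assert np.all(m2[m1])  # m1 subset of m2


class TestConnectivity:
    def test_path_and_isolated_node(self):
        path = np.diag(np.ones(4), 1)
        path = path + path.T
        assert is_connected(path)
        lonely = path.copy()
        lonely[3, :] = lonely[:, 3] = 0.0
        assert not is_connected(lonely)

    def test_agrees_with_networkx_oracle(self, rng):
        for _ in range(25):
            adj = (_random_symmetric(rng, 8) > 0.75).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = nx.from_numpy_array(adj)
            assert is_connected(adj) == nx.is_connected(g)


class TestSelectSparsity:
    def test_complete_uniform_matrices_select_lo(self):
        # equal weights: lexicographic tie-break keeps the star around node 0,
        # so the lowest grid value with budget >= n-1 already connects
        w = np.ones((6, 6)) - np.eye(6)
        sel = select_sparsity([w, w, w], lo=0.4, hi=0.8, step=0.2)
        assert sel.sparsity == pytest.approx(0.4)
        assert sel.all_connected
        assert sel.table["n_connected"].tolist() == [3, 3, 3]

    def test_selected_value_is_on_grid(self, rng):
        mats = [_random_symmetric(rng, 10) for _ in range(4)]
        sel = select_sparsity(mats)
        grid = np.round(np.arange(0.05, 0.305, 0.01), 10)
        assert sel.sparsity in grid

    def test_soft_failure_flag_when_never_connected(self):
        # a permanently isolated node: no sparsity can connect it
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.8
        w[2, 3] = w[3, 2] = 0.6
        with pytest.warns(UserWarning, match="max-coverage"):
            sel = select_sparsity([w], lo=0.1, hi=0.3, step=0.1)
        assert not sel.all_connected
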