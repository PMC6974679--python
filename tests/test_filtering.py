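"""Unit tests for surrogate statistical filtering and OMST topology filtering."""

import numpy as np
import pytest

from nmstate.connectivity import make_window_plan
from nmstate.filtering import (
    FilteredGraph,
    SurrogateConfig,
    cut_splice_surrogate,
    edge_pvalues,
    fdr_mask,
    omst_filter,
    statistical_filter,
)


def _coupled_and_independent_phases(seed=0, fs=128.0, duration=16.0):
    """Three channels; 0-1 are lag-coupled during the even 2 s blocks only.

    The rotation surrogate draws its null from the rest of the recording,
    so it has power exactly when coupling is intermittent — the dynamic-
    connectivity regime the filter is designed for. Channel 2 is always
    independent.
    """
    rng = np.random.default_rng(seed)
    T = int(fs * duration)
    t = np.arange(T) / fs
    driver = 2 * np.pi * 20 * t + np.cumsum(rng.normal(0, 0.3, T))
    indep_b = 2 * np.pi * 24 * t + np.cumsum(rng.normal(0, 0.3, T))
    indep_c = 2 * np.pi * 17 * t + np.cumsum(rng.normal(0, 0.3, T))
    block = (np.arange(T) // int(2 * fs)) % 2  # 0 = coupled, 1 = uncoupled
    follower = np.where(block == 0, driver + np.pi / 4, indep_b)
    return np.vstack([driver, follower, indep_c])


class TestSurrogateConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SurrogateConfig(n_surrogates=0)
        with pytest.raises(ValueError):
            SurrogateConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SurrogateConfig(fdr_q=0.0)


class TestCutSplice:
    def test_preserves_sample_multiset(self, rng):
        x = rng.normal(0, 1, 200)
        s = cut_splice_surrogate(x, rng)
        assert s.shape == x.shape
        assert np.allclose(np.sort(s), np.sort(x))
        assert not np.allclose(s, x)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            cut_splice_surrogate(np.zeros(3), rng)


class TestEdgePvalues:
    def test_coupled_edge_small_independent_edge_large(self):
        phases = _coupled_and_independent_phases(seed=0)
        window = (1024, 1280)  # an even (coupled) 2 s block
        p, observed = edge_pvalues(
            phases, window, SurrogateConfig(n_surrogates=200, seed=1)
        )
        assert p.shape == (3, 3)
        assert np.allclose(p, p.T) and np.all(np.diag(p) == 1.0)
        assert p[0, 1] == pytest.approx(1.0 / 201.0)  # strongly coupled
        assert p[0, 2] > 0.05 and p[1, 2] > 0.05  # independent
        assert observed[0, 1] > 0.5

    def test_pvalues_never_zero(self):
        phases = _coupled_and_independent_phases(seed=2)
        p, _ = edge_pvalues(
            phases, (0, 256), SurrogateConfig(n_surrogates=50, seed=3)
        )
        assert np.all(p >= 1.0 / 51.0)


class TestFdrMask:
    def test_all_tiny_pvalues_survive(self):
        p = np.full((5, 5), 1e-6)
        np.fill_diagonal(p, 1.0)
        mask = fdr_mask(p, q=0.05)
        assert mask.sum() == 20  # all off-diagonal entries

    def test_all_ones_rejected(self):
        p = np.ones((5, 5))
        assert fdr_mask(p, q=0.05).sum() == 0

    def test_mask_symmetric_with_false_diagonal(self, rng):
        p = rng.uniform(size=(6, 6))
        p = (p + p.T) / 2
        mask = fdr_mask(p, q=0.2)
        assert np.array_equal(mask, mask.T)
        assert not mask.diagonal().any()


class TestStatisticalFilter:
    def test_coupled_edges_survive_independent_edges_zeroed(self):
        phases = _coupled_and_independent_phases(seed=4)
        plan = make_window_plan(phases.shape[1], 128.0, 2.0, 2.0)
        cfg = SurrogateConfig(n_surrogates=100, alpha=0.05, fdr_q=0.05, seed=5)
        tensor = statistical_filter(phases, plan, cfg)
        assert tensor.shape == (plan.n_windows, 3, 3)
        coupled_windows = np.arange(plan.n_windows) % 2 == 0
        coupled = tensor[coupled_windows, 0, 1]
        uncoupled = tensor[~coupled_windows, 0, 1]
        indep = tensor[:, 0, 2]
        assert np.mean(coupled > 0) >= 0.75
        assert np.mean(uncoupled > 0) <= 0.25
        assert np.mean(indep > 0) <= 0.2


class TestOmst:
    def _random_connected(self, rng, n, p=0.6):
        from scipy.sparse.csgraph import connected_components

        while True:
            A = rng.random((n, n)) < p
            W = np.triu(A, 1) * rng.uniform(0.1, 1.0, (n, n))
            W = W + W.T
            if connected_components(W > 0, directed=False)[0] == 1:
                return W

    def test_tree_input_returned_whole(self):
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 0.5), (1, 2, 0.8), (2, 3, 0.3)]:
            W[i, j] = W[j, i] = w
        fg, diag = omst_filter(W)
        assert diag["m_star"] == 1
        assert np.allclose(fg.weights, W)

    def test_rounds_are_edge_disjoint_spanning_trees(self, rng):
        W = self._random_connected(rng, 8)
        _, diag = omst_filter(W)
        seen = set()
        n = W.shape[0]
        for tree in diag["rounds"]:
            assert len(tree) == n - 1
            edges = {frozenset((i, j)) for i, j, _ in tree}
            assert not (edges & seen)
            seen |= edges
            # each round spans all nodes
            nodes = {v for i, j, _ in tree for v in (i, j)}
            assert nodes == set(range(n))

    def test_selection_subset_of_input_weights(self, rng):
        W = self._random_connected(rng, 7)
        fg, _ = omst_filter(W)
        assert isinstance(fg, FilteredGraph)
        nz = fg.weights > 0
        assert np.allclose(fg.weights[nz], W[nz])
        assert np.array_equal(fg.mask, fg.weights > 0)

    def test_cost_curve_increasing_j_matches_ge_minus_cost(self, rng):
        W = self._random_connected(rng, 8)
        _, diag = omst_filter(W)
        assert np.all(np.diff(diag["cost_curve"]) > 0)
        assert np.allclose(
            diag["j_curve"], diag["ge_curve"] - diag["cost_curve"]
        )

    def test_disconnected_input_filtered_per_component(self, rng):
        W = np.zeros((6, 6))
        W[:3, :3] = self._random_connected(rng, 3, p=1.0)
        W[3:, 3:] = self._random_connected(rng, 3, p=1.0)
        with pytest.warns(UserWarning, match="disconnected"):
            fg, diag = omst_filter(W)
        assert "components" in diag
        assert np.all(fg.weights[:3, 3:] == 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            omst_filter(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            omst_filter(np.array([[0.0, -1.0], [-1.0, 0.0]]))
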