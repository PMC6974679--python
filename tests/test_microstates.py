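"""Unit tests for Laplacian eigen-features, neural gas and state alignment."""

import numpy as np
import pytest

from nmstate.microstates import (
    SymbolicTimeSeries,
    align_states,
    laplacian_spectrum_sequence,
    neural_gas_fit,
    normalized_laplacian,
    symbolize,
)


def _clique_tensor(blocks, n_nodes, n_windows, rng, jitter=0.02):
    """Windows of a fixed block-clique graph with small weight jitter."""
    G = np.zeros((n_nodes, n_nodes))
    for lo, hi in blocks:
        G[lo:hi, lo:hi] = 0.7
    np.fill_diagonal(G, 0.0)
    out = np.empty((n_windows, n_nodes, n_nodes))
    for j in range(n_windows):
        noise = rng.normal(0, jitter, (n_nodes, n_nodes))
        noise = (noise + noise.T) / 2
        W = np.clip(G + (G > 0) * noise, 0, 1)
        np.fill_diagonal(W, 0.0)
        out[j] = W
    return out


class TestNormalizedLaplacian:
    def test_k2_spectrum(self):
        L = normalized_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        lam = np.sort(np.linalg.eigvalsh(L))
        assert np.allclose(lam, [0.0, 2.0])

    def test_k3_spectrum(self):
        G = np.ones((3, 3)) - np.eye(3)
        lam = np.sort(np.linalg.eigvalsh(normalized_laplacian(G)))
        assert np.allclose(lam, [0.0, 1.5, 1.5])

    def test_weight_scale_invariance(self, rng):
        A = rng.random((5, 5))
        A = np.triu(A, 1)
        W = A + A.T
        l1 = np.linalg.eigvalsh(normalized_laplacian(W))
        l2 = np.linalg.eigvalsh(normalized_laplacian(3.7 * W))
        assert np.allclose(np.sort(l1), np.sort(l2))

    def test_isolated_node_contributes_zero_eigenvalue(self):
        G = np.zeros((3, 3))
        G[0, 1] = G[1, 0] = 1.0
        lam = np.sort(np.linalg.eigvalsh(normalized_laplacian(G)))
        assert np.allclose(lam, [0.0, 0.0, 2.0])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            normalized_laplacian(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestSpectrumSequence:
    def test_shape_bounds_and_sorting(self, rng):
        T = np.abs(rng.normal(0, 1, (4, 6, 6)))
        T = (T + T.transpose(0, 2, 1)) / 2
        for j in range(4):
            np.fill_diagonal(T[j], 0.0)
        V = laplacian_spectrum_sequence(T)
        assert V.shape == (6, 4)
        assert np.all((V >= 0) & (V <= 2))
        assert np.all(np.diff(V, axis=0) >= 0)

    def test_spectrum_invariant_to_node_relabeling(self, rng):
        W = np.abs(rng.normal(0, 1, (7, 7)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        perm = rng.permutation(7)
        V1 = laplacian_spectrum_sequence(W[None])
        V2 = laplacian_spectrum_sequence(W[np.ix_(perm, perm)][None])
        assert np.allclose(V1, V2)


class TestNeuralGas:
    def test_k1_is_mean_with_unit_distortion(self, rng):
        V = rng.normal(0, 1, (5, 40))
        cb = neural_gas_fit(V, 1)
        assert np.allclose(cb.prototypes[0], V.mean(axis=1))
        assert cb.distortion == pytest.approx(1.0)

    def test_two_separated_clusters_recovered(self, rng):
        a = rng.normal(0, 0.05, (4, 30))
        b = rng.normal(3, 0.05, (4, 30))
        V = np.concatenate([a, b], axis=1)
        cb = neural_gas_fit(V, 2, seed=0)
        labels = cb.assignments
        # each half uniformly assigned to one prototype, halves differ
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]
        assert cb.distortion < 0.05

    def test_deterministic_under_seed(self, rng):
        V = rng.normal(0, 1, (4, 50))
        cb1 = neural_gas_fit(V, 3, seed=7)
        cb2 = neural_gas_fit(V, 3, seed=7)
        assert np.allclose(cb1.prototypes, cb2.prototypes)
        assert np.array_equal(cb1.assignments, cb2.assignments)

    def test_distortion_decreases_with_k(self, rng):
        V = np.concatenate(
            [rng.normal(m, 0.1, (3, 20)) for m in (0.0, 1.0, 2.0)], axis=1
        )
        d = [neural_gas_fit(V, k, seed=0).distortion for k in (1, 2, 3)]
        assert d[0] == pytest.approx(1.0)
        assert d[2] < d[1] < d[0]

    def test_invalid_k_rejected(self, rng):
        V = rng.normal(0, 1, (3, 10))
        with pytest.raises(ValueError):
            neural_gas_fit(V, 0)
        with pytest.raises(ValueError):
            neural_gas_fit(V, 11)


class TestSymbolize:
    def test_labels_one_based(self, rng):
        V = rng.normal(0, 1, (3, 20))
        sts = symbolize(neural_gas_fit(V, 2, seed=0))
        assert sts.labels.min() >= 1 and sts.labels.max() <= 2
        assert len(sts) == 20

    def test_label_range_validated(self):
        with pytest.raises(ValueError):
            SymbolicTimeSeries(labels=np.array([0, 1]), k=2)


class TestAlignStates:
    def _cohort_codebooks(self, rng, n_subjects=4, swap_half=True):
        """Codebooks whose prototypes are noisy copies of two archetypes,
        stored in per-subject random order."""
        arch = np.vstack(
            [np.linspace(0, 2, 8), np.concatenate([np.zeros(4), np.full(4, 2.0)])]
        )
        books, orders = [], []
        for s in range(n_subjects):
            order = np.array([1, 0]) if (swap_half and s % 2) else np.array([0, 1])
            protos = arch[order] + rng.normal(0, 0.01, (2, 8))
            books.append(
                type("CB", (), {"prototypes": protos, "k": 2, "assignments": None})()
            )
            orders.append(order)
        return books, orders

    def test_permutations_undo_subject_level_swaps(self, rng):
        books, orders = self._cohort_codebooks(rng)
        res = align_states(books, seed=0)
        assert res["n_clusters"] == 2
        relabeled = [
            perm[order] for perm, order in zip(res["permutations"], orders)
        ]
        # after alignment every subject maps archetype i to the same label
        assert all(np.array_equal(r, relabeled[0]) for r in relabeled)

    def test_group_matching_identity_for_shared_archetypes(self, rng):
        books, _ = self._cohort_codebooks(rng)
        res = align_states(books, group_labels=["a", "a", "b", "b"], seed=0)
        gm = res["group_matching"]
        assert gm is not None
        assert sorted(gm["a"]) == sorted(gm["b"]) == [0, 1]

    def test_identical_prototypes_degenerate_path(self):
        cb = type(
            "CB",
            (),
            {"prototypes": np.ones((2, 4)), "k": 2, "assignments": None},
        )
        with pytest.warns(UserWarning, match="identical"):
            res = align_states([cb(), cb()], seed=0)
        assert all(np.array_equal(p, [0, 1]) for p in res["permutations"])

    def test_single_subject_rejected(self, rng):
        books, _ = self._cohort_codebooks(rng, n_subjects=1, swap_half=False)
        with pytest.raises(ValueError):
            align_states(books)
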