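"""Network microstates: Laplacian eigen-features and vector quantization.

Every filtered window graph G is summarized by the ascending eigenvalues of
its normalized Laplacian

    L = I − D^{−1/2} G D^{−1/2},

a spectrum lying in [0, 2] whose shape captures the graph's synchronization
structure while being invariant to node permutations of isomorphic graphs.
Stacking the per-window spectra column-wise gives the eigen-feature matrix
V (n_eigen × n_windows). The neural-gas algorithm quantizes the columns of
V into a small codebook of k prototype spectra — the network microstates —
and the per-window nearest-prototype assignment yields a symbolic time
series (STS) that can be analysed as a first-order Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "Codebook",
    "SymbolicTimeSeries",
    "normalized_laplacian",
    "laplacian_spectrum_sequence",
    "neural_gas_fit",
    "symbolize",
    "align_states",
]


@dataclass
class Codebook:
    """Fitted vector-quantization codebook.

    Attributes
    ----------
    prototypes : ndarray (k, n_eigen)
        The microstate prototype spectra.
    assignments : ndarray (n_windows,)
        Index of the nearest prototype for each window (0-based).
    distortion : float
        Normalized distortion error
        ``DE = sum_t ||v(t) − v_rec(t)||² / sum_t ||v(t) − v̄||²``
        where v_rec is the assigned prototype; DE = 1 for k = 1 and
        shrinks toward 0 as the codebook captures the data.
    """

    prototypes: np.ndarray
    assignments: np.ndarray
    distortion: float

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]


@dataclass
class SymbolicTimeSeries:
    """Per-window microstate labels in {1..k}."""

    labels: np.ndarray
    k: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not (
            self.labels.min() >= 1 and self.labels.max() <= self.k
        ):
            raise ValueError("labels must lie in 1..k")

    def __len__(self) -> int:
        return self.labels.size


def normalized_laplacian(G: np.ndarray) -> np.ndarray:
    """Normalized Laplacian ``I − D^{−1/2} G D^{−1/2}`` of a weighted graph.

    Isolated nodes (zero strength) contribute an all-zero row/column,
    including the diagonal, so each isolated node adds one zero eigenvalue,
    consistent with counting it as its own connected component.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("negative edge weights not allowed")
    deg = G.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    L = -(dinv[:, None] * G * dinv[None, :])
    np.fill_diagonal(L, np.where(deg > 0, 1.0, 0.0))
    return L


def laplacian_spectrum_sequence(tensor: np.ndarray) -> np.ndarray:
    """Ascending normalized-Laplacian eigenvalues for every window graph.

    Parameters
    ----------
    tensor : ndarray (n_windows, n_nodes, n_nodes)

    Returns
    -------
    V : ndarray (n_nodes, n_windows)
        Column j holds the sorted spectrum of window j, clipped to the
        theoretical range [0, 2] to remove floating-point underflow.
    """
    tensor = np.asarray(tensor, dtype=float)
    n_windows, n_nodes, _ = tensor.shape
    V = np.empty((n_nodes, n_windows))
    for j in range(n_windows):
        lam = np.linalg.eigvalsh(normalized_laplacian(tensor[j]))
        V[:, j] = np.clip(np.sort(lam), 0.0, 2.0)
    return V


def _distortion(V: np.ndarray, prototypes: np.ndarray, assignments: np.ndarray) -> float:
    resid = V - prototypes[assignments].T
    centered = V - V.mean(axis=1, keepdims=True)
    denom = float(np.sum(centered**2))
    if denom == 0:
        return 0.0 if np.allclose(resid, 0) else np.inf
    return float(np.sum(resid**2)) / denom


def _assign(V: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(V.T**2, axis=1, keepdims=True)
        - 2 * V.T @ prototypes.T
        + np.sum(prototypes**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def neural_gas_fit(
    V: np.ndarray,
    k: int,
    *,
    lambda_start: float = 10.0,
    lambda_end: float = 0.01,
    eps_start: float = 0.5,
    eps_end: float = 0.005,
    steps_per_sample: int = 50,
    seed: int = 0,
) -> Codebook:
    """Fit a k-prototype codebook to the columns of V by neural gas.

    Neural gas is a rank-based soft competitive quantizer: at every
    adaptation step a random data column is drawn, the prototypes are
    ranked by distance to it, and each prototype moves toward the sample
    by ``eps(t) * exp(-rank / lambda(t))``, with both the learning rate
    ``eps`` and the neighborhood width ``lambda`` decaying exponentially
    over the run. Compared to plain k-means it is far less sensitive to
    initialization because distant prototypes are also (weakly) adapted.

    Prototypes are initialized from k distinct random data columns; the
    total number of adaptation steps is ``steps_per_sample * n_windows``.
    For ``k == 1`` the optimal prototype is the data mean in closed form
    and the distortion error is exactly 1 by construction.
    """
    V = np.asarray(V, dtype=float)
    n_eigen, n_windows = V.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_windows:
        raise ValueError(f"k={k} exceeds the number of data columns {n_windows}")

    if k == 1:
        proto = V.mean(axis=1, keepdims=True).T
        assignments = np.zeros(n_windows, dtype=int)
        return Codebook(proto, assignments, _distortion(V, proto, assignments))

    rng = np.random.default_rng(seed)
    X = V.T  # samples as rows
    init_idx = rng.choice(n_windows, size=k, replace=False)
    prototypes = X[init_idx].copy()

    t_max = steps_per_sample * n_windows
    order = rng.integers(0, n_windows, size=t_max)
    frac = np.arange(t_max) / max(t_max - 1, 1)
    lambdas = lambda_start * (lambda_end / lambda_start) ** frac
    epss = eps_start * (eps_end / eps_start) ** frac
    ranks = np.arange(k)

    for t in range(t_max):
        v = X[order[t]]
        d2 = np.sum((prototypes - v) ** 2, axis=1)
        rank_of = np.empty(k, dtype=int)
        rank_of[np.argsort(d2, kind="stable")] = ranks
        h = epss[t] * np.exp(-rank_of / lambdas[t])
        prototypes += h[:, None] * (v - prototypes)

    assignments = _assign(V, prototypes)
    return Codebook(prototypes, assignments, _distortion(V, prototypes, assignments))


def symbolize(codebook: Codebook, meta: dict | None = None) -> SymbolicTimeSeries:
    """Turn a fitted codebook's assignments into 1-based microstate labels."""
    return SymbolicTimeSeries(
        labels=codebook.assignments + 1, k=codebook.k, meta=meta or {}
    )


def _cosine_matrix(P: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = P / norms
    return U @ U.T


def align_states(
    codebooks: list[Codebook],
    group_labels: list | None = None,
    cluster_candidates: range | tuple = (2, 3, 4, 5),
    seed: int = 0,
) -> dict:
    """Align microstate labels across subjects (and optionally groups).

    All subjects' prototype spectra are pooled and clustered by K-means on
    unit-normalized vectors (i.e. cosine geometry); the number of clusters
    is chosen from ``cluster_candidates`` by the maximum silhouette index
    (cosine metric). Each subject's prototypes are then matched one-to-one
    to the cluster centers by maximum cosine similarity (Hungarian
    assignment), giving a per-subject relabeling such that "state s" means
    the same prototype cohort-wide. When ``group_labels`` is given the
    per-group mean prototypes are additionally matched across groups by
    highest cosine similarity.

    Returns
    -------
    dict with keys
        ``n_clusters`` — silhouette-selected cluster count;
        ``silhouette`` — per-candidate silhouette scores;
        ``permutations`` — list of per-subject label permutations ``perm``
        with ``perm[old_state_index] = new_state_index`` (0-based);
        ``cluster_centers`` — the pooled cluster centers;
        ``group_matching`` — cross-group state correspondence (if groups).
    """
    if len(codebooks) < 2:
        raise ValueError("alignment requires at least two subjects")
    k = codebooks[0].k
    P = np.vstack([cb.prototypes for cb in codebooks])
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    if np.allclose(P, P[0]):
        warnings.warn(
            "all prototypes identical; alignment is arbitrary but deterministic",
            stacklevel=2,
        )
        perms = [np.arange(k) for _ in codebooks]
        return {
            "n_clusters": k,
            "silhouette": {},
            "permutations": perms,
            "cluster_centers": P[:k].copy(),
            "group_matching": None,
        }
    norms[norms == 0] = 1.0
    U = P / norms

    sil: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for c in cluster_candidates:
        if c >= len(P):
            continue
        km = KMeans(n_clusters=c, n_init=10, random_state=seed).fit(U)
        if len(np.unique(km.labels_)) < 2:
            continue
        sil[c] = float(silhouette_score(U, km.labels_, metric="cosine"))
        fits[c] = km
    if not sil:
        raise ValueError("no valid clustering found over the candidate range")
    n_clusters = max(sil, key=lambda c: (sil[c], -c))
    centers = fits[n_clusters].cluster_centers_

    # Per-subject one-to-one matching of prototypes to the first k centers
    # (ordered by cluster population so "state 1" is the dominant state).
    # Matching uses the K-means geometry itself (Euclidean distance of the
    # unit-normalized prototypes to the centers): sorted spectra are often
    # globally similar, so raw cosine similarities can all be close to 1
    # while the clustering still separates them cleanly.
    counts = np.bincount(fits[n_clusters].labels_, minlength=n_clusters)
    center_order = np.argsort(-counts, kind="stable")[:k]
    target = centers[center_order]
    perms = []
    for i, cb in enumerate(codebooks):
        Ui = U[i * k : (i + 1) * k]
        cost = ((Ui[:, None, :] - target[None, :, :]) ** 2).sum(axis=2)
        row, col = linear_sum_assignment(cost)
        perm = np.empty(k, dtype=int)
        perm[row] = col
        perms.append(perm)

    group_matching = None
    if group_labels is not None:
        groups = sorted(set(group_labels), key=str)
        if len(groups) == 2:
            means = []
            for g in groups:
                sel = [
                    cb.prototypes[np.argsort(perm)]
                    for cb, perm, gl in zip(codebooks, perms, group_labels)
                    if gl == g
                ]
                means.append(np.mean(sel, axis=0))
            sim = _cosine_matrix(np.vstack(means))[:k, k:]
            row, col = linear_sum_assignment(-sim)
            group_matching = {groups[0]: row.tolist(), groups[1]: col.tolist()}

    return {
        "n_clusters": n_clusters,
        "silhouette": sil,
        "permutations": perms,
        "cluster_centers": target,
        "group_matching": group_matching,
    }
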