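"""Node metrics, subnetwork summaries and time-resolved modularity cartography.

Per-window graphs yield node degree and strength; averaging those within and
between labeled anatomical subnetworks (default mode, frontoparietal,
occipital, cingulo-opercular, sensorimotor) summarizes each microstate as a
small within/between block profile. Time-resolved community structure is
characterized per window by the modularity score Q of a Louvain partition,
the within-module degree z-score W and the participation coefficient B, and
the pooled (B, W) point cloud of each microstate is binned into a
"topological mapping" percent-time histogram whose spread distinguishes
concentrated from dispersed modular regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ModularityFrame",
    "degree_strength",
    "ban_mean_degree",
    "modularity_partition",
    "module_degree_zscore",
    "participation_coefficient",
    "modularity_frames",
    "topological_mapping",
    "tm_group_difference",
]

#: Conventional anatomical subnetwork labels.
BAN_LABELS = ("DMN", "FP", "OCC", "CO", "SM")


@dataclass
class ModularityFrame:
    """One window's community structure and cartographic node profiles."""

    partition: np.ndarray  # module index per node
    q: float
    w: np.ndarray  # within-module degree z-score per node
    b: np.ndarray  # participation coefficient per node


def degree_strength(graph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree (nonzero edge count) and strength (weight sum)."""
    G = np.asarray(graph, dtype=float)
    off = G.copy()
    np.fill_diagonal(off, 0.0)
    return (off != 0).sum(axis=1), off.sum(axis=1)


def _ban_indices(subnetwork_map: dict) -> dict:
    groups: dict = {}
    for node, label in subnetwork_map.items():
        groups.setdefault(label, []).append(node)
    return {lab: np.asarray(sorted(idx)) for lab, idx in groups.items()}


def _block_summary(M: np.ndarray, groups: dict) -> dict:
    """Within/between block means of a symmetric node-pair matrix.

    Within a block A: the mean per-node count/weight of connections to
    other nodes of A. Between blocks (A, B): the mean per-node
    cross-connection value over the nodes of A ∪ B (each cross edge is
    incident to one node on each side, hence the factor 2).
    """
    out = {}
    labels = sorted(groups)
    for a_i, a in enumerate(labels):
        ia = groups[a]
        sub = M[np.ix_(ia, ia)]
        out[(a, a)] = float(sub.sum(axis=1).mean()) if ia.size else 0.0
        for b in labels[a_i + 1 :]:
            ib = groups[b]
            cross = M[np.ix_(ia, ib)].sum()
            out[(a, b)] = float(2.0 * cross / (ia.size + ib.size))
    return out


def ban_mean_degree(
    tensor: np.ndarray,
    sts,
    subnetwork_map: dict,
    use_strength: bool = False,
) -> dict:
    """Per-microstate mean degree (or strength) within/between subnetworks.

    For every state the windows assigned to it are averaged, and for each
    of the 5 subnetworks (and each of the 10 unordered pairs) the mean
    per-node within/between connection count — or weight when
    ``use_strength`` — is reported: 15 values per state.

    Returns
    -------
    dict mapping state label → dict ``{(ban_a, ban_b): value}``; a state
    with zero windows maps to ``None``.
    """
    labels = np.asarray(getattr(sts, "labels", sts), dtype=int)
    k = int(getattr(sts, "k", labels.max()))
    tensor = np.asarray(tensor, dtype=float)
    groups = _ban_indices(subnetwork_map)
    result: dict = {}
    for s in range(1, k + 1):
        sel = labels == s
        if not np.any(sel):
            result[s] = None
            continue
        sub = tensor[sel]
        M = sub.mean(axis=0) if use_strength else (sub != 0).mean(axis=0)
        np.fill_diagonal(M, 0.0)
        result[s] = _block_summary(M, groups)
    return result


def modularity_partition(
    graph: np.ndarray, gamma: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Louvain community partition and Newman weighted modularity Q.

    Greedy node-moving with fine-tuning refinement (Louvain), resolution
    ``gamma``, deterministic under ``seed``. An empty (zero-weight) graph
    yields the single-community partition with Q = 0.
    """
    W = np.asarray(graph, dtype=float)
    if np.any(W < 0):
        raise ValueError("modularity requires nonnegative weights")
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    if off.sum() == 0:
        return np.zeros(n, dtype=int), 0.0
    G = nx.from_numpy_array(off)
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=seed
    )
    partition = np.empty(n, dtype=int)
    for m, nodes in enumerate(comms):
        for v in nodes:
            partition[v] = m
    q = nx.community.modularity(G, comms, weight="weight", resolution=gamma)
    return partition, float(q)


def module_degree_zscore(graph: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Within-module degree z-score W per node.

    W_r = (kappa_r − mean_module kappa) / sd_module kappa, where kappa is
    the node's strength of connections inside its own module (population
    standard deviation). Modules with zero spread give W = 0.
    """
    W = np.asarray(graph, dtype=float)
    part = np.asarray(partition, dtype=int)
    n = W.shape[0]
    z = np.zeros(n)
    for m in np.unique(part):
        idx = np.flatnonzero(part == m)
        kappa = W[np.ix_(idx, idx)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            z[idx] = (kappa - kappa.mean()) / sd
    return z


def participation_coefficient(
    graph: np.ndarray, partition: np.ndarray
) -> np.ndarray:
    """Participation coefficient B per node.

    B_r = 1 − sum_s (kappa_rs / kappa_r)² over modules s, where kappa_rs
    is the node's strength into module s and kappa_r its total strength.
    B = 0 when all connections stay within the node's own module (or the
    node is isolated); B approaches 1 − 1/n_modules for a uniform spread.
    """
    W = np.asarray(graph, dtype=float)
    part = np.asarray(partition, dtype=int)
    total = W.sum(axis=1)
    b = np.zeros(W.shape[0])
    nz = total > 0
    acc = np.zeros(W.shape[0])
    for m in np.unique(part):
        idx = part == m
        ks = W[:, idx].sum(axis=1)
        acc[nz] += (ks[nz] / total[nz]) ** 2
    b[nz] = 1.0 - acc[nz]
    return b


def modularity_frames(
    tensor: np.ndarray, gamma: float = 1.0, seed: int = 0
) -> list[ModularityFrame]:
    """Partition every window graph and compute its cartographic profiles."""
    frames = []
    for j, G in enumerate(np.asarray(tensor, dtype=float)):
        part, q = modularity_partition(G, gamma=gamma, seed=seed)
        frames.append(
            ModularityFrame(
                partition=part,
                q=q,
                w=module_degree_zscore(G, part),
                b=participation_coefficient(G, part),
            )
        )
    return frames


def topological_mapping(
    frames: list[ModularityFrame],
    sts,
    state: int,
    bins: tuple[int, int] = (20, 20),
    b_range: tuple[float, float] = (0.0, 1.0),
    w_range: tuple[float, float] = (-3.0, 3.0),
) -> dict:
    """Joint (B, W) percent-time histogram of one microstate.

    The (participation, within-module z-score) pairs of every node in
    every window assigned to ``state`` are pooled and binned on a fixed
    grid; the histogram is normalized to percent so bins sum to 100.
    Values outside the grid are clipped into the edge bins so no mass is
    lost. An empty state returns ``hist=None`` with ``empty=True``.
    """
    labels = np.asarray(getattr(sts, "labels", sts), dtype=int)
    sel = np.flatnonzero(labels == state)
    b_edges = np.linspace(*b_range, bins[0] + 1)
    w_edges = np.linspace(*w_range, bins[1] + 1)
    if sel.size == 0:
        return {"hist": None, "b_edges": b_edges, "w_edges": w_edges, "empty": True}
    B = np.concatenate([frames[j].b for j in sel])
    W = np.concatenate([frames[j].w for j in sel])
    B = np.clip(B, b_range[0], b_range[1])
    W = np.clip(W, w_range[0], w_range[1])
    hist, _, _ = np.histogram2d(B, W, bins=[b_edges, w_edges])
    hist = 100.0 * hist / hist.sum()
    return {"hist": hist, "b_edges": b_edges, "w_edges": w_edges, "empty": False}


def tm_group_difference(tm_a: dict, tm_b: dict) -> dict:
    """Relative difference map between two topological-mapping profiles.

    Computes (b − a) / a on every bin where the reference profile a is
    nonzero, and the percentage of those bins with positive and with
    negative differences. Bins where the reference is zero are excluded
    from the sign counts (the map holds NaN there).
    """
    if tm_a.get("empty") or tm_b.get("empty"):
        raise ValueError("cannot difference an empty profile")
    a, b = tm_a["hist"], tm_b["hist"]
    if a.shape != b.shape or not np.allclose(tm_a["b_edges"], tm_b["b_edges"]):
        raise ValueError("profiles must share the same bin grid")
    support = a > 0
    rel = np.full_like(a, np.nan)
    rel[support] = (b[support] - a[support]) / a[support]
    n_support = int(support.sum())
    pos = float(100.0 * np.sum(rel[support] > 0) / n_support) if n_support else 0.0
    neg = float(100.0 * np.sum(rel[support] < 0) / n_support) if n_support else 0.0
    return {"relative_difference": rel, "percent_positive": pos, "percent_negative": neg}
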