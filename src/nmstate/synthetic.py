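"""Ground-truthed synthetic cohorts of phase-coupled oscillatory signals.

The generator emulates the statistical structure the analysis pipeline
assumes: band-limited oscillatory node signals whose lagged phase-coupling
topology switches among a small set of latent states according to a
first-order Markov chain, with optional group-level differences in the
transition rates and coupling graphs.

Signal model. A common narrowband phase process
``Phi(t) = 2*pi*f_c*t + random walk`` drives every coupled component: in
the active state, one node per connected component of the state's coupling
graph carries ``Phi`` itself and every other coupled node carries
``Phi + phase_lag + jitter``, so the pairwise imaginary phase-locking value
of a driver–follower pair has the closed form ``|sin(phase_lag)|`` (up to
jitter attenuation). Uncoupled nodes run independent phase processes with
their own within-band frequencies, so their pairwise iPLV vanishes with
window length. State changes are aligned to window boundaries (the default
step equals the window), making the planted per-window labels unambiguous.
Observation noise is additive Gaussian applied after the narrowband
synthesis, which keeps the Hilbert phase well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nmstate.connectivity import ROITimeseries, make_window_plan

__all__ = [
    "StateSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_state_sequence",
    "generate_coupled_timeseries",
    "generate_voxel_cluster",
    "generate_cohort",
]


@dataclass
class StateSpec:
    """One latent coupling state.

    Parameters
    ----------
    state_id : int
        Label of the state (1-based by convention).
    coupling_graph : ndarray (n_nodes, n_nodes)
        Symmetric nonnegative coupling strengths, zero diagonal. Any
        nonzero entry marks the pair as phase-coupled in this state.
    phase_lag : float
        Base lag in radians. Within a coupled component the m-th node (in
        index order) carries an offset of ``m * phase_lag`` from the
        component's driver, so every coupled pair has a nonzero relative
        lag. No multiple of ``phase_lag`` up to the largest component size
        may equal 0 or pi (mod pi), or the imaginary PLV would be blind to
        that pair.
    """

    state_id: int
    coupling_graph: np.ndarray
    phase_lag: float = np.pi / 4

    def __post_init__(self) -> None:
        G = np.asarray(self.coupling_graph, dtype=float)
        if not np.allclose(G, G.T):
            raise ValueError("coupling_graph must be symmetric")
        if np.any(np.diag(G) != 0):
            raise ValueError("coupling_graph must have zero diagonal")
        if np.any(G < 0):
            raise ValueError("coupling strengths must be nonnegative")
        self.coupling_graph = G
        if np.any(G > 0):
            # largest coupled component bounds the staggered-lag multiples
            from scipy.sparse.csgraph import connected_components

            coupled = (G > 0).any(axis=1)
            _, labels = connected_components(G > 0, directed=False)
            sizes = np.bincount(labels[coupled])
            c_max = int(sizes.max())
            for m in range(1, c_max):
                lag_mod = abs(m * self.phase_lag) % np.pi
                if min(lag_mod, np.pi - lag_mod) < 1e-9:
                    raise ValueError(
                        f"lag multiple {m}*phase_lag is 0 or pi (mod pi); "
                        "such a coupled pair would be invisible to the iPLV"
                    )


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    ``transition_matrices`` maps each group name to a row-stochastic
    matrix over the states; the same ``states`` repertoire is shared by
    all groups. ``step_s`` defaults to the window length so that latent
    state changes fall exactly on analysis-window boundaries.
    """

    n_subjects_per_group: int = 10
    n_nodes: int = 12
    fs: float = 128.0
    duration: float = 120.0
    band: tuple[float, float] = (13.0, 30.0)
    states: list[StateSpec] = field(default_factory=list)
    transition_matrices: dict = field(default_factory=dict)
    noise_sd: float = 0.2
    seed: int = 0
    window_s: float = 2.0
    step_s: float | None = None
    phase_walk_sd: float = 0.3
    phase_jitter_sd: float = 0.05
    independent_walk_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.step_s is None:
            self.step_s = self.window_s
        if not 0 < self.band[0] < self.band[1] < self.fs / 2:
            raise ValueError(f"band {self.band} outside (0, fs/2)")
        if self.duration * self.fs < self.window_s * self.fs:
            raise ValueError("duration shorter than one analysis window")
        for g, P in self.transition_matrices.items():
            P = np.asarray(P, dtype=float)
            _validate_stochastic(P)
            if P.shape[0] != len(self.states):
                raise ValueError(f"transition matrix for {g} does not match states")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def n_windows(self) -> int:
        plan = make_window_plan(self.n_samples, self.fs, self.window_s, self.step_s)
        return plan.n_windows


@dataclass
class GroundTruth:
    """Planted latent structure of a generated cohort."""

    state_sequences: dict  # subject_id -> ndarray of planted labels
    groups: dict  # subject_id -> group name
    coupling_graphs: dict  # state_id -> coupling matrix


def _validate_stochastic(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")


def generate_state_sequence(
    transition_matrix: np.ndarray,
    n_windows: int,
    seed: int | np.random.Generator = 0,
    start: int | None = None,
) -> np.ndarray:
    """Sample a label sequence from a first-order Markov chain.

    Labels are 0-based state indices. The initial state is drawn
    uniformly unless ``start`` is given. Empirical transition frequencies
    converge to the configured matrix as ``n_windows`` grows.
    """
    P = np.asarray(transition_matrix, dtype=float)
    _validate_stochastic(P)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_states = P.shape[0]
    seq = np.empty(n_windows, dtype=int)
    seq[0] = int(rng.integers(n_states)) if start is None else start
    # inverse-CDF draws keep the chain reproducible under one generator
    cdf = np.cumsum(P, axis=1)
    u = rng.random(n_windows - 1)
    for t in range(1, n_windows):
        seq[t] = int(np.searchsorted(cdf[seq[t - 1]], u[t - 1], side="right"))
    return seq


def _components(G: np.ndarray) -> list[list[int]]:
    """Connected components of the coupled subgraph, in index order."""
    n = G.shape[0]
    coupled = (G > 0).any(axis=1)
    adj = G > 0
    visited = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if visited[i] or not coupled[i]:
            continue
        stack, comp = [i], []
        visited[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(adj[v]):
                if not visited[w]:
                    visited[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _state_layout(state: StateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (component index, lag offset) for one state.

    Component index is −1 for uncoupled nodes. Within a component the
    m-th node (in index order) carries a lag of ``m * phase_lag``:
    staggered lags make every coupled pair carry a nonzero relative lag,
    so a coupled component appears as a weighted clique to the imaginary
    PLV; the component's first node retains the closed-form
    ``|sin(phase_lag)|`` pairing with its immediate follower.
    """
    n = state.coupling_graph.shape[0]
    comp_of = np.full(n, -1, dtype=int)
    lag = np.zeros(n)
    for c, comp in enumerate(_components(state.coupling_graph)):
        for m, v in enumerate(comp):
            comp_of[v] = c
            lag[v] = m * state.phase_lag
    return comp_of, lag


def _subject_signals(
    config: CohortConfig,
    seq: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n, T = config.n_nodes, config.n_samples
    fs = config.fs
    t = np.arange(T) / fs
    f_c = 0.5 * (config.band[0] + config.band[1])

    layouts = {s.state_id: _state_layout(s) for s in config.states}
    state_ids = [s.state_id for s in config.states]

    # one independent narrowband phase process per coupled component, so
    # distinct components are genuinely unsynchronized
    drivers = {}
    for sid in state_ids:
        for c in range(layouts[sid][0].max() + 1):
            drivers[(sid, c)] = (
                2 * np.pi * f_c * t
                + np.cumsum(rng.normal(0, config.phase_walk_sd, T))
                + rng.uniform(0, 2 * np.pi)
            )
    f_i = rng.uniform(config.band[0], config.band[1], n)
    indep = (
        2 * np.pi * f_i[:, None] * t[None, :]
        + np.cumsum(rng.normal(0, config.independent_walk_sd, (n, T)), axis=1)
        + rng.uniform(0, 2 * np.pi, n)[:, None]
    )
    jitter = rng.normal(0, config.phase_jitter_sd, (n, T))

    step = int(round(config.step_s * fs))
    block = np.clip(np.arange(T) // step, 0, seq.size - 1)
    phases = np.empty((n, T))
    for w, sid_idx in enumerate(seq):
        sid = state_ids[sid_idx]
        comp_of, lag = layouts[sid]
        cols = block == w
        for i in range(n):
            if comp_of[i] < 0:
                phases[i, cols] = indep[i, cols]
            else:
                phases[i, cols] = (
                    drivers[(sid, comp_of[i])][cols] + lag[i] + jitter[i, cols]
                )

    signals = np.cos(phases)
    if config.noise_sd > 0:
        signals = signals + rng.normal(0, config.noise_sd, signals.shape)
    return signals


def generate_coupled_timeseries(
    config: CohortConfig,
) -> tuple[dict, GroundTruth]:
    """Generate a full cohort of state-switching coupled signals.

    Returns
    -------
    subjects : dict mapping subject_id -> ROITimeseries
        Subject ids are ``"<group>_<index>"``.
    ground_truth : GroundTruth
        Planted per-window state labels (1-based state_ids), group
        membership and per-state coupling graphs.
    """
    if not config.states:
        raise ValueError("config.states must contain at least one StateSpec")
    if not config.transition_matrices:
        raise ValueError("config.transition_matrices must name at least one group")
    for s in config.states:
        if s.coupling_graph.shape[0] != config.n_nodes:
            raise ValueError("coupling_graph size does not match n_nodes")

    root = np.random.SeedSequence(config.seed)
    n_windows = config.n_windows
    state_ids = np.array([s.state_id for s in config.states])

    subjects: dict = {}
    sequences: dict = {}
    groups: dict = {}
    group_names = sorted(config.transition_matrices)
    child_seeds = root.spawn(len(group_names) * config.n_subjects_per_group)
    i = 0
    for g in group_names:
        P = np.asarray(config.transition_matrices[g], dtype=float)
        for s_idx in range(config.n_subjects_per_group):
            rng = np.random.default_rng(child_seeds[i])
            i += 1
            seq = generate_state_sequence(P, n_windows, rng)
            sid = f"{g}_{s_idx}"
            subjects[sid] = ROITimeseries(
                signals=_subject_signals(config, seq, rng),
                fs=config.fs,
                band=config.band,
            )
            sequences[sid] = state_ids[seq]
            groups[sid] = g

    gt = GroundTruth(
        state_sequences=sequences,
        groups=groups,
        coupling_graphs={s.state_id: s.coupling_graph.copy() for s in config.states},
    )
    return subjects, gt


# kept as an alias: a cohort is exactly what the time-series generator emits
generate_cohort = generate_coupled_timeseries


def generate_voxel_cluster(
    roi_signal: np.ndarray,
    n_voxels: int,
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Voxel-level copies of one ROI signal with independent noise.

    Emulates the voxel time series inside an atlas region, all sharing the
    region's representative activity; the correlation of each voxel with
    the source signal decreases with ``noise_sd``.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    x = np.asarray(roi_signal, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    out = np.tile(x, (n_voxels, 1))
    if noise_sd > 0:
        out = out + rng.normal(0, noise_sd, out.shape)
    return out
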