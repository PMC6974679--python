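"""Chronnectomics: temporal summary statistics of a microstate sequence.

The symbolic time series (STS) of per-window microstate labels is treated
as a first-order Markov chain and summarized by:

* **Flexibility index (FI)** — the transition rate, i.e. the fraction of
  consecutive window pairs whose label changes.
* **Occupancy time (OT)** — the fraction of windows spent in each state.
* **Dwell time (DT)** — the mean length (in windows) of the consecutive
  runs of each state.
* **Complexity index (CI)** — the number of distinct contiguous substrings
  of length 1..l_max, a richness measure of the symbolic dynamics.
* **Transition probability matrix (PT)** — pairwise transition fractions,
  normalized by the total number of consecutive pairs (so the whole matrix
  sums to 1 and FI + trace(PT) = 1 exactly).

Significance of each statistic is assessed against a null of exchangeable
labels: the STS is shuffled (full random permutation, which preserves OT
exactly) and add-one permutation p-values are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChronnectomicProfile",
    "flexibility_index",
    "occupancy_time",
    "dwell_time",
    "transition_matrix",
    "complexity_index",
    "chronnectomic_significance",
    "chronnectomic_profile",
]


@dataclass
class ChronnectomicProfile:
    """All chronnectomic statistics of one STS, with optional p-values."""

    fi: float
    ot: np.ndarray
    dt: np.ndarray
    ci: int
    pt: np.ndarray
    k: int
    pvalues: dict = field(default_factory=dict)


def _labels(sts) -> np.ndarray:
    x = np.asarray(getattr(sts, "labels", sts), dtype=int)
    if x.ndim != 1:
        raise ValueError("STS must be one-dimensional")
    return x


def _k_of(sts, x: np.ndarray) -> int:
    k = getattr(sts, "k", None)
    return int(k) if k is not None else int(x.max())


def flexibility_index(sts) -> float:
    """Transition rate: (# label changes) / (length − 1)."""
    x = _labels(sts)
    if x.size < 2:
        raise ValueError("flexibility index needs at least 2 windows")
    return float(np.count_nonzero(np.diff(x) != 0)) / (x.size - 1)


def occupancy_time(sts) -> np.ndarray:
    """Fraction of windows spent in each state 1..k; sums to 1."""
    x = _labels(sts)
    if x.size == 0:
        raise ValueError("empty STS")
    k = _k_of(sts, x)
    return np.bincount(x, minlength=k + 1)[1:] / x.size


def _runs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (state of each run, length of each run)."""
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [x.size]))
    return x[starts], ends - starts


def dwell_time(sts) -> np.ndarray:
    """Mean consecutive run length per state, in windows.

    States that never occur get dwell time 0.
    """
    x = _labels(sts)
    if x.size == 0:
        raise ValueError("empty STS")
    k = _k_of(sts, x)
    states, lengths = _runs(x)
    dt = np.zeros(k)
    for s in range(1, k + 1):
        sel = states == s
        if np.any(sel):
            dt[s - 1] = lengths[sel].mean()
    return dt


def transition_matrix(sts, row_stochastic: bool = False) -> np.ndarray:
    """Pairwise transition fractions PT of the label chain.

    ``PT[a-1, b-1]`` is the number of consecutive pairs (a, b) divided by
    the total number of pairs (length − 1), so the matrix sums to 1; for
    the sequence [1, 2, 2, 1, 2] this gives PT_12 = 2/4 = 0.5 and
    PT_21 = 1/4 = 0.25. With ``row_stochastic=True`` each row is instead
    normalized by its own outgoing-pair count (rows of absent states stay
    zero), the form used for Markov-chain diagrams.
    """
    x = _labels(sts)
    if x.size < 2:
        raise ValueError("transition matrix needs at least 2 windows")
    k = _k_of(sts, x)
    pt = np.zeros((k, k))
    np.add.at(pt, (x[:-1] - 1, x[1:] - 1), 1.0)
    if row_stochastic:
        rowsum = pt.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pt = np.where(rowsum > 0, pt / rowsum, 0.0)
    else:
        pt /= x.size - 1
    return pt


def complexity_index(sts, l_max: int = 10) -> int:
    """Number of distinct contiguous substrings of length 1..l_max.

    A constant sequence has exactly one distinct substring per length
    (CI = l_max); richer symbolic dynamics produce larger counts, bounded
    by ``sum_l min(k^l, n − l + 1)``.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    x = _labels(sts)
    n = x.size
    total = 0
    for length in range(1, l_max + 1):
        if length > n:
            break
        seen = {x[i : i + length].tobytes() for i in range(n - length + 1)}
        total += len(seen)
    return total


def chronnectomic_significance(
    sts,
    n_shuffles: int = 1000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> dict:
    """Permutation significance of the chronnectomic statistics.

    Each shuffle is a uniform random permutation of the labels, which
    preserves occupancy exactly (so OT p-values are 1 by construction)
    while destroying temporal ordering. FI, per-state DT and CI get
    two-sided add-one p-values ``2·min(P[surr ≤ obs], P[surr ≥ obs])``;
    every PT entry gets a two-sided p-value and the PT p-value matrix is
    Benjamini–Hochberg corrected over its entries.

    Returns a dict with keys ``fi``, ``dt`` (per state), ``ci``, ``ot``
    (per state, all 1.0), ``pt`` (raw matrix) and ``pt_fdr`` (corrected).
    """
    x = _labels(sts)
    k = _k_of(sts, x)
    rng = np.random.default_rng(seed)

    obs_fi = flexibility_index(x)
    obs_dt = dwell_time(SimpleSTS(x, k))
    obs_ci = complexity_index(SimpleSTS(x, k))
    obs_pt = transition_matrix(SimpleSTS(x, k))

    fi_s = np.empty(n_shuffles)
    dt_s = np.empty((n_shuffles, k))
    ci_s = np.empty(n_shuffles)
    pt_s = np.empty((n_shuffles, k, k))
    for i in range(n_shuffles):
        xs = rng.permutation(x)
        s = SimpleSTS(xs, k)
        fi_s[i] = flexibility_index(xs)
        dt_s[i] = dwell_time(s)
        ci_s[i] = complexity_index(s)
        pt_s[i] = transition_matrix(s)

    def two_sided(surr: np.ndarray, obs) -> np.ndarray:
        ge = (1.0 + np.sum(surr >= obs, axis=0)) / (1.0 + n_shuffles)
        le = (1.0 + np.sum(surr <= obs, axis=0)) / (1.0 + n_shuffles)
        return np.minimum(1.0, 2.0 * np.minimum(ge, le))

    p_pt = two_sided(pt_s, obs_pt)
    flat = p_pt.ravel()
    _, p_adj, _, _ = multipletests(flat, alpha=fdr_q, method="fdr_bh")

    return {
        "fi": float(two_sided(fi_s[:, None], obs_fi)[0]),
        "dt": two_sided(dt_s, obs_dt),
        "ci": float(two_sided(ci_s[:, None], obs_ci)[0]),
        "ot": np.ones(k),
        "pt": p_pt,
        "pt_fdr": p_adj.reshape(k, k),
    }


@dataclass
class SimpleSTS:
    """Minimal label-sequence carrier used internally and in tests."""

    labels: np.ndarray
    k: int


def chronnectomic_profile(
    sts,
    l_max: int = 10,
    n_shuffles: int | None = None,
    seed: int = 0,
) -> ChronnectomicProfile:
    """Compute the full chronnectomic profile of one STS.

    When ``n_shuffles`` is given, permutation p-values are attached.
    """
    x = _labels(sts)
    k = _k_of(sts, x)
    profile = ChronnectomicProfile(
        fi=flexibility_index(x),
        ot=occupancy_time(SimpleSTS(x, k)),
        dt=dwell_time(SimpleSTS(x, k)),
        ci=complexity_index(SimpleSTS(x, k), l_max=l_max),
        pt=transition_matrix(SimpleSTS(x, k)),
        k=k,
    )
    if n_shuffles:
        profile.pvalues = chronnectomic_significance(
            SimpleSTS(x, k), n_shuffles=n_shuffles, seed=seed
        )
    return profile
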