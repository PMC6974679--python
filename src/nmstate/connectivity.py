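"""Time-resolved phase-coupling connectivity from multichannel signals.

The connectivity estimator is the imaginary part of the phase-locking value
(iPLV),

    iPLV_xy = | Im( sum_t exp(i (phi_x(t) - phi_y(t))) ) | / N,

computed between instantaneous Hilbert phases within sliding windows.
Taking only the imaginary part discards zero-lag synchronization, which in
electrophysiological source data is dominated by volume conduction /
field spread; a nonzero iPLV therefore indicates lagged phase coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "BANDS",
    "ROITimeseries",
    "PhaseSeries",
    "WindowPlan",
    "bandpass_filter",
    "roi_representative_signal",
    "analytic_phase",
    "iplv",
    "make_window_plan",
    "compute_dfcg",
]

#: Canonical electrophysiological frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha_low": (8.0, 10.0),
    "alpha_high": (10.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma_low": (30.0, 55.0),
    "gamma_high": (55.0, 90.0),
}


@dataclass
class ROITimeseries:
    """Per-subject multichannel signal matrix with sampling metadata.

    Parameters
    ----------
    signals : ndarray, shape (n_nodes, n_samples)
        Band-limited real-valued signals, one row per region of interest.
    fs : float
        Sampling rate in Hz. Must exceed twice the band's upper edge.
    band : (float, float)
        Passband in Hz.
    node_labels : list of str, optional
        Region names; defaults to ``roi_0 .. roi_{n-1}``.
    """

    signals: np.ndarray
    fs: float
    band: tuple[float, float]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (nodes x samples) array")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.fs <= 2 * self.band[1]:
            raise ValueError(
                f"sampling rate {self.fs} Hz violates Nyquist for band {self.band}"
            )
        if not self.node_labels:
            self.node_labels = [f"roi_{i}" for i in range(self.signals.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per node."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout over a sample axis.

    Windows are half-open sample ranges ``[start, start + window_len)``,
    0-based, advancing by ``step`` samples.
    """

    window_len: int
    step: int
    n_windows: int

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step

    def window(self, j: int) -> tuple[int, int]:
        start = j * self.step
        return start, start + self.window_len


def bandpass_filter(
    signals: np.ndarray,
    fs: float,
    band: tuple[float, float],
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass filter applied along the last axis.

    The default filter order is chosen so the impulse response spans about
    three cycles of the band's lower edge, a common rule of thumb that keeps
    the transition bands narrow relative to the passband.
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} outside (0, fs/2) for fs={fs}")
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if numtaps is None:
        numtaps = int(3 * fs / low) | 1  # odd length
    numtaps = min(numtaps | 1, (x.shape[-1] // 3) * 2 - 1)
    taps = sp_signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    return sp_signal.filtfilt(taps, [1.0], x, axis=-1)


def roi_representative_signal(
    voxel_matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse voxel time series of one ROI into a representative signal.

    Each voxel is weighted by its total pairwise association (absolute
    Pearson correlation) with the other voxels of the ROI, so voxels that
    covary with the local population dominate and outliers are attenuated.
    The association-strength vector is normalized to sum to one and the
    representative signal is the weighted sum of the voxel series.

    Parameters
    ----------
    voxel_matrix : ndarray, shape (n_voxels, n_samples)

    Returns
    -------
    representative : ndarray, shape (n_samples,)
    weights : ndarray, shape (n_voxels,)
        Nonnegative, summing to 1.
    """
    X = np.atleast_2d(np.asarray(voxel_matrix, dtype=float))
    n_vox = X.shape[0]
    if n_vox == 1:
        return X[0].copy(), np.array([1.0])

    sd = X.std(axis=1)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            "constant voxel series detected; assigned zero weight", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.abs(np.nan_to_num(C, nan=0.0))
    np.fill_diagonal(C, 0.0)
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    strength = C.sum(axis=0)
    total = strength.sum()
    if total == 0:
        # no informative associations at all: fall back to the plain mean
        weights = np.full(n_vox, 1.0 / n_vox)
    else:
        weights = strength / total
    return weights @ X, weights


def analytic_phase(ts: ROITimeseries | np.ndarray) -> PhaseSeries:
    """Instantaneous phase of each channel via the Hilbert transform.

    The input is assumed band-limited; for broadband input the phase is not
    physically interpretable. Raises on any all-zero channel, whose phase is
    undefined.
    """
    x = ts.signals if isinstance(ts, ROITimeseries) else np.atleast_2d(ts)
    if np.any(np.all(x == 0, axis=-1)):
        raise ValueError("all-zero channel: instantaneous phase undefined")
    analytic = sp_signal.hilbert(x, axis=-1)
    return PhaseSeries(phases=np.angle(analytic))


def iplv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Imaginary phase-locking value between two phase sequences.

    Returns ``|Im(sum_t exp(i(phi_a - phi_b)))| / N`` in [0, 1]. Zero for
    identical (or zero-lag locked) sequences; ``|sin(d)|`` for a constant
    lag ``d``.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase sequences must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sin(a - b))))


def make_window_plan(
    n_samples: int, fs: float, window_s: float, step_s: float
) -> WindowPlan:
    """Lay out sliding windows of ``window_s`` seconds every ``step_s`` seconds."""
    if step_s <= 0:
        raise ValueError("step must be positive")
    window_len = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if window_len < 2:
        raise ValueError("window shorter than 2 samples")
    if step < 1:
        raise ValueError("step shorter than 1 sample")
    if window_len > n_samples:
        raise ValueError(
            f"window of {window_len} samples exceeds signal length {n_samples}"
        )
    n_windows = (n_samples - window_len) // step + 1
    return WindowPlan(window_len=window_len, step=step, n_windows=n_windows)


def compute_dfcg(
    ts: ROITimeseries | PhaseSeries, plan: WindowPlan
) -> np.ndarray:
    """Dynamic functional connectivity tensor of windowed iPLV graphs.

    Phases are computed once on the full-length signal and sliced per
    window, which avoids per-window Hilbert edge artifacts. Returns an
    array of shape ``(n_windows, n_nodes, n_nodes)``; each slice is
    symmetric with zero diagonal and entries in [0, 1].
    """
    if isinstance(ts, PhaseSeries):
        phases = ts.phases
    else:
        phases = analytic_phase(ts).phases
    n_nodes = phases.shape[0]
    tensor = np.empty((plan.n_windows, n_nodes, n_nodes))
    Z = np.exp(1j * phases)
    for j in range(plan.n_windows):
        lo, hi = plan.window(j)
        Zw = Z[:, lo:hi]
        # iPLV_ab = |Im(<e^{i phi_a} e^{-i phi_b}>)|
        C = (Zw @ Zw.conj().T) / Zw.shape[1]
        G = np.abs(C.imag)
        np.fill_diagonal(G, 0.0)
        tensor[j] = G
    return tensor
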