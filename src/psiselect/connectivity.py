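"""Instantaneous phase, pairwise phase synchronization, and binary networks.

The phase synchronization index (PSI) between two band-limited signals is
the modulus of the time-averaged complex phase difference

    PSI = | < exp(j (phi_x(t) - phi_y(t))) > |

with instantaneous phases taken from the discrete analytic signal (Hilbert
transform).  PSI is 1 under perfect phase locking and near 0 for
independent signals; it depends only on phases, never on amplitudes.  A
functional network is obtained by thresholding the symmetric PSI matrix:
an edge exists where PSI strictly exceeds tau (default 0.3).

An optional phase-lag index (PLI) mode — the modulus of the time-averaged
*sign* of the phase difference — is provided as well; PLI discards zero-lag
coupling and is therefore insensitive to volume conduction, a property PSI
as defined above does not have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocessing import BandLimitedEpoch

__all__ = [
    "AnalyticSignal",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "analytic_phase",
    "psi",
    "pli",
    "connectivity_matrix",
    "binarize",
]

DEFAULT_TAU = 0.3


@dataclass
class AnalyticSignal:
    """Discrete analytic signal: source x, Hilbert pair x_h, amplitude A and
    wrapped phase phi with ``A**2 == x**2 + x_h**2``."""

    x: np.ndarray
    x_h: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise synchrony matrix with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    band: str | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("connectivity entries must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected unweighted adjacency matrix plus the threshold that made it."""

    adjacency: np.ndarray
    tau: float = DEFAULT_TAU
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        a = a.astype(int)
        if not np.isin(a, [0, 1]).all():
            raise ValueError("adjacency entries must be 0 or 1")
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def analytic_phase(x: np.ndarray) -> AnalyticSignal:
    """Analytic signal of a real series via the frequency-domain Hilbert pair.

    The phase is ``arctan2(x_h, x)`` in (-pi, pi].  A constant input is a
    documented degenerate case: its analytic amplitude is 0 and the phase is
    defined as 0 everywhere.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("analytic_phase expects a 1-D series")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0.0:
        z = np.zeros_like(x)
        return AnalyticSignal(x=x, x_h=z, amplitude=z, phase=z)
    z = hilbert(x - x.mean())
    return AnalyticSignal(
        x=x, x_h=z.imag, amplitude=np.abs(z), phase=np.angle(z)
    )


def _phases(samples: np.ndarray) -> np.ndarray:
    """Row-wise instantaneous phases of a channels x time matrix."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    centered = samples - samples.mean(axis=1, keepdims=True)
    z = hilbert(centered, axis=1)
    phase = np.angle(z)
    flat = np.ptp(samples, axis=1) == 0.0
    phase[flat] = 0.0
    return phase


def psi(x: np.ndarray, y: np.ndarray) -> float:
    """Phase synchronization index of two equal-length real series (1:1
    frequency locking)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("psi requires equal-length signals")
    dphi = analytic_phase(x).phase - analytic_phase(y).phase
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-lag index: |mean sign(wrapped phase difference)|.

    Zero-lag (and anti-phase) coupling contributes nothing, so PLI is robust
    to volume conduction at the price of missing genuine zero-lag synchrony.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pli requires equal-length signals")
    dphi = analytic_phase(x).phase - analytic_phase(y).phase
    wrapped = np.angle(np.exp(1j * dphi))
    return float(np.abs(np.mean(np.sign(wrapped))))


def connectivity_matrix(
    epoch: BandLimitedEpoch | np.ndarray,
    *,
    method: str = "psi",
) -> ConnectivityMatrix:
    """All-pairs synchrony of one band-limited epoch.

    Entry (i, j) equals ``psi(channel_i, channel_j)`` (or PLI under
    ``method="pli"``); the matrix is symmetric with zero diagonal.  Computed
    in one vectorized pass over the channel phase matrix.
    """
    if isinstance(epoch, BandLimitedEpoch):
        samples, band, names = epoch.samples, epoch.band, epoch.channel_names
    else:
        samples, band, names = np.asarray(epoch, dtype=float), None, None
    samples = np.atleast_2d(samples)
    n, t = samples.shape
    if n < 2:
        raise ValueError("need at least 2 channels")
    phase = _phases(samples)
    if method == "psi":
        z = np.exp(1j * phase)
        m = np.abs(z @ z.conj().T) / t
    elif method == "pli":
        m = np.empty((n, n))
        for i in range(n):
            d = phase[i] - phase[i:]
            m[i, i:] = np.abs(np.mean(np.sign(np.angle(np.exp(1j * d))), axis=1))
            m[i:, i] = m[i, i:]
    else:
        raise ValueError(f"unknown method {method!r}")
    m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(
        m, band=band, channel_names=list(names) if names is not None else None
    )


def binarize(cm: ConnectivityMatrix, tau: float = DEFAULT_TAU) -> BinaryNetwork:
    """Threshold a connectivity matrix into an undirected binary network.

    An edge is kept only where the synchrony value *strictly* exceeds tau.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must lie in [0, 1)")
    adj = (cm.values > tau).astype(int)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, tau=tau, channel_names=cm.channel_names)
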