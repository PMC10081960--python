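"""Spiral GRAPPA along the partition-encoding direction.

Each k-space point of a skipped partition is predicted as a linear
combination of a 2 x (2v+1) x C source neighborhood: the same readout
window on the two flanking acquired partitions, across all coils.  Because
spiral samples are not equally spaced, the kernel is calibrated separately
for every readout location i (unlike Cartesian GRAPPA, where one kernel is
shared by all locations).  Weights are fitted by least squares on the fully
sampled ACS partitions, pooling calibration instances across all time
frames and all stride-1 ACS offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .synthdata import MRFKspace

__all__ = ["GrappaKernelSet", "calibrate_grappa", "apply_grappa", "source_vector_length"]


def source_vector_length(v: int, n_coils: int) -> int:
    """Length of one GRAPPA source vector: 2 partitions x (2v+1) points x C coils."""
    return 2 * (2 * v + 1) * n_coils


@dataclass
class GrappaKernelSet:
    """Per-location GRAPPA weights.

    ``weights`` has shape ``(Q, D, (R-1)*C)`` with ``D = 2*(2v+1)*C``; the
    column for (offset m, coil c) is ``weights[i, :, (m-1)*C + c]``.  Source
    entries are ordered (flanking partition, readout offset -v..+v, coil),
    flattened in that order.
    """

    weights: np.ndarray
    v: int
    R: int
    n_coils: int
    ridge: float

    def __post_init__(self):
        D = source_vector_length(self.v, self.n_coils)
        if self.weights.shape[1:] != (D, (self.R - 1) * self.n_coils):
            raise ValueError("kernel weight array has inconsistent shape")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")

    @property
    def n_readout(self) -> int:
        return self.weights.shape[0]

    def kernel(self, i: int, m: int, c: int) -> np.ndarray:
        """Weight vector predicting (readout i, offset m, coil c)."""
        if not (1 <= m <= self.R - 1):
            raise ValueError(f"offset m must lie in 1..{self.R - 1}")
        return self.weights[i, :, (m - 1) * self.n_coils + c]


def _source_windows(data: np.ndarray, v: int) -> np.ndarray:
    """Sliding readout windows with zero padding.

    ``data`` is ``(..., Q, C)``; returns ``(..., Q, 2v+1, C)`` where entry
    ``[..., i, j, c]`` is ``data[..., i - v + j, c]`` (zero outside range).
    """
    pad = [(0, 0)] * data.ndim
    pad[-2] = (v, v)
    padded = np.pad(data, pad)
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * v + 1, axis=-2)
    # sliding_window_view appends the window axis; reorder to (..., Q, 2v+1, C)
    return np.moveaxis(win, -1, -2)


def calibrate_grappa(
    acs: np.ndarray, R: int, v: int = 1, ridge: float = 1e-6
) -> GrappaKernelSet:
    """Least-squares calibration of location-specific kernels on ACS data.

    Parameters
    ----------
    acs:
        Complex ``(T, P_acs, Q, C)`` fully sampled central partitions.
    R:
        Partition acceleration factor; sources are partitions p and p+R,
        targets the R-1 partitions in between, pooled over all stride-1
        starting offsets p and all time frames.
    v:
        Readout half-width of the kernel (2v+1 points per partition);
        readout edges use zero-padded neighborhoods.
    ridge:
        Relative Tikhonov factor: the normal matrix receives
        ``ridge * mean(diag)`` on its diagonal.  ``ridge=0`` is plain least
        squares (minimum-norm if under-determined, with a warning).

    Calibration instances are pooled across all time frames passed in;
    per-frame kernels are obtained by calling with a single-frame slice
    ``acs[t:t+1]`` (pooling is the default since calibration data per
    kernel is scarce).
    """
    acs = np.asarray(acs)
    if acs.ndim != 4:
        raise ValueError("acs must be (T, P_acs, Q, C)")
    T, P_acs, Q, C = acs.shape
    if P_acs < R + 1:
        raise ValueError(f"need P_acs >= R+1 = {R + 1}, got {P_acs}")
    if Q < 2 * v + 1:
        raise ValueError("readout too short for kernel half-width v")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")

    D = source_vector_length(v, C)
    n_pos = P_acs - R
    win = _source_windows(acs, v)  # (T, P_acs, Q, 2v+1, C)
    p0 = np.arange(n_pos)
    # (T, n_pos, Q, 2, 2v+1, C) -> flatten source axes
    src = np.stack([win[:, p0], win[:, p0 + R]], axis=3)
    src = src.reshape(T, n_pos, Q, D)
    offs = np.arange(1, R)
    tgt = acs[:, p0[:, None] + offs[None, :]]  # (T, n_pos, R-1, Q, C)
    tgt = np.moveaxis(tgt, 3, 2).reshape(T, n_pos, Q, (R - 1) * C)

    n_inst = T * n_pos
    A_all = src.reshape(n_inst, Q, D)
    B_all = tgt.reshape(n_inst, Q, (R - 1) * C)
    if ridge == 0 and n_inst < D:
        warnings.warn(
            f"GRAPPA calibration under-determined ({n_inst} instances for {D} "
            "unknowns) with ridge=0; returning minimum-norm solutions",
            RuntimeWarning,
        )

    weights = np.empty((Q, D, (R - 1) * C), dtype=complex)
    for i in range(Q):
        A = A_all[:, i]
        B = B_all[:, i]
        if ridge == 0:
            weights[i] = np.linalg.lstsq(A, B, rcond=None)[0]
            continue
        G = A.conj().T @ A
        lam = ridge * (np.real(np.trace(G)) / D)
        G[np.diag_indices(D)] += lam
        rhs = A.conj().T @ B
        try:
            with warnings.catch_warnings():
                # ridge keeps the system solvable; scipy still warns when the
                # unregularized part is near-singular
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                weights[i] = scipy.linalg.solve(G, rhs, assume_a="pos")
        except np.linalg.LinAlgError:
            weights[i] = np.linalg.lstsq(A, B, rcond=None)[0]
    return GrappaKernelSet(weights=weights, v=v, R=R, n_coils=C, ridge=ridge)


def _flanking_pairs(mask: np.ndarray, R: int) -> dict[tuple[int, int], list[int]]:
    """Group skipped partitions by the acquired (low, high) pair predicting them.

    Each skipped partition p lies between the enclosing multiples of R,
    ``lo = R * floor(p / R)`` and ``lo + R``, both on the regular acquired
    grid, with kernel offset ``m = p - lo``.  Trailing partitions beyond
    the last multiple of R use the wrapped pair (lo, 0): the partition
    axis is a DFT axis, so the shift-invariant kernel relation continues
    periodically across the kz boundary.
    """
    P = mask.shape[0]
    groups: dict[tuple[int, int], list[int]] = {}
    for p in np.where(~mask)[0]:
        lo = (p // R) * R
        hi = (lo + R) % P
        if not (mask[lo] and mask[hi]):
            raise ValueError(f"no acquired flanking pair available for partition {p}")
        groups.setdefault((lo, int(hi)), []).append(int(p))
    return groups


def apply_grappa(kernels: GrappaKernelSet, ks: MRFKspace) -> MRFKspace:
    """Predict every skipped partition from its flanking acquired pair.

    Acquired partitions pass through unchanged (data consistency); the
    returned object has all partitions filled and ``acquired_mask`` all
    True.
    """
    T, P, Q, C = ks.data.shape
    if Q != kernels.n_readout or C != kernels.n_coils:
        raise ValueError("kernel set does not match data dimensions")
    R, v = kernels.R, kernels.v
    out = ks.copy()
    groups = _flanking_pairs(ks.acquired_mask, R)
    for (lo, hi), missing in groups.items():
        pair = np.stack([ks.data[:, lo], ks.data[:, hi]], axis=1)  # (T, 2, Q, C)
        win = _source_windows(pair, v)  # (T, 2, Q, 2v+1, C)
        src = np.moveaxis(win, 1, 2).reshape(T, Q, -1)  # (T, Q, D)
        pred = np.einsum("tqd,qdk->tqk", src, kernels.weights)
        pred = pred.reshape(T, Q, R - 1, C)
        for p in missing:
            m = p - lo
            out.data[:, p] = pred[:, :, m - 1].astype(out.data.dtype)
    out.acquired_mask = np.ones(P, dtype=bool)
    return out
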