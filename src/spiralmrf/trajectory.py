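"""Spiral readout trajectories and partition-direction sampling schedules.

A stack-of-spirals 3D acquisition samples a 2D spiral arm in-plane at every
Cartesian partition (kz) position.  Frames of an MRF time series rotate the
arm by the golden angle so that successive frames cover complementary
in-plane k-space.  Acceleration is applied along the partition-encoding
direction: only every R-th partition is acquired, plus a centered block of
fully sampled auto-calibration (ACS) partitions used to calibrate or train
the k-space interpolators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpiralTrajectory",
    "SamplingSchedule",
    "GOLDEN_ANGLE",
    "make_spiral",
    "make_schedule",
    "effective_acceleration",
    "realized_acceleration",
    "temporal_acceleration",
    "combined_acceleration",
    "round_half_away",
    "acs_index_range",
]

#: Golden-angle increment in radians, 2*pi*(1 - 1/phi) ~ 222.49 deg
#: (equivalently -137.51 deg modulo 2*pi).
GOLDEN_ANGLE = 2.0 * math.pi * (1.0 - 2.0 / (1.0 + math.sqrt(5.0)))


@dataclass(frozen=True)
class SpiralTrajectory:
    """A single spiral interleaf.

    Attributes
    ----------
    coords:
        ``(Q, 2)`` k-space coordinates in cycles/FOV, normalized so the
        maximum supported radius is just below 0.5 (the in-plane Nyquist
        limit for a unit pixel grid).
    n_interleaves_full:
        Number of rotated copies of this arm required to tile the plane at
        the Nyquist rate.  A single-arm acquisition therefore carries an
        in-plane undersampling factor of ``n_interleaves_full``.
    k_max:
        Maximum spiral radius in cycles/FOV.
    turns:
        Number of revolutions of the arm from center to edge.
    """

    coords: np.ndarray
    n_interleaves_full: int
    k_max: float
    turns: float

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def rotated(self, angle: float) -> np.ndarray:
        """Coordinates of the arm rotated by ``angle`` radians."""
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return self.coords @ rot.T

    def full_coords(self) -> np.ndarray:
        """All ``n_interleaves_full`` rotated arms concatenated.

        Used for fully sampled in-plane reference reconstructions; a single
        MRF frame acquires only one arm.
        """
        arms = [
            self.rotated(2.0 * math.pi * j / self.n_interleaves_full)
            for j in range(self.n_interleaves_full)
        ]
        return np.concatenate(arms, axis=0)


@dataclass(frozen=True)
class SamplingSchedule:
    """Partition-direction sampling pattern and per-frame arm angles.

    ``acquired_indices`` is the union of the regular every-R-th grid
    (starting at partition 0) and the centered ACS block.
    """

    n_partitions: int
    R: int
    acs_indices: np.ndarray
    acquired_indices: np.ndarray
    frame_angles: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frame_angles.shape[0]

    @property
    def acquired_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_partitions, dtype=bool)
        mask[self.acquired_indices] = True
        return mask

    @property
    def skipped_indices(self) -> np.ndarray:
        return np.where(~self.acquired_mask)[0]


def make_spiral(
    Q: int,
    n_interleaves_full: int = 48,
    k_max: float = 0.5,
    turns: float = 4.0,
) -> SpiralTrajectory:
    """Build a uniform-density Archimedean spiral arm.

    The arm is parameterized as ``k(tau) = k_max * tau * exp(i*2*pi*turns*tau)``
    with ``tau`` sampled uniformly on [0, 1], so the radius grows linearly with
    arc parameter and the final point sits exactly at ``k_max``.  ``turns`` and
    ``n_interleaves_full`` jointly set the radial gap between successive
    windings of the interleaved set, ``k_max / (turns * n_interleaves_full)``;
    choosing ``turns * n_interleaves_full >= k_max * 2 * M`` tiles an M-pixel
    plane at Nyquist when all arms are played out (documentation contract,
    not asserted numerically).

    Parameters
    ----------
    Q:
        Number of readout points along the arm (>= 2).
    n_interleaves_full:
        Arms needed for full in-plane sampling (>= 1).
    k_max:
        Edge of sampled k-space in cycles/FOV (> 0).
    turns:
        Revolutions from center to edge (> 0).
    """
    if Q < 2:
        raise ValueError(f"Q must be >= 2, got {Q}")
    if n_interleaves_full < 1:
        raise ValueError(f"n_interleaves_full must be >= 1, got {n_interleaves_full}")
    if k_max <= 0:
        raise ValueError(f"k_max must be positive, got {k_max}")
    if turns <= 0:
        raise ValueError(f"turns must be positive, got {turns}")
    tau = np.linspace(0.0, 1.0, Q)
    radius = k_max * tau
    phase = 2.0 * math.pi * turns * tau
    coords = np.stack([radius * np.cos(phase), radius * np.sin(phase)], axis=1)
    return SpiralTrajectory(
        coords=coords,
        n_interleaves_full=int(n_interleaves_full),
        k_max=float(k_max),
        turns=float(turns),
    )


def acs_index_range(n_partitions: int, n_acs: int) -> tuple[int, int]:
    """Half-open index range of the centered ACS block.

    The block is centered on the partition-direction k-space center
    ``n_partitions // 2``; for even ``n_acs`` the extra index falls on the
    high side: ``floor(P/2) - floor(n/2) .. floor(P/2) + ceil(n/2) - 1``.
    """
    center = n_partitions // 2
    lo = center - n_acs // 2
    hi = lo + n_acs
    return lo, hi


def make_schedule(
    n_partitions: int,
    R: int,
    n_acs: int,
    T: int,
    golden_angle: float = GOLDEN_ANGLE,
    angle0: float = 0.0,
) -> SamplingSchedule:
    """Build a partition sampling schedule with a centered ACS block.

    Acquired partitions are every R-th partition starting at index 0, plus
    ``n_acs`` contiguous partitions centered on the kz center.  Frame angles
    start at ``angle0`` and advance by ``golden_angle`` per frame.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if not (1 <= R <= n_partitions):
        raise ValueError(f"R must satisfy 1 <= R <= {n_partitions}, got {R}")
    if not (0 <= n_acs <= n_partitions):
        raise ValueError(f"n_acs must satisfy 0 <= n_acs <= {n_partitions}, got {n_acs}")
    if T < 1:
        raise ValueError("T must be >= 1")
    lo, hi = acs_index_range(n_partitions, n_acs)
    acs = np.arange(lo, hi, dtype=np.int64)
    regular = np.arange(0, n_partitions, R, dtype=np.int64)
    acquired = np.union1d(regular, acs)
    angles = angle0 + golden_angle * np.arange(T, dtype=float)
    return SamplingSchedule(
        n_partitions=int(n_partitions),
        R=int(R),
        acs_indices=acs,
        acquired_indices=acquired,
        frame_angles=angles,
    )


def effective_acceleration(n_partitions: int, R: int, n_acs: int) -> float:
    """Idealized effective acceleration along the partition direction.

    Counts the regular grid as ``N / R`` partitions and charges each ACS
    partition the extra ``(R - 1) / R`` it would not otherwise have been
    acquired:

        N * R / (N + n_acs * (R - 1))

    The realized acquired-set count can differ by +-1 when R does not divide
    N; see :func:`realized_acceleration` for the exact set-based figure.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if n_acs < 0 or n_acs > n_partitions:
        raise ValueError("n_acs out of range")
    return n_partitions * R / (n_partitions + n_acs * (R - 1))


def realized_acceleration(n_partitions: int, R: int, n_acs: int) -> float:
    """Exact acceleration ``N / |acquired set|`` for the realized schedule."""
    sched = make_schedule(n_partitions, R, n_acs, T=1)
    return n_partitions / sched.acquired_indices.size


def temporal_acceleration(n_frames_total: int, n_frames_used: int) -> float:
    """Acceleration from truncating the MRF time series (e.g. 768 -> 192)."""
    if n_frames_used < 1 or n_frames_used > n_frames_total:
        raise ValueError("n_frames_used must lie in 1..n_frames_total")
    return n_frames_total / n_frames_used


def combined_acceleration(R: int, temporal: float) -> float:
    """Total acceleration when partition and temporal acceleration combine."""
    return R * temporal


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed factors)."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
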