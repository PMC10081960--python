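"""Synthetic stack-of-spirals MRF acquisition.

Generates everything the interpolators need to be exercised end to end:

* a digital brain phantom (concentric ellipsoids of WM / GM / CSF with
  conventional 3T relaxation values),
* smooth complex coil sensitivities (low-order polynomial fields),
* a fingerprint time course per tissue driven by a flip-angle train with an
  inversion pulse and T2-preparation modules between segments,
* the forward model: coil-weighted images, a Cartesian DFT along the
  partition (kz) direction, an in-plane NDFT on the golden-angle-rotated
  spiral arm, and additive complex Gaussian noise,
* retrospective undersampling along the partition direction.

The fingerprint model is a deliberately simple gradient-spoiled recursion
(see :func:`simulate_fingerprint`), not a Bloch/EPG simulation; the k-space
interpolators under study are agnostic to fingerprint fidelity, which only
needs to make distinct tissues produce distinct, matchable time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import SamplingSchedule, SpiralTrajectory
from .nufft import DirectNUFFT

__all__ = [
    "DigitalPhantom",
    "CoilSensitivities",
    "AcquisitionSchedule",
    "MRFKspace",
    "default_acquisition",
    "simulate_fingerprint",
    "make_phantom",
    "forward_sample",
    "undersample",
    "DEFAULT_TISSUES",
]

# Conventional 3T brain values (ms, ms, a.u.) per label: 1=WM, 2=GM, 3=CSF.
DEFAULT_TISSUES = {
    1: (800.0, 70.0, 0.7),
    2: (1300.0, 90.0, 0.8),
    3: (4000.0, 1800.0, 1.0),
}


@dataclass(frozen=True)
class DigitalPhantom:
    """Labelled anatomy with per-label T1/T2/PD and partial-volume maps.

    ``label_map`` is ``(M, M, P)`` with 0 = background and labels 1..3 for
    WM, GM, CSF; ``t1_ms``/``t2_ms``/``pd`` are length-4 arrays indexed by
    label (entry 0 unused).  ``coverage`` is ``(4, M, M, P)``: the
    fraction of each voxel occupied by each label, estimated on a
    supersampled grid — real objects are not pixel-crisp, and the forward
    model uses these fractional indicators so tissue interfaces carry
    sub-voxel partial-volume mixing.  ``label_map`` is the per-voxel
    dominant label.  ``pd_texture`` is an optional smooth multiplicative
    proton-density modulation standing in for within-tissue fine structure
    (real anatomy carries signal at all spatial frequencies; homogeneous
    shells do not).
    """

    label_map: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    coverage: np.ndarray | None = None
    pd_texture: np.ndarray | None = None

    def __post_init__(self):
        labels = np.unique(self.label_map)
        if labels.min() < 0 or labels.max() > 3:
            raise ValueError("labels must lie in {0..3}")
        for lab in range(1, 4):
            if not (self.t1_ms[lab] > self.t2_ms[lab] > 0):
                raise ValueError(f"label {lab}: need T1 > T2 > 0")
        if self.coverage is not None and self.coverage.shape != (4,) + self.label_map.shape:
            raise ValueError("coverage must have shape (4,) + label_map.shape")
        if self.pd_texture is not None and self.pd_texture.shape != self.label_map.shape:
            raise ValueError("pd_texture must match label_map shape")

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def label_fractions(self) -> np.ndarray:
        """``(4, M, M, P)`` per-label voxel fractions (crisp if no coverage)."""
        if self.coverage is not None:
            return self.coverage
        return np.stack([(self.label_map == lab).astype(float) for lab in range(4)])

    def pd_volume(self) -> np.ndarray:
        frac = self.label_fractions()
        vol = np.tensordot(self.pd, frac, axes=(0, 0))
        if self.pd_texture is not None:
            vol = vol * self.pd_texture
        return vol


@dataclass(frozen=True)
class CoilSensitivities:
    """``(C, M, M, P)`` complex sensitivity maps, smooth in space."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def sos(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Flip-angle train and preparation modules of the MRF sequence.

    ``T = n_segments * trs_per_segment`` TRs are played out; an inversion
    pulse (if enabled) precedes the train, and at each segment boundary a
    longitudinal recovery gap of ``segment_delay_ms`` is followed by a
    T2-preparation module whose effective echo time cycles through
    ``t2prep_te_ms``.
    """

    flip_deg: np.ndarray
    tr_ms: float
    te_ms: float
    n_segments: int
    trs_per_segment: int
    t2prep_te_ms: tuple[float, ...]
    inversion: bool
    segment_delay_ms: float = 0.0

    def __post_init__(self):
        if self.flip_deg.shape[0] != self.n_segments * self.trs_per_segment:
            raise ValueError("T must equal n_segments * trs_per_segment")

    @property
    def n_frames(self) -> int:
        return self.flip_deg.shape[0]


def default_acquisition(
    T: int = 48,
    n_segments: int = 4,
    tr_ms: float = 9.2,
    te_ms: float = 1.3,
    flip_lo_deg: float = 5.0,
    flip_hi_deg: float = 12.0,
    t2prep_te_ms: tuple[float, ...] = (50.0, 90.0),
    inversion: bool = True,
    segment_delay_ms: float = 300.0,
) -> AcquisitionSchedule:
    """Desk-scale acquisition: sinusoidal flip ramps within each segment.

    The per-segment half-sine ramp between ``flip_lo_deg`` and
    ``flip_hi_deg`` stands in for a pseudo-randomized train while staying
    deterministic and inside the stated flip-angle band.
    """
    if T % n_segments != 0:
        raise ValueError("T must be divisible by n_segments")
    trs = T // n_segments
    j = np.arange(trs)
    ramp = flip_lo_deg + (flip_hi_deg - flip_lo_deg) * np.sin(np.pi * (j + 0.5) / trs) ** 2
    return AcquisitionSchedule(
        flip_deg=np.tile(ramp, n_segments),
        tr_ms=tr_ms,
        te_ms=te_ms,
        n_segments=n_segments,
        trs_per_segment=trs,
        t2prep_te_ms=tuple(t2prep_te_ms),
        inversion=inversion,
        segment_delay_ms=segment_delay_ms,
    )


@dataclass
class MRFKspace:
    """Multi-coil spiral k-space, the pipeline's central exchange object.

    ``data`` is complex ``(T, P, Q, C)``; partitions where
    ``acquired_mask`` is False hold zeros.  ``scale`` is the normalization
    factor (max magnitude over the ACS partitions) used by the learned
    interpolators.
    """

    data: np.ndarray
    trajectory: SpiralTrajectory
    schedule: SamplingSchedule
    acquired_mask: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        T, P, Q, _ = self.data.shape
        if P != self.schedule.n_partitions:
            raise ValueError("partition count mismatch between data and schedule")
        if T != self.schedule.n_frames:
            raise ValueError("frame count mismatch between data and schedule")
        if Q % self.trajectory.n_points != 0:
            raise ValueError("readout length is not a multiple of the arm length")
        if self.acquired_mask.shape != (P,):
            raise ValueError("acquired_mask must have one entry per partition")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def copy(self) -> "MRFKspace":
        return replace(self, data=self.data.copy(), acquired_mask=self.acquired_mask.copy())


def simulate_fingerprint(t1_ms, t2_ms, acq: AcquisitionSchedule) -> np.ndarray:
    """Stand-in fingerprint recursion for one (or an array of) tissue(s).

    Starting from ``Mz = -1`` when the inversion pulse is enabled (else 1),
    each TR emits ``s_t = Mz * sin(alpha_t) * exp(-TE/T2)``, then applies
    gradient-spoiled saturation ``Mz <- Mz * cos(alpha_t)`` and T1 recovery
    ``Mz <- 1 + (Mz - 1) * exp(-TR/T1)``.  At each segment boundary the
    longitudinal recovery gap is applied, followed by T2-preparation
    ``Mz <- Mz * exp(-TE_p/T2)`` with TE_p cycling through the schedule's
    list.  This is a gradient-spoiled approximation, not a Bloch/EPG
    simulation; see the methods note.

    Accepts scalars or broadcastable arrays for ``t1_ms``/``t2_ms`` and
    returns a complex array of shape ``(T,) + broadcast_shape``.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    t1, t2 = np.broadcast_arrays(t1, t2)
    shape = t1.shape
    e_tr = np.exp(-acq.tr_ms / t1)
    e_te = np.exp(-acq.te_ms / t2)
    e_gap = np.exp(-acq.segment_delay_ms / t1)
    mz = np.full(shape, -1.0 if acq.inversion else 1.0)
    alpha = np.deg2rad(acq.flip_deg)
    out = np.empty((acq.n_frames,) + shape, dtype=complex)
    preps = acq.t2prep_te_ms
    for t in range(acq.n_frames):
        if t > 0 and t % acq.trs_per_segment == 0:
            mz = 1.0 + (mz - 1.0) * e_gap
            if preps:
                te_p = preps[(t // acq.trs_per_segment - 1) % len(preps)]
                mz = mz * np.exp(-te_p / t2)
        out[t] = mz * np.sin(alpha[t]) * e_te
        mz = mz * np.cos(alpha[t])
        mz = 1.0 + (mz - 1.0) * e_tr
    return out


def frame_image(phantom: DigitalPhantom, acq: AcquisitionSchedule, frame: int = 0) -> np.ndarray:
    """Noise-free complex image of one MRF frame (coil weighting excluded)."""
    frac = phantom.label_fractions()
    img = np.zeros(phantom.label_map.shape, dtype=complex)
    for lab in (1, 2, 3):
        if np.any(frac[lab] > 0):
            fp = simulate_fingerprint(phantom.t1_ms[lab], phantom.t2_ms[lab], acq)[frame]
            img += phantom.pd[lab] * fp * frac[lab]
    if phantom.pd_texture is not None:
        img = img * phantom.pd_texture
    return img


def _labels_at(M: int, P: int, semi: tuple[float, float, float], offset=(0.0, 0.0, 0.0)):
    """Concentric-shell labels evaluated at (optionally shifted) voxel centers."""
    x = (np.arange(M) - M / 2.0 + 0.5 + offset[0]) / (M / 2.0)
    y = (np.arange(M) - M / 2.0 + 0.5 + offset[1]) / (M / 2.0)
    z = (np.arange(P) - P / 2.0 + 0.5 + offset[2]) / (P / 2.0)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    rho = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2
    lab = np.zeros((M, M, P), dtype=np.int8)
    lab[rho <= 1.0] = 3
    lab[rho <= 0.80] = 2
    lab[rho <= 0.52] = 1
    return lab


def make_phantom(
    M: int,
    P: int,
    C: int,
    seed: int = 0,
    tissues: dict | None = None,
    circular: bool = False,
    uniform_coil: bool = False,
    texture: float = 0.35,
) -> tuple[DigitalPhantom, CoilSensitivities]:
    """Concentric-ellipsoid anatomy plus localized surface-coil maps.

    The outer shell is CSF, the middle shell GM, and the core WM; the
    in-plane axes are slightly unequal unless ``circular`` (useful for
    rotation-invariance checks).  Tissue boundaries carry 2x-supersampled
    partial-volume coverage, and ``texture`` sets the relative amplitude
    of a smooth seed-controlled proton-density modulation that stands in
    for within-tissue fine structure (0 disables it).  Coil sensitivities
    are Gaussian lobes on a ring around the object, staggered along z,
    globally scaled so the root-sum-of-squares is ~1 inside the object;
    ``uniform_coil`` replaces them with all-ones maps.  Deterministic
    given ``seed``.
    """
    if min(M, P, C) < 1:
        raise ValueError("M, P, C must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = dict(DEFAULT_TISSUES if tissues is None else tissues)

    ax, ay = (0.88, 0.88) if circular else (0.9, 0.78)
    semi = (ax, ay, 0.9)
    # partial-volume coverage from a 2x supersampled grid
    cov = np.zeros((4, M, M, P))
    offs = (-0.25, 0.25)
    for dx in offs:
        for dy in offs:
            for dz in offs:
                sub = _labels_at(M, P, semi, offset=(dx, dy, dz))
                for lab in range(4):
                    cov[lab] += sub == lab
    cov /= 8.0
    label = np.argmax(cov, axis=0).astype(np.int8)
    t1 = np.zeros(4)
    t2 = np.zeros(4)
    pd = np.zeros(4)
    for lab, (a, b, c) in tissues.items():
        t1[lab], t2[lab], pd[lab] = a, b, c
    texture_vol = None
    if texture > 0:
        from scipy.ndimage import gaussian_filter

        # correlation length ~1 voxel: real anatomy carries structure down to
        # the voxel scale, giving an edge/center partition-energy ratio of
        # ~1e-2..1e-3 as in high-resolution brain acquisitions
        field = gaussian_filter(rng.standard_normal((M, M, P)), sigma=(1.0, 1.0, 0.5))
        field /= field.std() if field.std() > 0 else 1.0
        texture_vol = np.clip(1.0 + texture * field, 0.2, 1.8)
    phantom = DigitalPhantom(
        label_map=label, t1_ms=t1, t2_ms=t2, pd=pd, coverage=cov, pd_texture=texture_vol
    )

    if uniform_coil:
        maps = np.ones((C, M, M, P), dtype=complex)
        return phantom, CoilSensitivities(maps=maps)

    # Localized surface-coil model: Gaussian magnitude lobes centered on a
    # ring around the object with centers spread along z (a receive array
    # needs sensitivity variation along the partition direction for
    # parallel imaging to be possible there), with a smooth linear phase.
    x = np.linspace(-1.0, 1.0, M)
    z = np.linspace(-1.0, 1.0, P)
    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    maps = np.empty((C, M, M, P), dtype=complex)
    ring_r = 1.1
    golden = 2.0 * np.pi * 0.38196601125
    for c in range(C):
        theta = golden * c + 0.25 * rng.random()
        cx, cy = ring_r * np.cos(theta), ring_r * np.sin(theta)
        cz = (-0.7 + 1.4 * c / (C - 1) if C > 1 else 0.0) + 0.1 * (rng.random() - 0.5)
        xyw = 0.45 * (1.0 + 0.1 * rng.random())
        zw = 0.20 * (1.0 + 0.1 * rng.random())
        d2 = ((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * xyw**2) + (Z - cz) ** 2 / (2.0 * zw**2)
        phase = (
            2.0 * np.pi * rng.random()
            + rng.normal(scale=0.8) * X
            + rng.normal(scale=0.8) * Y
            + rng.normal(scale=0.8) * Z
        )
        maps[c] = np.exp(-d2) * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[phantom.mask].mean()
    return phantom, CoilSensitivities(maps=maps)


def forward_sample(
    phantom: DigitalPhantom,
    coils: CoilSensitivities,
    traj: SpiralTrajectory,
    sched: SamplingSchedule,
    acq: AcquisitionSchedule,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_relative: bool = True,
    full_inplane: bool = False,
    dtype=np.complex64,
) -> MRFKspace:
    """Forward-sample the phantom onto the stack-of-spirals trajectory.

    Per frame, the per-voxel image is ``PD * fingerprint_t * coil map``; a
    centered discrete Fourier transform along the partition direction gives
    Cartesian kz, and the in-plane NDFT is evaluated at the arm rotated by
    the frame's golden angle (all arms when ``full_inplane``).  Complex
    Gaussian noise with std ``noise_sigma`` (a fraction of the noiseless
    peak magnitude when ``noise_relative``) is added i.i.d.  All partitions
    are sampled; undersampling is applied separately by :func:`undersample`.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    M, _, P = phantom.label_map.shape
    C = coils.n_coils
    if coils.maps.shape != (C, M, M, P):
        raise ValueError("coil maps do not match phantom shape")
    if P != sched.n_partitions:
        raise ValueError("schedule partition count does not match phantom")
    T = sched.n_frames
    if T != acq.n_frames:
        raise ValueError("sampling schedule and acquisition schedule disagree on T")

    # per-label PD-weighted fractional indicators and fingerprints
    frac = phantom.label_fractions()
    labels = [lab for lab in (1, 2, 3) if np.any(frac[lab] > 0)]
    weights = np.stack([frac[lab] * phantom.pd[lab] for lab in labels], axis=0)  # (L, M, M, P)
    if phantom.pd_texture is not None:
        weights = weights * phantom.pd_texture[None]
    fps = np.stack(
        [simulate_fingerprint(phantom.t1_ms[lab], phantom.t2_ms[lab], acq) for lab in labels],
        axis=1,
    )  # (T, L)

    # kz spectrum of each label indicator weighted by each coil, computed once:
    # kz_maps (L, C, M, M, P) would be large; instead transform coil-weighted
    # indicators label-by-label.
    def kz_transform(vol):
        return np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(vol, axes=-1), axis=-1), axes=-1
        )

    kz_label = np.empty((len(labels), C, M, M, P), dtype=complex)
    for li in range(len(labels)):
        kz_label[li] = kz_transform(weights[li][None] * coils.maps)

    Q_arm = traj.n_points
    coords0 = traj.full_coords() if full_inplane else traj.coords
    Q = coords0.shape[0]
    data = np.empty((T, P, Q, C), dtype=dtype)
    for t in range(T):
        # frame image spectrum in (x, y, kz): combine labels with frame weights
        frame_kz = np.tensordot(fps[t], kz_label, axes=(0, 0))  # (C, M, M, P)
        angle = sched.frame_angles[t]
        c_, s_ = np.cos(angle), np.sin(angle)
        coords = coords0 @ np.array([[c_, -s_], [s_, c_]]).T
        op = DirectNUFFT(coords, M, dtype=np.complex128)
        # (M, M, P*C) -> (Q, P, C)
        stacked = np.moveaxis(frame_kz, 0, -1).reshape(M, M, P * C)
        samp = op.forward(stacked).reshape(Q, P, C)
        data[t] = np.moveaxis(samp, 0, 1).astype(dtype)

    if noise_sigma > 0:
        sigma = noise_sigma * (np.abs(data).max() if noise_relative else 1.0)
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = (data + (sigma * noise)).astype(dtype)

    if sched.acs_indices.size:
        scale = float(np.abs(data[:, sched.acs_indices]).max())
    else:
        scale = float(np.abs(data).max())
    return MRFKspace(
        data=data,
        trajectory=traj,
        schedule=sched,
        acquired_mask=np.ones(P, dtype=bool),
        scale=scale if scale > 0 else 1.0,
    )


def undersample(ks: MRFKspace, sched: SamplingSchedule | None = None) -> MRFKspace:
    """Zero out partitions outside the schedule's acquired set.

    Acquired partitions are preserved bit-identically; the returned object
    carries the updated ``acquired_mask``.
    """
    sched = ks.schedule if sched is None else sched
    if sched.n_partitions != ks.data.shape[1]:
        raise ValueError("schedule partition count does not match data")
    out = ks.copy()
    mask = sched.acquired_mask
    out.data[:, ~mask] = 0
    out.acquired_mask = mask
    out.schedule = sched
    return out
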