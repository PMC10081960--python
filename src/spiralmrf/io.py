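"""On-disk formats: HDF5 k-space bundles, NIfTI maps, JSON metrics.

The bundle is self-describing: complex64 k-space, the spiral arm, the
sampling schedule and acquisition metadata travel together so every
pipeline stage can run from a single file.  All indices are 0-based; the
partition index increases with kz and the frame index with acquisition
time.  Floats are stored as 32-bit complex pairs; a save/load round trip
is bit-exact at that precision.
"""

from __future__ import annotations

import json
import math

import h5py
import numpy as np

from .grappa import GrappaKernelSet
from .recon import MetricReport, TissueMaps
from .synthdata import MRFKspace
from .trajectory import SamplingSchedule, SpiralTrajectory

__all__ = [
    "BUNDLE_VERSION",
    "BundleFormatError",
    "save_bundle",
    "load_bundle",
    "save_kernels",
    "load_kernels",
    "save_maps",
    "load_volume",
    "save_metrics",
]

BUNDLE_VERSION = "1"


class BundleFormatError(RuntimeError):
    """Raised for malformed, truncated or unsupported bundle files."""


def save_bundle(path, ks: MRFKspace, meta: dict | None = None) -> None:
    """Write an :class:`MRFKspace` to an HDF5 bundle."""
    meta = dict(meta or {})
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ks.data.astype(np.complex64))
        traj = f.create_group("traj")
        traj.create_dataset("coords", data=ks.trajectory.coords)
        traj.create_dataset("frame_angles", data=ks.schedule.frame_angles)
        traj.attrs["n_interleaves_full"] = ks.trajectory.n_interleaves_full
        traj.attrs["k_max"] = ks.trajectory.k_max
        traj.attrs["turns"] = ks.trajectory.turns
        sched = f.create_group("schedule")
        sched.attrs["R"] = ks.schedule.R
        sched.attrs["n_partitions"] = ks.schedule.n_partitions
        sched.create_dataset("acs_indices", data=ks.schedule.acs_indices)
        sched.create_dataset("acquired_indices", data=ks.schedule.acquired_indices)
        sched.create_dataset("acquired_mask", data=ks.acquired_mask)
        g = f.create_group("meta")
        g.attrs["scale"] = ks.scale
        g.attrs["version"] = BUNDLE_VERSION
        for key, val in meta.items():
            g.attrs[key] = val


def load_bundle(path) -> MRFKspace:
    """Read a bundle back into an :class:`MRFKspace`.

    Raises :class:`BundleFormatError` on truncation, missing groups,
    inconsistent shapes or an unsupported version string.
    """
    try:
        with h5py.File(path, "r") as f:
            try:
                meta = f["meta"]
                version = meta.attrs["version"]
                if str(version) != BUNDLE_VERSION:
                    raise BundleFormatError(
                        f"unsupported bundle version {version!r} (expected {BUNDLE_VERSION})"
                    )
                data = f["kspace"][...]
                coords = f["traj/coords"][...]
                angles = f["traj/frame_angles"][...]
                traj = SpiralTrajectory(
                    coords=coords,
                    n_interleaves_full=int(f["traj"].attrs["n_interleaves_full"]),
                    k_max=float(f["traj"].attrs["k_max"]),
                    turns=float(f["traj"].attrs["turns"]),
                )
                sched = SamplingSchedule(
                    n_partitions=int(f["schedule"].attrs["n_partitions"]),
                    R=int(f["schedule"].attrs["R"]),
                    acs_indices=f["schedule/acs_indices"][...],
                    acquired_indices=f["schedule/acquired_indices"][...],
                    frame_angles=angles,
                )
                mask = f["schedule/acquired_mask"][...].astype(bool)
                scale = float(meta.attrs["scale"])
            except KeyError as exc:
                raise BundleFormatError(f"bundle is missing {exc}") from exc
    except OSError as exc:
        raise BundleFormatError(f"not a readable HDF5 bundle: {exc}") from exc
    try:
        return MRFKspace(
            data=data, trajectory=traj, schedule=sched, acquired_mask=mask, scale=scale
        )
    except ValueError as exc:
        raise BundleFormatError(f"inconsistent bundle contents: {exc}") from exc


def save_kernels(path, kernels: GrappaKernelSet) -> None:
    np.savez(
        path,
        weights=kernels.weights,
        v=kernels.v,
        R=kernels.R,
        n_coils=kernels.n_coils,
        ridge=kernels.ridge,
    )


def load_kernels(path) -> GrappaKernelSet:
    with np.load(path) as z:
        return GrappaKernelSet(
            weights=z["weights"],
            v=int(z["v"]),
            R=int(z["R"]),
            n_coils=int(z["n_coils"]),
            ridge=float(z["ridge"]),
        )


def save_maps(directory, maps: TissueMaps, voxel_size_mm=(1.0, 1.0, 1.0)) -> dict:
    """Write T1/T2/PD/mask volumes as NIfTI files; returns the paths."""
    import pathlib

    import nibabel as nib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    paths = {}
    for name, vol in (
        ("t1_ms", maps.t1_ms),
        ("t2_ms", maps.t2_ms),
        ("pd", maps.pd),
        ("mask", maps.mask.astype(np.uint8)),
    ):
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), p)
        paths[name] = str(p)
    return paths


def load_volume(path) -> np.ndarray:
    """Load a NIfTI volume (or an ``.npz``/``.npy`` array) as a numpy array."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asanyarray(nib.load(path).dataobj)
    if path.endswith(".npz"):
        with np.load(path) as z:
            return z[list(z.keys())[0]]
    return np.load(path)


def _json_safe(x):
    if isinstance(x, float) and not math.isfinite(x):
        return "inf" if x > 0 else ("-inf" if x < 0 else "nan")
    return x


def save_metrics(path, report: MetricReport | dict) -> None:
    """Write a metric report as JSON; non-finite values become strings."""
    d = report.as_dict() if isinstance(report, MetricReport) else dict(report)
    with open(path, "w") as f:
        json.dump({k: _json_safe(v) for k, v in d.items()}, f, indent=2, sort_keys=True)
        f.write("\n")
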