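"""Config-driven pipeline helpers shared by the CLI and the test suite."""

from __future__ import annotations

import numpy as np

from .synthdata import (
    AcquisitionSchedule,
    MRFKspace,
    default_acquisition,
    forward_sample,
    make_phantom,
    undersample,
)
from .trajectory import SamplingSchedule, SpiralTrajectory, make_schedule, make_spiral

__all__ = ["acq_from_config", "traj_from_config", "schedule_from_config", "simulate_from_config"]


def acq_from_config(cfg: dict) -> AcquisitionSchedule:
    return default_acquisition(
        T=cfg["T"],
        n_segments=cfg["n_segments"],
        tr_ms=cfg["tr_ms"],
        te_ms=cfg["te_ms"],
        t2prep_te_ms=tuple(cfg["t2prep_te_ms"]),
        inversion=cfg["inversion"],
        segment_delay_ms=cfg["segment_delay_ms"],
    )


def traj_from_config(cfg: dict) -> SpiralTrajectory:
    return make_spiral(
        Q=cfg["Q"],
        n_interleaves_full=cfg["n_interleaves_full"],
        k_max=cfg["k_max"],
        turns=cfg["turns"],
    )


def schedule_from_config(cfg: dict, R: int | None = None, n_acs: int | None = None) -> SamplingSchedule:
    return make_schedule(
        n_partitions=cfg["P"],
        R=cfg["R"] if R is None else R,
        n_acs=cfg["n_acs"] if n_acs is None else n_acs,
        T=cfg["T"],
    )


def simulate_from_config(
    cfg: dict,
    seed: int = 0,
    full_inplane: bool = False,
    noiseless: bool = False,
):
    """Phantom + coils + fully sampled forward k-space for a config dict.

    Returns ``(ks, phantom, coils, acq)``; apply
    :func:`spiralmrf.synthdata.undersample` separately for acceleration.
    """
    phantom, coils = make_phantom(cfg["M"], cfg["P"], cfg["C"], seed=seed)
    traj = traj_from_config(cfg)
    sched = schedule_from_config(cfg)
    acq = acq_from_config(cfg)
    ks = forward_sample(
        phantom,
        coils,
        traj,
        sched,
        acq,
        noise_sigma=0.0 if noiseless else cfg["noise_sigma"],
        seed=seed + 1,
        full_inplane=full_inplane,
    )
    return ks, phantom, coils, acq
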