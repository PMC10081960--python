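"""Named parameter presets for the simulation and reconstruction pipeline.

``desk`` is the default problem size used throughout the test suite and
worked examples: large enough for the interpolators to be meaningfully
compared, small enough for a single CPU.  The ``paper-1mm`` and
``paper-0.8mm`` presets record the full acquisition geometries of the
in-vivo protocols this simulator parameterizes (matrix 256/320, 144/176
partitions, 768 frames, 32 coils); they are configuration records, not
test defaults.
"""

from __future__ import annotations

import copy

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, dict] = {
    # small fixture preset used by the CLI smoke tests
    "tiny": {
        "M": 32, "P": 12, "Q": 128, "C": 4, "T": 16,
        "R": 2, "n_acs": 6,
        "n_interleaves_full": 8, "turns": 2.0, "k_max": 0.5,
        "n_segments": 4, "tr_ms": 9.2, "te_ms": 1.3,
        "t2prep_te_ms": [50.0, 90.0], "inversion": True, "segment_delay_ms": 300.0,
        "noise_sigma": 2e-4,
        "block_channels": [16, 32, 32], "n_blocks": 1, "K": 5, "epochs": 20,
        "voxel_size_mm": [8.0, 8.0, 8.0],
    },
    "desk": {
        "M": 64, "P": 24, "Q": 512, "C": 8, "T": 48,
        "R": 4, "n_acs": 8,
        "n_interleaves_full": 8, "turns": 4.0, "k_max": 0.5,
        "n_segments": 4, "tr_ms": 9.2, "te_ms": 1.3,
        "t2prep_te_ms": [50.0, 90.0], "inversion": True, "segment_delay_ms": 300.0,
        "noise_sigma": 1e-4,
        "block_channels": [64, 128, 128], "n_blocks": 3, "K": 5, "epochs": 100,
        "voxel_size_mm": [4.0, 4.0, 8.0],
    },
    "paper-1mm": {
        "M": 256, "P": 144, "Q": 2452, "C": 32, "T": 768,
        "R": 4, "n_acs": 12,
        "n_interleaves_full": 48, "turns": 2.7, "k_max": 0.5,
        "n_segments": 16, "tr_ms": 9.2, "te_ms": 1.3,
        "t2prep_te_ms": [50.0, 90.0], "inversion": True, "segment_delay_ms": 300.0,
        "noise_sigma": 1e-4,
        "block_channels": [512, 1024, 1024], "n_blocks": 3, "K": 5, "epochs": 100,
        "voxel_size_mm": [1.0, 1.0, 1.0],
    },
    "paper-0.8mm": {
        "M": 320, "P": 176, "Q": 3300, "C": 32, "T": 768,
        "R": 4, "n_acs": 16,
        "n_interleaves_full": 48, "turns": 3.4, "k_max": 0.5,
        "n_segments": 16, "tr_ms": 12.6, "te_ms": 1.3,
        "t2prep_te_ms": [50.0, 90.0], "inversion": True, "segment_delay_ms": 300.0,
        "noise_sigma": 1e-4,
        "block_channels": [512, 1024, 1024], "n_blocks": 3, "K": 5, "epochs": 100,
        "voxel_size_mm": [0.8, 0.8, 0.8],
    },
}


def get_preset(name: str, overrides: dict | None = None) -> dict:
    """Deep copy of a named preset, optionally updated with overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = copy.deepcopy(PRESETS[name])
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
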