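"""Learned k-space interpolators along the partition-encoding direction.

Two scan-specific ("self-calibrated") models share one architecture:

* ``cartesian_cnn`` — treats the spiral readout as a straight line and
  aggregates neighbors with a width-3 1D convolution;
* ``gcn`` — replaces the width-3 aggregation with a graph convolution whose
  propagation matrix encodes the true non-uniform spiral geometry
  (:mod:`spiralmrf.kgraph`); the two width-1 layers of each block are
  pointwise in both variants.

Each block applies (aggregation, ReLU, width-1 conv, ReLU, width-1 conv),
wrapped in a residual connection (identity shortcut when channel counts
match, learned pointwise projection otherwise) followed by ReLU; a final
pointwise linear layer maps to the output channels.  Inputs are the two
flanking acquired partitions with real and imaginary parts stacked across
coils (2*2*C channels); outputs are the R-1 skipped partitions in between
((R-1)*2*C channels), each sample normalized by the RMS magnitude of its
own input pair so the learned relation is scale-equivariant across the kz
amplitude decay.  Training minimizes the MSE against the fully sampled ACS
partitions with ADAM, batch size 1, and a learning rate decayed by 0.99 per
epoch — the model is trained anew for every scan and every R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .grappa import _flanking_pairs
from .kgraph import KSpaceGraph, build_adjacency
from .synthdata import MRFKspace

__all__ = [
    "InterpolatorConfig",
    "TrainingConfig",
    "TrainingPair",
    "Interpolator",
    "make_training_pairs",
    "build_interpolator",
    "gcn_config",
    "train_interpolator",
    "interpolate_partitions",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class InterpolatorConfig:
    """Architecture hyperparameters.

    ``block_channels`` are the filter counts of the three layers of each
    block, (512, 1024, 1024) by default; ``K`` is the graph kernel size
    (gcn only) and ``cnn_kernel`` the aggregation width of the Cartesian
    variant.  Channel arithmetic: inputs carry ``2 * 2 * n_coils`` real
    channels, outputs ``(R - 1) * 2 * n_coils``.
    """

    kind: str
    R: int
    n_coils: int
    n_blocks: int = 1
    block_channels: tuple[int, int, int] = (512, 1024, 1024)
    K: int = 5
    cnn_kernel: int = 3
    normalization: str = "pair"

    def __post_init__(self):
        if self.kind not in ("cartesian_cnn", "gcn"):
            raise ValueError("kind must be 'cartesian_cnn' or 'gcn'")
        if self.normalization not in ("pair", "global"):
            raise ValueError("normalization must be 'pair' or 'global'")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.R < 2:
            raise ValueError("R must be >= 2 for interpolation")

    @property
    def in_channels(self) -> int:
        return 2 * 2 * self.n_coils

    @property
    def out_channels(self) -> int:
        return (self.R - 1) * 2 * self.n_coils


@dataclass(frozen=True)
class TrainingConfig:
    lr0: float = 5e-4
    lr_decay_per_epoch: float = 0.99
    batch_size: int = 1
    epochs: int = 100
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self):
        if not (0 < self.lr_decay_per_epoch <= 1):
            raise ValueError("lr_decay_per_epoch must lie in (0, 1]")
        if self.loss != "mse":
            raise ValueError("only the 'mse' loss is supported")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.lr_decay_per_epoch**epoch


@dataclass(frozen=True)
class TrainingPair:
    """One ACS training sample.

    ``input`` is ``(Q, 2*2*C)`` — the two acquired partitions p and p+R
    with channel layout [partition A real coils 1..C, partition A imag,
    partition B real, partition B imag]; ``target`` is
    ``(Q, (R-1)*2*C)`` — the skipped partitions ordered by offset m, each
    as [real coils 1..C, imag coils 1..C].  Both are normalized by the
    sample's own pair scale (or the global ACS factor in 'global' mode).
    """

    input: np.ndarray
    target: np.ndarray
    frame: int
    position: int


def stack_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Real-stack two complex ``(Q, C)`` partitions into ``(Q, 4C)``."""
    return np.concatenate([a.real, a.imag, b.real, b.imag], axis=1)


def stack_offsets(parts: np.ndarray) -> np.ndarray:
    """Real-stack ``(R-1, Q, C)`` complex targets into ``(Q, (R-1)*2C)``."""
    return np.concatenate([np.concatenate([p.real, p.imag], axis=1) for p in parts], axis=1)


def unstack_offsets(y: np.ndarray, n_coils: int) -> np.ndarray:
    """Inverse of :func:`stack_offsets`: ``(Q, (R-1)*2C)`` -> ``(R-1, Q, C)``."""
    Q, W = y.shape
    n_off = W // (2 * n_coils)
    blocks = y.reshape(Q, n_off, 2, n_coils)
    return np.moveaxis(blocks[:, :, 0] + 1j * blocks[:, :, 1], 0, 1)


def _pair_scale(a: np.ndarray, b: np.ndarray) -> float:
    """RMS magnitude of a flanking partition pair (the per-pair scale)."""
    return float(np.sqrt((np.mean(np.abs(a) ** 2) + np.mean(np.abs(b) ** 2)) / 2.0))


def make_training_pairs(
    acs: np.ndarray,
    R: int,
    stride: int = 1,
    scale: float | None = None,
    normalization: str = "pair",
) -> list[TrainingPair]:
    """Build (input, target) pairs from the fully sampled ACS block.

    One pair per (frame, start offset p) with both p and p+R inside the
    ACS; starts advance by ``stride``.  With ``normalization='pair'`` (the
    default) each sample is divided by the RMS magnitude of its own input
    pair, which makes the learned relation scale-equivariant — essential
    for generalizing from the high-amplitude central ACS partitions to the
    weak outer-kz partitions at inference.  ``'global'`` divides everything
    by one ACS scale factor (max magnitude by default) instead.
    """
    acs = np.asarray(acs)
    T, P_acs, Q, C = acs.shape
    if P_acs <= R:
        raise ValueError(f"ACS block with {P_acs} partitions yields no pairs at R={R}")
    if normalization not in ("pair", "global"):
        raise ValueError("normalization must be 'pair' or 'global'")
    if scale is None:
        scale = float(np.abs(acs).max())
    if scale <= 0:
        raise ValueError("ACS data is identically zero")
    pairs = []
    for t in range(T):
        for p in range(0, P_acs - R, stride):
            s = _pair_scale(acs[t, p], acs[t, p + R]) if normalization == "pair" else scale
            if s == 0:
                continue
            inp = stack_pair(acs[t, p] / s, acs[t, p + R] / s)
            tgt = stack_offsets(acs[t, p + 1 : p + R] / s)
            pairs.append(TrainingPair(input=inp, target=tgt, frame=t, position=p))
    return pairs


class Interpolator:
    """A built (possibly trained) interpolation network."""

    def __init__(self, cfg: InterpolatorConfig, graph: KSpaceGraph | None, seed: int):
        if cfg.kind == "gcn" and graph is None:
            raise ValueError("gcn interpolator requires a k-space graph")
        self.cfg = cfg
        self.graph = graph if cfg.kind == "gcn" else None
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        prop = self.graph.propagation if self.graph is not None else None

        def aggregation(a, b):
            if cfg.kind == "gcn":
                return nn.GraphConv(prop, a, b, rng)
            if cfg.cnn_kernel == 1:
                return nn.PointwiseConv(a, b, rng)
            return nn.Conv1d(cfg.cnn_kernel, a, b, rng)

        c1, c2, c3 = cfg.block_channels
        blocks: list[nn.Layer] = []
        ch = cfg.in_channels
        for _ in range(cfg.n_blocks):
            body = nn.Sequential(
                aggregation(ch, c1), nn.ReLU(),
                nn.PointwiseConv(c1, c2, rng), nn.ReLU(),
                nn.PointwiseConv(c2, c3, rng),
            )
            shortcut = None if ch == c3 else nn.PointwiseConv(ch, c3, rng)
            blocks.append(nn.Residual(body, shortcut))
            ch = c3
        self.net = nn.Sequential(*blocks, nn.PointwiseConv(ch, cfg.out_channels, rng))

    def params(self) -> list[nn.Parameter]:
        return self.net.params()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.graph is not None and x.shape[0] != self.graph.n_points:
            raise ValueError("readout length does not match the k-space graph")
        return self.net.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            if p.value.shape != np.asarray(w).shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w


def build_interpolator(
    cfg: InterpolatorConfig, graph: KSpaceGraph | None = None, seed: int = 0
) -> Interpolator:
    """Instantiate an interpolator with seed-controlled initialization."""
    return Interpolator(cfg, graph, seed)


def gcn_config(R: int, n_coils: int, variant: str = "gcn-3b", **kwargs) -> InterpolatorConfig:
    """Named GCN variants: ``'gcn-1b'`` (one block) and ``'gcn-3b'`` (three)."""
    blocks = {"gcn-1b": 1, "gcn-3b": 3}
    if variant not in blocks:
        raise ValueError(f"variant must be one of {sorted(blocks)}")
    return InterpolatorConfig(
        kind="gcn", R=R, n_coils=n_coils, n_blocks=blocks[variant], **kwargs
    )


def train_interpolator(
    model: Interpolator, pairs: list[TrainingPair], tcfg: TrainingConfig
) -> tuple[Interpolator, list[float]]:
    """Self-calibrated training on ACS pairs; returns per-epoch mean loss.

    Deterministic for a given ``tcfg.seed`` (which drives the per-epoch
    shuffling; initialization is seeded at build time).
    """
    if not pairs:
        raise ValueError("no training pairs provided")
    opt = nn.Adam(model.params())
    rng = np.random.default_rng(tcfg.seed)
    history: list[float] = []
    n = len(pairs)
    for epoch in range(tcfg.epochs):
        lr = tcfg.lr_at(epoch)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, tcfg.batch_size):
            opt.zero_grad()
            batch = order[start : start + tcfg.batch_size]
            batch_loss = 0.0
            for idx in batch:
                pair = pairs[idx]
                pred = model.forward(pair.input)
                loss, dy = nn.mse_loss(pred, pair.target)
                model.backward(dy / batch.size)
                batch_loss += loss / batch.size
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"training loss became non-finite at epoch {epoch}"
                )
            opt.step(lr)
            total += batch_loss * batch.size
        history.append(total / n)
    return model, history


def interpolate_partitions(model: Interpolator, ks: MRFKspace) -> MRFKspace:
    """Predict every skipped partition with the trained interpolator.

    Skipped partitions are grouped by their flanking acquired pair on the
    regular grid; each group is predicted in one forward pass per frame
    (all R-1 offsets at once).  Acquired partitions pass through unchanged
    and the inputs/outputs are de-/re-normalized by the stored scale.
    """
    T, P, Q, C = ks.data.shape
    cfg = model.cfg
    if C != cfg.n_coils:
        raise ValueError("coil count does not match the model configuration")
    if model.graph is not None and Q != model.graph.n_points:
        raise ValueError("readout length does not match the model's graph")
    groups = _flanking_pairs(ks.acquired_mask, cfg.R)
    out = ks.copy()
    for (lo, hi), missing in groups.items():
        for t in range(T):
            if cfg.normalization == "pair":
                s = _pair_scale(ks.data[t, lo], ks.data[t, hi]) or 1.0
            else:
                s = ks.scale
            x = stack_pair(ks.data[t, lo] / s, ks.data[t, hi] / s)
            pred = unstack_offsets(model.forward(x), C) * s  # (R-1, Q, C)
            for p in missing:
                out.data[t, p] = pred[p - lo - 1].astype(out.data.dtype)
    out.acquired_mask = np.ones(P, dtype=bool)
    return out


def save_model(path, model: Interpolator, scale: float = 1.0) -> None:
    """Serialize config, seed, weights, graph and scale to one ``.npz``."""
    cfg = model.cfg
    payload = {
        "kind": cfg.kind,
        "R": cfg.R,
        "n_coils": cfg.n_coils,
        "n_blocks": cfg.n_blocks,
        "block_channels": np.asarray(cfg.block_channels),
        "K": cfg.K,
        "cnn_kernel": cfg.cnn_kernel,
        "normalization": cfg.normalization,
        "seed": model.seed,
        "scale": scale,
        "n_weights": len(model.get_weights()),
    }
    if model.graph is not None:
        payload["graph_coords"] = model.graph.coords
        payload["graph_symmetrized"] = model.graph.symmetrized
    for i, w in enumerate(model.get_weights()):
        payload[f"w{i}"] = w
    np.savez(path, **payload)


def load_model(path) -> tuple[Interpolator, float]:
    """Inverse of :func:`save_model`; returns (model, scale)."""
    with np.load(path, allow_pickle=False) as z:
        cfg = InterpolatorConfig(
            kind=str(z["kind"]),
            R=int(z["R"]),
            n_coils=int(z["n_coils"]),
            n_blocks=int(z["n_blocks"]),
            block_channels=tuple(int(c) for c in z["block_channels"]),
            K=int(z["K"]),
            cnn_kernel=int(z["cnn_kernel"]),
            normalization=str(z["normalization"]),
        )
        graph = None
        if "graph_coords" in z:
            graph = build_adjacency(
                z["graph_coords"], cfg.K, symmetrize=bool(z["graph_symmetrized"])
            )
        model = build_interpolator(cfg, graph, seed=int(z["seed"]))
        model.set_weights([z[f"w{i}"] for i in range(int(z["n_weights"]))])
        return model, float(z["scale"])
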