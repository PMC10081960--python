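"""CNN / GCN interpolator construction, training and inference."""

import numpy as np
import pytest

from spiralmrf import build_adjacency, make_spiral, undersample
from spiralmrf.interpnet import (
    InterpolatorConfig,
    TrainingConfig,
    TrainingDivergedError,
    build_interpolator,
    interpolate_partitions,
    load_model,
    make_training_pairs,
    save_model,
    stack_pair,
    train_interpolator,
    unstack_offsets,
)
from spiralmrf import nn
from spiralmrf.trajectory import make_schedule

from conftest import nmse


def small_cfg(kind, R=2, C=2, channels=(8, 16, 16), **kw):
    return InterpolatorConfig(
        kind=kind, R=R, n_coils=C, block_channels=channels, **kw
    )


@pytest.fixture(scope="module")
def toy_graph():
    arm = make_spiral(Q=32, n_interleaves_full=4, k_max=0.5, turns=2.0)
    return build_adjacency(arm.coords, K=5)


class TestTrainingPairs:
    @pytest.mark.parametrize("R,expected_per_frame", [(2, 10), (4, 8)])
    def test_pair_counts(self, R, expected_per_frame):
        rng = np.random.default_rng(0)
        acs = rng.standard_normal((3, 12, 16, 2)) + 0j
        pairs = make_training_pairs(acs, R=R)
        assert len(pairs) == 3 * expected_per_frame
        assert pairs[0].target.shape == (16, (R - 1) * 2 * 2)

    def test_feature_width_for_32_coils(self):
        rng = np.random.default_rng(0)
        acs = rng.standard_normal((1, 3, 4, 32)) + 0j
        pairs = make_training_pairs(acs, R=2)
        assert pairs[0].input.shape == (4, 128)  # 2 partitions x re/im x 32 coils
        assert InterpolatorConfig(kind="gcn", R=2, n_coils=32).in_channels == 128

    def test_pair_normalization_gives_unit_rms_inputs(self):
        rng = np.random.default_rng(1)
        acs = 100.0 * (rng.standard_normal((1, 4, 8, 1)) + 1j * rng.standard_normal((1, 4, 8, 1)))
        for pair in make_training_pairs(acs, R=2):
            a = pair.input[:, :2] @ np.array([1, 1j])  # recombine complex partition A
            b = pair.input[:, 2:] @ np.array([1, 1j])
            rms = np.sqrt((np.mean(np.abs(a) ** 2) + np.mean(np.abs(b) ** 2)) / 2)
            assert rms == pytest.approx(1.0, rel=1e-12)

    def test_global_normalization_bounded_by_acs_peak(self):
        rng = np.random.default_rng(1)
        acs = 100.0 * (rng.standard_normal((1, 4, 8, 1)) + 1j * rng.standard_normal((1, 4, 8, 1)))
        pairs = make_training_pairs(acs, R=2, normalization="global")
        peak = max(np.abs(p.input).max() for p in pairs)
        assert peak <= 1.0 + 1e-12

    def test_empty_acs_rejected(self):
        acs = np.zeros((1, 2, 4, 1), dtype=complex)
        with pytest.raises(ValueError):
            make_training_pairs(acs + 1, R=2)

    def test_stack_roundtrip(self):
        rng = np.random.default_rng(2)
        parts = rng.standard_normal((3, 8, 4)) + 1j * rng.standard_normal((3, 8, 4))
        assert np.allclose(unstack_offsets(
            np.concatenate([np.concatenate([p.real, p.imag], axis=1) for p in parts], axis=1), 4
        ), parts)


class TestArchitecture:
    def test_default_block_channels(self):
        cfg = InterpolatorConfig(kind="gcn", R=4, n_coils=32)
        assert cfg.block_channels == (512, 1024, 1024)
        assert cfg.out_channels == 3 * 2 * 32

    def test_gcn_has_fewer_parameters_than_cnn(self):
        for n_blocks in (1, 3):
            arm = make_spiral(Q=16, n_interleaves_full=4, k_max=0.5, turns=2.0)
            graph = build_adjacency(arm.coords, K=5)
            gcn = build_interpolator(
                small_cfg("gcn", channels=(16, 32, 32), n_blocks=n_blocks), graph
            )
            cnn = build_interpolator(
                small_cfg("cartesian_cnn", channels=(16, 32, 32), n_blocks=n_blocks)
            )
            assert gcn.n_parameters < cnn.n_parameters

    def test_gcn_k1_equals_pointwise_cnn(self, toy_graph):
        """With K=1 the propagation matrix is the identity, so a GCN with the
        same weights as an all-pointwise CNN computes the same function."""
        arm = toy_graph.coords
        g1 = build_adjacency(arm, K=1)
        cfgg = small_cfg("gcn", K=1)
        cfgc = small_cfg("cartesian_cnn", cnn_kernel=1)
        gcn = build_interpolator(cfgg, g1, seed=0)
        cnn = build_interpolator(cfgc, seed=0)
        cnn.set_weights(gcn.get_weights())
        x = np.random.default_rng(3).standard_normal((len(arm), cfgg.in_channels))
        assert np.max(np.abs(gcn.forward(x) - cnn.forward(x))) < 1e-6

    def test_graph_conv_matches_dense_oracle(self):
        coords = np.array(
            [[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1], [0, 2], [1, 2]], float
        )
        graph = build_adjacency(coords, K=3)
        rng = np.random.default_rng(4)
        layer = nn.GraphConv(graph.propagation, 3, 5, rng)
        relu = nn.ReLU()
        H = rng.standard_normal((8, 3))
        got = relu.forward(layer.forward(H))
        P = graph.propagation.toarray()
        expected = np.maximum(P @ H @ layer.W.value + layer.b.value, 0.0)
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_output_finite_for_random_inputs(self, toy_graph):
        model = build_interpolator(small_cfg("gcn"), toy_graph, seed=1)
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.standard_normal((toy_graph.n_points, model.cfg.in_channels)) * 10
            assert np.all(np.isfinite(model.forward(x)))

    def test_gcn_requires_graph(self):
        with pytest.raises(ValueError):
            build_interpolator(small_cfg("gcn"), None)

    def test_graph_size_mismatch_rejected(self, toy_graph):
        model = build_interpolator(small_cfg("gcn"), toy_graph)
        with pytest.raises(ValueError):
            model.forward(np.zeros((toy_graph.n_points + 1, model.cfg.in_channels)))


class TestTraining:
    def test_learning_rate_schedule(self):
        tcfg = TrainingConfig()
        assert tcfg.lr_at(10) == pytest.approx(5e-4 * 0.99**10, rel=1e-12)
        assert tcfg.lr_at(0) == 5e-4

    def test_overfit_single_pair(self, toy_graph):
        """A single sample can be memorized to < 1e-3 of the initial MSE.

        Uses a larger initial learning rate than the production schedule:
        500 single-sample steps at 5e-4 move parameters by at most ~0.25
        in ADAM's normalized units, too little for full memorization.
        """
        rng = np.random.default_rng(6)
        acs = rng.standard_normal((1, 3, 32, 2)) + 1j * rng.standard_normal((1, 3, 32, 2))
        pairs = make_training_pairs(acs, R=2)[:1]
        model = build_interpolator(small_cfg("gcn", channels=(16, 32, 32)), toy_graph, seed=0)
        loss0, _ = nn.mse_loss(model.forward(pairs[0].input), pairs[0].target)
        model, history = train_interpolator(
            model, pairs, TrainingConfig(epochs=500, seed=0, lr0=1e-2)
        )
        loss_final, _ = nn.mse_loss(model.forward(pairs[0].input), pairs[0].target)
        assert loss_final < 1e-3 * loss0

    def test_deterministic_given_seed(self, toy_graph):
        rng = np.random.default_rng(7)
        acs = rng.standard_normal((2, 4, 32, 2)) + 1j * rng.standard_normal((2, 4, 32, 2))
        pairs = make_training_pairs(acs, R=2)
        runs = []
        for _ in range(2):
            model = build_interpolator(small_cfg("gcn"), toy_graph, seed=3)
            _, history = train_interpolator(model, pairs, TrainingConfig(epochs=20, seed=3))
            runs.append(history[-1])
        assert abs(runs[0] - runs[1]) < 1e-10

    def test_loss_history_smoothed_nonincreasing(self, tiny_sim, tiny_undersampled, toy_graph):
        und = tiny_undersampled
        acs = und.data[:, und.schedule.acs_indices]
        pairs = make_training_pairs(acs, R=und.schedule.R, scale=und.scale)
        graph = build_adjacency(und.trajectory.coords, K=5)
        cfg = small_cfg("gcn", R=und.schedule.R, C=und.data.shape[3], channels=(16, 32, 32))
        model = build_interpolator(cfg, graph, seed=0)
        _, history = train_interpolator(model, pairs, TrainingConfig(epochs=60, seed=0))
        h = np.asarray(history)
        smoothed = np.convolve(h, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smoothed) <= 1e-3 * smoothed[0])

    def test_divergence_raises(self, toy_graph):
        rng = np.random.default_rng(8)
        acs = rng.standard_normal((1, 3, 32, 2)) + 0j
        # absurd learning rate: ADAM steps of ~1e150 overflow the forward pass
        pairs = make_training_pairs(acs, R=2)
        model = build_interpolator(small_cfg("gcn"), toy_graph, seed=0)
        with pytest.raises(TrainingDivergedError):
            train_interpolator(model, pairs, TrainingConfig(epochs=5, seed=0, lr0=1e150))

    def test_empty_pairs_rejected(self, toy_graph):
        model = build_interpolator(small_cfg("gcn"), toy_graph)
        with pytest.raises(ValueError):
            train_interpolator(model, [], TrainingConfig(epochs=1))


@pytest.fixture(scope="module")
def trained(tiny_undersampled):
    und = tiny_undersampled
    acs = und.data[:, und.schedule.acs_indices]
    pairs = make_training_pairs(acs, R=und.schedule.R)
    graph = build_adjacency(und.trajectory.coords, K=5)
    cfg = small_cfg("gcn", R=und.schedule.R, C=und.data.shape[3], channels=(16, 32, 32))
    model = build_interpolator(cfg, graph, seed=0)
    model, _ = train_interpolator(model, pairs, TrainingConfig(epochs=150, seed=0))
    return model


class TestInference:

    def test_acquired_bit_identical_and_complete(self, trained, tiny_undersampled):
        und = tiny_undersampled
        out = interpolate_partitions(trained, und)
        idx = und.schedule.acquired_indices
        assert np.array_equal(out.data[:, idx], und.data[:, idx])
        assert out.acquired_mask.all()
        assert not np.any(np.all(out.data == 0, axis=(0, 2, 3)))

    def test_beats_nearest_neighbor_copy(self, trained, tiny_sim, tiny_undersampled):
        und, ref = tiny_undersampled, tiny_sim["ksn"].data
        out = interpolate_partitions(trained, und)
        nn_fill = und.data.copy()
        acq = np.where(und.acquired_mask)[0]
        for p in np.where(~und.acquired_mask)[0]:
            nearest = acq[np.argmin(np.abs(acq - p))]
            nn_fill[:, p] = und.data[:, nearest]
        assert nmse(out.data, ref) < nmse(nn_fill, ref)

    def test_coil_mismatch_rejected(self, trained, tiny_undersampled):
        und = tiny_undersampled.copy()
        und.data = und.data[..., :-1]
        with pytest.raises(ValueError):
            interpolate_partitions(trained, und)

    def test_save_load_roundtrip(self, trained, tiny_undersampled, tmp_path):
        path = tmp_path / "model.npz"
        save_model(path, trained, scale=tiny_undersampled.scale)
        loaded, scale = load_model(path)
        assert scale == tiny_undersampled.scale
        x = np.random.default_rng(9).standard_normal(
            (trained.graph.n_points, trained.cfg.in_channels)
        )
        assert np.array_equal(loaded.forward(x), trained.forward(x))
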