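import numpy as np
import pytest
from naive import naive_conv2d, naive_forward, naive_maxpool

import fxpreg as fr
from conftest import stack_inputs
from fxpreg.model import (
    NetworkWeights,
    TrainConfig,
    conv2d_valid,
    count_parameters,
    forward_batch,
    forward_float,
    init_weights,
    load_weights,
    maxpool_2x2,
    relu,
    save_weights,
)


class TestConv:
    def test_1x1_ones_kernel_is_identity(self, rng):
        x = rng.random((5, 6, 1))
        out = conv2d_valid(x, np.ones((1, 1, 1, 1)), np.zeros(1))
        assert np.allclose(out, x)

    def test_hand_computed_window_sums(self):
        ramp = np.arange(1.0, 10.0).reshape(3, 3, 1)
        out = conv2d_valid(ramp, np.ones((2, 2, 1, 1)), np.zeros(1))
        assert np.array_equal(out[:, :, 0], [[12, 16], [24, 28]])

    def test_architecture_output_shape(self, rng):
        out = conv2d_valid(
            rng.random((32, 32, 3)), rng.random((2, 2, 3, 8)), rng.random(8)
        )
        assert out.shape == (31, 31, 8)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d_valid(rng.random((5, 5, 2)), rng.random((2, 2, 3, 4)), np.zeros(4))


class TestRelu:
    def test_all_negative_zeroed(self):
        assert np.array_equal(relu(np.array([-3.0, -0.1])), [0.0, 0.0])

    def test_non_negative_unchanged_and_mixed(self):
        assert np.array_equal(relu(np.array([-1.0, 0.5])), [0.0, 0.5])
        x = np.array([0.0, 2.0])
        assert np.array_equal(relu(x), x)


class TestMaxPool:
    def test_constant_image(self):
        out = maxpool_2x2(np.full((6, 6, 2), 3.5))
        assert out.shape == (3, 3, 2) and np.all(out == 3.5)

    def test_odd_size_drops_trailing(self, rng):
        assert maxpool_2x2(rng.random((31, 31, 8))).shape == (15, 15, 8)

    def test_single_peak_appears_once(self):
        x = np.zeros((4, 4, 1))
        x[1, 2, 0] = 9.0
        out = maxpool_2x2(x)
        assert np.count_nonzero(out == 9.0) == 1


class TestForward:
    def test_zero_weights_give_zero_prediction(self, rng):
        w = NetworkWeights(
            conv1_w=np.zeros((2, 2, 3, 8)),
            conv1_b=np.zeros(8),
            conv2_w=np.zeros((2, 2, 8, 16)),
            conv2_b=np.zeros(16),
            head_rot_w=np.zeros(784),
            head_dx_w=np.zeros(784),
            head_dy_w=np.zeros(784),
        )
        p = forward_float(w, rng.random((32, 32, 3)))
        assert p.as_array().tolist() == [0.0, 0.0, 0.0]

    def test_layer_shape_trace(self, rng):
        w = init_weights(0)
        cache = {}
        forward_batch(w, rng.random((2, 32, 32, 3)), cache=cache)
        assert cache["a1"].shape[1:] == (31, 31, 8)
        assert cache["p1"].shape[1:] == (15, 15, 8)
        assert cache["a2"].shape[1:] == (14, 14, 16)
        assert cache["flat"].shape[1:] == (784,)
        assert cache["y"].shape[1:] == (3,)

    def test_matches_naive_loop_forward(self, rng):
        w = init_weights(3)
        x = rng.random((32, 32, 3))
        assert np.allclose(
            forward_float(w, x).as_array(), naive_forward(w, x), atol=1e-9
        )

    def test_input_shape_enforced(self):
        with pytest.raises(ValueError):
            forward_float(init_weights(0), np.zeros((16, 32, 3)))


def test_vectorized_layers_match_naive_loops(rng):
    """Oracle equivalence on random small instances."""
    for _ in range(5):
        x = rng.standard_normal((5, 5, 2))
        k = rng.standard_normal((2, 2, 2, 3))
        b = rng.standard_normal(3)
        assert np.allclose(conv2d_valid(x, k, b), naive_conv2d(x, k, b), atol=1e-9)
        assert np.allclose(maxpool_2x2(x), naive_maxpool(x), atol=1e-9)


def test_channel_permutation_consistency(rng):
    """Permuting conv1 kernels with conv2's input channels is a no-op."""
    w = init_weights(11)
    perm = rng.permutation(8)
    w2 = w.copy()
    w2.conv1_w = w.conv1_w[:, :, :, perm]
    w2.conv1_b = w.conv1_b[perm]
    w2.conv2_w = w.conv2_w[:, :, perm, :]
    x = rng.random((32, 32, 3))
    assert np.allclose(
        forward_float(w, x).as_array(), forward_float(w2, x).as_array(), atol=1e-12
    )


class TestParameterCounts:
    def test_total(self):
        assert count_parameters(init_weights(0)) == 2984

    def test_per_layer(self):
        w = init_weights(0)
        assert w.conv1_w.size + w.conv1_b.size == 104
        assert w.conv2_w.size + w.conv2_b.size == 528
        assert w.head_rot_w.size == 784


class TestTraining:
    def test_one_step_changes_weights(self, tiny_dataset):
        w0, _ = fr.train(
            tiny_dataset, TrainConfig(learning_rate=1e-3, epochs=0, seed=1)
        )
        w1, _ = fr.train(
            tiny_dataset, TrainConfig(learning_rate=1e-3, epochs=1, seed=1)
        )
        assert not np.allclose(w1.conv1_w, w0.conv1_w)

    def test_overfits_small_set(self, tiny_dataset):
        """Loss on a 10-pair set decreases over 200 epochs (dropout active)."""
        ds = fr.DatasetSplit(
            train=tiny_dataset.train[:10], val=tiny_dataset.val[:2], seed=0
        )
        cfg = TrainConfig(learning_rate=1e-3, epochs=200, batch_size=10, seed=2)
        _, hist = fr.train(ds, cfg)
        assert hist["train"][-1].sum() < hist["train"][0].sum()
        assert hist["train"].shape == (200, 3)
        assert np.all(np.isfinite(hist["val"]))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fr.train(fr.DatasetSplit(), TrainConfig())

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=9)
        w1, _ = fr.train(tiny_dataset, cfg)
        w2, _ = fr.train(tiny_dataset, cfg)
        assert np.array_equal(w1.conv2_w, w2.conv2_w)


def test_parameter_recovery_on_held_out_pairs(desk_experiment):
    """The trained network recovers the true motion: R^2 > 0.7 per head."""
    ds, w = desk_experiment["ds"], desk_experiment["w"]
    x, t = stack_inputs(ds.test)
    y = forward_batch(w, x)
    for j in range(3):
        _, _, _, r2 = fr.regression_metrics(t[:, j], y[:, j])
        assert r2 > 0.7


def test_self_registration_predicts_near_identity(desk_experiment):
    """Identical-image pairs register with motion much smaller than the
    typical true motions the network was trained on."""
    ds, w = desk_experiment["ds"], desk_experiment["w"]
    preds = []
    for pair in ds.test[:50]:
        pred = forward_float(w, fr.concat_pair(pair.fixed, pair.fixed))
        preds.append(fr.RigidParams.from_normalized(pred.as_array()).as_array())
    mean_pred = np.mean(np.abs(preds), axis=0)
    mean_true = np.mean(
        np.abs([p.gt.as_array() for p in ds.test]), axis=0
    )  # ~(5.5 deg, 5 px, 5 px) for uniform draws
    assert np.all(mean_pred < 0.5 * mean_true)


class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path):
        w = init_weights(5)
        path = tmp_path / "w.npz"
        save_weights(w, path)
        w2 = load_weights(path)
        for k, v in w.tensors().items():
            assert np.array_equal(v, getattr(w2, k))

    def test_header_records_param_count(self, tmp_path):
        from fxpreg.model import load_weight_metadata

        path = tmp_path / "w.npz"
        save_weights(init_weights(0), path)
        assert load_weight_metadata(path)["param_count"] == 2984

    def test_wrong_shape_rejected(self, tmp_path):
        w = init_weights(0)
        path = tmp_path / "w.npz"
        save_weights(w, path)
        import json

        import numpy as np_

        with np_.load(path) as z:
            data = {k: z[k] for k in z.files}
        data["conv1_w"] = data["conv1_w"][..., :4]
        np_.savez(path, **data)
        with pytest.raises(ValueError):
            load_weights(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "w.npz"
        path.write_bytes(b"not a weight file")
        with pytest.raises(ValueError):
            load_weights(path)
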