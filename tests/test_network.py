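"""Bilateral network wiring, gradient, and training-contract tests."""

import numpy as np
import pytest

from hemisim.kinematics import HOME_LEFT, HOME_RIGHT
from hemisim.network import BilateralNetwork, NetworkConfig, PlasticityMask


@pytest.fixture()
def batch(rng):
    images = rng.uniform(size=(3, 2, 8, 8))
    hsp = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
    req_l = rng.uniform(-0.3, 0.3, (3, 3))
    req_r = rng.uniform(-0.3, 0.3, (3, 3))
    return images, hsp, req_l, req_r


class TestArchitecture:
    def test_halves_have_identical_shapes(self, tiny_net):
        for name in tiny_net.params:
            if "_L_" in name:
                twin = name.replace("_L_", "_R_")
                assert tiny_net.params[name].shape == tiny_net.params[twin].shape

    def test_cross_connections_only_at_two_levels(self, tiny_net):
        cross = [n for n in tiny_net.params if "cross" in n]
        assert sorted(cross) == [
            "conv2_L_cross_W",
            "conv2_R_cross_W",
            "fc7_L_cross_W",
            "fc7_R_cross_W",
        ]

    def test_output_layer_has_six_nodes_per_half(self):
        with pytest.raises(ValueError):
            NetworkConfig(fc_nodes=(50, 30, 5))


class TestForward:
    def test_outputs_strictly_in_unit_interval(self, tiny_net, batch):
        out = tiny_net.forward(batch[0], batch[1])
        for arm in ("left", "right"):
            assert out[arm].shape == (3, 6)
            assert np.all(out[arm] > 0.0) and np.all(out[arm] < 1.0)

    def test_zero_final_layer_gives_rest_pose(self, tiny_net, batch):
        # sigmoid(0) = 0.5 on every muscle -> both hands at their home points
        for h in ("L", "R"):
            tiny_net.params[f"fc8_{h}_W"][:] = 0.0
            tiny_net.params[f"fc8_{h}_b"][:] = 0.0
        hands = tiny_net.predict_hands(batch[0], batch[1])
        assert np.allclose(hands["left"], HOME_LEFT, atol=1e-12)
        assert np.allclose(hands["right"], HOME_RIGHT, atol=1e-12)

    def test_shape_mismatch_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError):
            tiny_net.forward(rng.uniform(size=(2, 2, 16, 16)), np.zeros((2, 2)))

    def test_zeroed_cross_connections_isolate_halves(self, tiny_net, batch, rng):
        """With cross-connections removed, the left arm ignores the right
        half's pathway entirely (perturbation check)."""
        for name in ("conv2_L_cross_W", "conv2_R_cross_W", "fc7_L_cross_W", "fc7_R_cross_W"):
            tiny_net.params[name][:] = 0.0
        before = tiny_net.forward(batch[0], batch[1])
        for name in ("conv1_R_W", "conv3_R_W", "fc6_R_W", "fc8_R_b"):
            tiny_net.params[name] += rng.normal(scale=0.5, size=tiny_net.params[name].shape)
        after = tiny_net.forward(batch[0], batch[1])
        assert np.array_equal(before["left"], after["left"])
        assert not np.array_equal(before["right"], after["right"])


class TestLossAndGradients:
    def test_perfect_reach_zero_loss(self, tiny_net_config, batch):
        import dataclasses

        tiny_net = BilateralNetwork(dataclasses.replace(tiny_net_config, l2=0.0), seed=3)
        images, hsp, _, _ = batch
        hands = tiny_net.predict_hands(images, hsp)
        loss = tiny_net.loss(images, hsp, hands["left"], hands["right"])
        assert loss == pytest.approx(0.0, abs=1e-24)

    def test_single_arm_error_contributes_d_squared(self, tiny_net_config, batch):
        import dataclasses

        tiny_net = BilateralNetwork(dataclasses.replace(tiny_net_config, l2=0.0), seed=3)
        images, hsp, _, _ = batch
        hands = tiny_net.predict_hands(images[:1], hsp[:1])
        off = hands["left"][0] + np.array([0.05, 0.0, 0.0])
        loss = tiny_net.loss(images[:1], hsp[:1], off[None, :], hands["right"][:1])
        assert loss == pytest.approx(0.05**2)

    def test_gradients_match_finite_differences(self, tiny_net, batch, rng):
        images, hsp, req_l, req_r = batch
        _, grads, _ = tiny_net.loss_and_grads(images, hsp, req_l, req_r)
        eps = 1e-6
        for name in ("conv1_L_W", "conv2_R_cross_W", "conv4_L_W", "fc6_R_W",
                     "fc7_L_cross_W", "fc8_R_W", "conv3_L_b", "fc7_R_b"):
            w = tiny_net.params[name]
            flat = list(np.ndindex(w.shape))
            n_probe = min(8, len(flat))
            for ix in [flat[i] for i in rng.choice(len(flat), size=n_probe, replace=False)]:
                orig = w[ix]
                w[ix] = orig + eps
                lp = tiny_net.loss(images, hsp, req_l, req_r)
                w[ix] = orig - eps
                lm = tiny_net.loss(images, hsp, req_l, req_r)
                w[ix] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(fd), abs(grads[name][ix]))
                assert abs(fd - grads[name][ix]) / denom < 1e-4, name


class TestTraining:
    def test_empty_dataset_rejected(self, tiny_net, tiny_dataset):
        empty = tiny_dataset.subset(np.zeros(len(tiny_dataset), dtype=bool))
        with pytest.raises(ValueError):
            tiny_net.train(empty, epochs=1)

    def test_empty_plasticity_mask_changes_nothing(self, tiny_net, tiny_dataset):
        small = _resized(tiny_net, tiny_dataset)
        before = {k: v.copy() for k, v in small.params.items()}
        small.train(tiny_dataset, epochs=1, seed=0, plasticity=PlasticityMask([]))
        assert all(np.array_equal(before[k], small.params[k]) for k in before)

    def test_mask_discipline(self, tiny_dataset):
        small = _resized(None, tiny_dataset)
        masked_out = [n for n in small.params if not n.startswith("fc7")]
        before = {k: small.params[k].copy() for k in masked_out}
        mask = PlasticityMask([n for n in small.params if n.startswith("fc7")])
        small.train(tiny_dataset, epochs=1, seed=0, plasticity=mask)
        for name in masked_out:
            assert np.array_equal(before[name], small.params[name]), name
        assert not np.array_equal(small.params["fc7_L_ipsi_W"], _resized(None, tiny_dataset).params["fc7_L_ipsi_W"])

    def test_identical_seeds_identical_weights(self, tiny_dataset):
        runs = []
        for _ in range(2):
            m = _resized(None, tiny_dataset)
            report = m.train(tiny_dataset, epochs=2, seed=7)
            runs.append((m, report))
        (m1, r1), (m2, r2) = runs
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)
        assert r1.epoch_loss == r2.epoch_loss
        assert len(r1.epoch_loss) == len(r1.epoch_re_left) == 2

    def test_loss_decreases_over_training(self, tiny_dataset):
        m = _resized(None, tiny_dataset)
        report = m.train(tiny_dataset, epochs=8, seed=1)
        assert report.epoch_loss[-1] < report.epoch_loss[0]


class TestCheckpoint:
    def test_roundtrip(self, tiny_dataset, tmp_path):
        m = _resized(None, tiny_dataset)
        m.train(tiny_dataset, epochs=1, seed=0)
        m.set_clamp("L", [0, 2])
        path = tmp_path / "model.ckpt.npz"
        m.save(path)
        loaded = type(m).load(path)
        assert all(np.array_equal(m.params[k], loaded.params[k]) for k in m.params)
        assert np.array_equal(m.keep["L"], loaded.keep["L"])
        out_a = m.forward(tiny_dataset.batch_images([0, 1]), tiny_dataset.hsp[[0, 1]])
        out_b = loaded.forward(tiny_dataset.batch_images([0, 1]), tiny_dataset.hsp[[0, 1]])
        assert np.array_equal(out_a["left"], out_b["left"])


def _resized(_unused, dataset):
    """A small network matching the tiny dataset's 16x16 resolution."""
    cfg = NetworkConfig(
        resolution=dataset.config.resolution,
        conv_maps=(1, 2, 2, 2, 1),
        fc_nodes=(8, 6, 6),
        batch_size=8,
        learning_rate=1e-3,
    )
    return BilateralNetwork(cfg, seed=5)
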