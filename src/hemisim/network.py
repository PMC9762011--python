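"""The bilaterally symmetric convolutional network driving the two arms.

Two mirror-image halves process the shared stereo image stack through five
convolutional layers and three fully connected layers each; the halves talk
to each other only through cross-connections at two levels (conv1 -> conv2
and fc6 -> fc7), the network's stand-in for callosal fibres.  Each half's
six sigmoid outputs are the agonist/antagonist muscle activations of the
ipsilateral arm, and training backpropagates the squared endpoint error of
both hands through the differentiable arm kinematics.

Layer sizes per half (feature maps / nodes): 2, 4, 8, 4, 2 convolutional
(5x5 kernels, stride 1, ReLU, a single 2x2 max-pool after layer 1) and
50, 30, 6 fully connected (sigmoid).  The two hand-selection bits enter at
fc6 on both halves.  The 30-node fc7 is the "penultimate" motor layer where
lesions are applied; an activation clamp forces selected nodes to zero on
every forward pass, and a structural zero-mask removes ablated callosal
weights from training permanently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .kinematics import (
    ArmGeometry,
    activations_to_angles,
    forward_kinematics,
    hand_jacobian,
    reaching_error,
)

HALVES = ("L", "R")
_CONTRA = {"L": "R", "R": "L"}
_ARM_OF_HALF = {"L": "left", "R": "right"}

#: The fc6 -> fc7 cross-connection weight blocks ("motor-side" callosal fibres).
MOTOR_CROSS_PARAMS = ("fc7_L_cross_W", "fc7_R_cross_W")
#: All cross-connection weight blocks (visual- and motor-side).
ALL_CROSS_PARAMS = ("conv2_L_cross_W", "conv2_R_cross_W") + MOTOR_CROSS_PARAMS


@dataclass(frozen=True)
class NetworkConfig:
    resolution: int = 64
    conv_maps: tuple = (2, 4, 8, 4, 2)
    kernel_size: int = 5
    fc_nodes: tuple = (50, 30, 6)
    learning_rate: float = 1e-4
    l2: float = 1e-4
    batch_size: int = 32
    optimizer: str = "adam"

    def __post_init__(self):
        if self.fc_nodes[-1] != 6:
            raise ValueError("output layer must have 6 nodes per half (6 muscles per arm)")
        if self.resolution % 2:
            raise ValueError("resolution must be even (2x2 pooling after layer 1)")

    @property
    def flat_features(self) -> int:
        return self.conv_maps[-1] * (self.resolution // 2) ** 2

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class TrainingReport:
    """Per-epoch mean endpoint loss and mean reaching error per arm."""

    epoch_loss: list = field(default_factory=list)
    epoch_re_left: list = field(default_factory=list)
    epoch_re_right: list = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""


class PlasticityMask:
    """Selection of trainable parameter blocks (by name)."""

    def __init__(self, names):
        self.names = frozenset(names)

    def __contains__(self, name):
        return name in self.names

    def __len__(self):
        return len(self.names)


class BilateralNetwork:
    """Split CNN with cross-connections; see module docstring."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        n7 = config.fc_nodes[1]
        # activation clamp: True = node alive.  Lesions clear entries.
        self.keep = {h: np.ones(n7, dtype=bool) for h in HALVES}
        # structural zeros in callosal weights (ablated, never retrained)
        self.cc_zero = {name: None for name in MOTOR_CROSS_PARAMS}
        self.lesion_state = None
        self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------ setup
    def _init_params(self, rng: np.random.Generator):
        cfg = self.config
        k2 = cfg.kernel_size**2
        m = cfg.conv_maps
        n6, n7, n8 = cfg.fc_nodes
        for h in HALVES:
            self._add(rng, f"conv1_{h}_W", 2 * k2, m[0])
            self.params[f"conv1_{h}_b"] = np.zeros(m[0])
            self._add(rng, f"conv2_{h}_ipsi_W", m[0] * k2, m[1])
            self._add(rng, f"conv2_{h}_cross_W", m[0] * k2, m[1])
            self.params[f"conv2_{h}_b"] = np.zeros(m[1])
            for i, (ci, co) in enumerate(zip(m[1:-1], m[2:]), start=3):
                self._add(rng, f"conv{i}_{h}_W", ci * k2, co)
                self.params[f"conv{i}_{h}_b"] = np.zeros(co)
            self._add(rng, f"fc6_{h}_W", cfg.flat_features + 2, n6)
            self.params[f"fc6_{h}_b"] = np.zeros(n6)
            self._add(rng, f"fc7_{h}_ipsi_W", n6, n7)
            self._add(rng, f"fc7_{h}_cross_W", n6, n7)
            self.params[f"fc7_{h}_b"] = np.zeros(n7)
            self._add(rng, f"fc8_{h}_W", n7, n8)
            self.params[f"fc8_{h}_b"] = np.zeros(n8)

    def _add(self, rng, name, fan_in, fan_out):
        self.params[name] = nn.glorot_init(rng, fan_in, fan_out, (fan_in, fan_out))

    # ----------------------------------------------------------------- basics
    @property
    def weight_names(self):
        return [k for k in self.params if k.endswith("_W")]

    def copy(self) -> "BilateralNetwork":
        clone = BilateralNetwork.__new__(BilateralNetwork)
        clone.config = self.config
        clone.seed = self.seed
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone.keep = {h: v.copy() for h, v in self.keep.items()}
        clone.cc_zero = {k: (None if v is None else v.copy()) for k, v in self.cc_zero.items()}
        clone.lesion_state = self.lesion_state
        return clone

    def set_clamp(self, half: str, node_indices) -> None:
        """Silence the given fc7 nodes of one half on every forward pass."""
        n7 = self.config.fc_nodes[1]
        idx = np.asarray(node_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n7):
            raise ValueError(f"clamp indices out of range for a {n7}-node layer")
        self.keep[half] = np.ones(n7, dtype=bool)
        self.keep[half][idx] = False

    def enforce_structural_zeros(self) -> None:
        for name, mask in self.cc_zero.items():
            if mask is not None:
                self.params[name][mask] = 0.0

    # ---------------------------------------------------------------- forward
    def forward(self, images: np.ndarray, hsp: np.ndarray, with_cache: bool = False):
        """Map a batch of stereo images + HSP bits to 6 activations per arm.

        Returns {'left': (B, 6), 'right': (B, 6)} of sigmoid outputs in (0, 1)
        (clamped fc7 nodes output exactly 0 upstream of fc8).
        """
        cfg = self.config
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (2, cfg.resolution, cfg.resolution):
            raise ValueError(
                f"expected images of shape (B, 2, {cfg.resolution}, {cfg.resolution}), got {x.shape}"
            )
        hsp = np.asarray(hsp, dtype=float).reshape(x.shape[0], 2)
        k = cfg.kernel_size
        p = self.params
        cache = {"x_shape": x.shape}
        pool, a6, a7 = {}, {}, {}
        # visual stack, per half
        for h in HALVES:
            z1, c1 = nn.conv2d_forward(x, p[f"conv1_{h}_W"], k)
            z1 += p[f"conv1_{h}_b"][None, :, None, None]
            a1, r1 = nn.relu_forward(z1)
            pl, cp = nn.maxpool2x2_forward(a1)
            pool[h] = pl
            cache[h] = {"conv1": c1, "relu1": r1, "pool": cp}
        for h in HALVES:
            z2i, c2i = nn.conv2d_forward(pool[h], p[f"conv2_{h}_ipsi_W"], k)
            z2x, c2x = nn.conv2d_forward(pool[_CONTRA[h]], p[f"conv2_{h}_cross_W"], k)
            z2 = z2i + z2x + p[f"conv2_{h}_b"][None, :, None, None]
            a, r2 = nn.relu_forward(z2)
            cache[h].update({"conv2_ipsi": c2i, "conv2_cross": c2x, "relu2": r2})
            for i in range(3, len(cfg.conv_maps) + 1):
                z, ci = nn.conv2d_forward(a, p[f"conv{i}_{h}_W"], k)
                z += p[f"conv{i}_{h}_b"][None, :, None, None]
                a, ri = nn.relu_forward(z)
                cache[h][f"conv{i}"] = ci
                cache[h][f"relu{i}"] = ri
            flat = a.reshape(a.shape[0], -1)
            f6in = np.concatenate([flat, hsp], axis=1)
            z6, c6 = nn.dense_forward(f6in, p[f"fc6_{h}_W"], p[f"fc6_{h}_b"])
            a6[h], s6 = nn.sigmoid_forward(z6)
            cache[h].update({"flat_shape": a.shape, "fc6": c6, "sig6": s6})
        out = {}
        for h in HALVES:
            z7i, c7i = nn.dense_forward(a6[h], p[f"fc7_{h}_ipsi_W"], p[f"fc7_{h}_b"])
            z7 = z7i + a6[_CONTRA[h]] @ p[f"fc7_{h}_cross_W"]
            s, s7 = nn.sigmoid_forward(z7)
            a7[h] = s * self.keep[h][None, :]
            z8, c8 = nn.dense_forward(a7[h], p[f"fc8_{h}_W"], p[f"fc8_{h}_b"])
            a8, s8 = nn.sigmoid_forward(z8)
            out[_ARM_OF_HALF[h]] = a8
            cache[h].update({"fc7": c7i, "a6": a6, "sig7": s7, "a7": a7[h], "fc8": c8, "sig8": s8})
        if with_cache:
            return out, cache
        return out

    def predict_hands(self, images, hsp):
        """Achieved hand positions per arm for a batch, shape (B, 3) each."""
        acts = self.forward(images, hsp)
        hands = {}
        for arm in ("left", "right"):
            geom = ArmGeometry.for_side(arm)
            hands[arm] = forward_kinematics(activations_to_angles(acts[arm]), geom).hand_position
        return hands

    # ------------------------------------------------------------------- loss
    def loss_and_grads(self, images, hsp, required_left, required_right):
        """Mean summed squared endpoint error of both arms + L2 penalty.

        Returns (loss, grads, per-arm reaching errors for the batch).
        """
        out, cache = self.forward(images, hsp, with_cache=True)
        b = out["left"].shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        required = {"left": np.asarray(required_left, float), "right": np.asarray(required_right, float)}
        loss = 0.0
        res = {}
        g_act = {}
        for arm in ("left", "right"):
            geom = ArmGeometry.for_side(arm)
            angles = activations_to_angles(out[arm])
            hand = forward_kinematics(angles, geom).hand_position
            r = hand - required[arm]
            loss += float(np.mean(np.sum(r * r, axis=1)))
            res[arm] = reaching_error(required[arm], hand)
            g_hand = 2.0 * r / b
            jac = hand_jacobian(angles, geom)  # (B, 3coord, 3angle)
            g_theta = np.einsum("bi,bij->bj", g_hand, jac)
            ga = np.empty_like(out[arm])
            ga[:, 0::2] = g_theta * (np.pi / 2)
            ga[:, 1::2] = -g_theta * (np.pi / 2)
            g_act[arm] = ga
        self._backward(g_act, cache, grads)
        # L2 regularization on weight matrices
        l2 = self.config.l2
        if l2:
            for name in self.weight_names:
                w = self.params[name]
                loss += l2 * float(np.sum(w * w))
                grads[name] += 2.0 * l2 * w
        return loss, grads, res

    def loss(self, images, hsp, required_left, required_right) -> float:
        value, _, _ = self.loss_and_grads(images, hsp, required_left, required_right)
        return value

    def _backward(self, g_act, cache, grads):
        p = self.params
        cfg = self.config
        g_a6 = {h: 0.0 for h in HALVES}
        for h in HALVES:
            ch = cache[h]
            g8 = nn.sigmoid_backward(g_act[_ARM_OF_HALF[h]], ch["sig8"])
            g_a7, gw8, gb8 = nn.dense_backward(g8, ch["fc8"])
            grads[f"fc8_{h}_W"] += gw8
            grads[f"fc8_{h}_b"] += gb8
            g_a7 = g_a7 * self.keep[h][None, :]
            g7 = nn.sigmoid_backward(g_a7, ch["sig7"])
            gx7, gw7, gb7 = nn.dense_backward(g7, ch["fc7"])
            grads[f"fc7_{h}_ipsi_W"] += gw7
            grads[f"fc7_{h}_b"] += gb7
            g_a6[h] = g_a6[h] + gx7
            grads[f"fc7_{h}_cross_W"] += ch["a6"][_CONTRA[h]].T @ g7
            g_a6[_CONTRA[h]] = g_a6[_CONTRA[h]] + g7 @ p[f"fc7_{h}_cross_W"].T
        g_pool = {h: 0.0 for h in HALVES}
        for h in HALVES:
            ch = cache[h]
            g6 = nn.sigmoid_backward(g_a6[h], ch["sig6"])
            gf6, gw6, gb6 = nn.dense_backward(g6, ch["fc6"])
            grads[f"fc6_{h}_W"] += gw6
            grads[f"fc6_{h}_b"] += gb6
            g = gf6[:, : cfg.flat_features].reshape(ch["flat_shape"])  # drop HSP columns
            for i in range(len(cfg.conv_maps), 2, -1):
                g = nn.relu_backward(g, ch[f"relu{i}"])
                grads[f"conv{i}_{h}_b"] += g.sum(axis=(0, 2, 3))
                g, gw = nn.conv2d_backward(g, ch[f"conv{i}"])
                grads[f"conv{i}_{h}_W"] += gw
            gz2 = nn.relu_backward(g, ch["relu2"])
            grads[f"conv2_{h}_b"] += gz2.sum(axis=(0, 2, 3))
            gpi, gwi = nn.conv2d_backward(gz2, ch["conv2_ipsi"])
            grads[f"conv2_{h}_ipsi_W"] += gwi
            g_pool[h] = g_pool[h] + gpi
            gpx, gwx = nn.conv2d_backward(gz2, ch["conv2_cross"])
            grads[f"conv2_{h}_cross_W"] += gwx
            g_pool[_CONTRA[h]] = g_pool[_CONTRA[h]] + gpx
        for h in HALVES:
            ch = cache[h]
            g_a1 = nn.maxpool2x2_backward(g_pool[h], ch["pool"])
            gz1 = nn.relu_backward(g_a1, ch["relu1"])
            grads[f"conv1_{h}_b"] += gz1.sum(axis=(0, 2, 3))
            _, gw1 = nn.conv2d_backward(gz1, ch["conv1"])
            grads[f"conv1_{h}_W"] += gw1

    # ------------------------------------------------------------------ train
    def train(self, dataset, epochs: int, seed: int = 0, plasticity: PlasticityMask | None = None,
              learning_rate: float | None = None) -> TrainingReport:
        """Seeded minibatch training; only masked parameters change.

        ``dataset`` is a ReachingDataset with rendered images.  The activation
        clamp and the structural callosal zeros persist throughout.
        """
        if len(dataset) == 0:
            raise ValueError("cannot train on an empty dataset")
        if epochs < 0:
            raise ValueError("epochs must be >= 0")
        cfg = self.config
        lr = cfg.learning_rate if learning_rate is None else learning_rate
        trainable = set(self.params) if plasticity is None else set(plasticity.names)
        sub = {k: self.params[k] for k in trainable}
        opt = nn.Adam(sub, lr) if cfg.optimizer == "adam" else nn.SGD(sub, lr)
        rng = np.random.default_rng(seed)
        report = TrainingReport(seed=seed, config_hash=cfg.hash())
        n = len(dataset)
        self.enforce_structural_zeros()
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, res_l, res_r = [], [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads, res = self.loss_and_grads(
                    dataset.batch_images(idx),
                    dataset.hsp[idx],
                    dataset.required_left[idx],
                    dataset.required_right[idx],
                )
                gsub = {k: grads[k] for k in trainable}
                for name, mask in self.cc_zero.items():
                    if mask is not None and name in gsub:
                        gsub[name][mask] = 0.0
                opt.step(sub, gsub)
                self.enforce_structural_zeros()
                losses.append(loss)
                res_l.append(float(np.mean(res["left"])))
                res_r.append(float(np.mean(res["right"])))
            report.epoch_loss.append(float(np.mean(losses)))
            report.epoch_re_left.append(float(np.mean(res_l)))
            report.epoch_re_right.append(float(np.mean(res_r)))
        return report

    # ------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "lesion_state": None if self.lesion_state is None else asdict(self.lesion_state),
            "format_version": 1,
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        arrays.update({f"keep::{h}": v for h, v in self.keep.items()})
        for name, mask in self.cc_zero.items():
            if mask is not None:
                arrays[f"cczero::{name}"] = mask
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "BilateralNetwork":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg_dict = meta["config"]
        cfg_dict["conv_maps"] = tuple(cfg_dict["conv_maps"])
        cfg_dict["fc_nodes"] = tuple(cfg_dict["fc_nodes"])
        model = cls(NetworkConfig(**cfg_dict), seed=meta["seed"])
        for key in data.files:
            if key.startswith("param::"):
                model.params[key[len("param::"):]] = data[key]
            elif key.startswith("keep::"):
                model.keep[key[len("keep::"):]] = data[key]
            elif key.startswith("cczero::"):
                model.cc_zero[key[len("cczero::"):]] = data[key]
        if meta["lesion_state"] is not None:
            from .lesion import LesionState

            ls = dict(meta["lesion_state"])
            ls["node_indices"] = tuple(ls["node_indices"])
            model.lesion_state = LesionState(**ls)
        return model
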