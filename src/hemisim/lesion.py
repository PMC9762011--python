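"""Stroke induction: acute lesions, chronic learned non-use, callosal damage.

An acute lesion silences the first ``n`` nodes of the left half's penultimate
(30-node) motor layer; the clamp persists through all later training, so
lesioned tissue never recovers.  A chronic model is obtained by retraining a
lesioned network for a few epochs on right-arm-only reaching (HSP [0 1]),
reproducing learned non-use: the idle paretic pathway drifts and left-arm
error grows beyond the acute level.  Callosal (corpus callosum) damage zeroes
a random fraction of the motor-side cross-connection weights structurally —
they are removed from every subsequent retraining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import MOTOR_CROSS_PARAMS, BilateralNetwork

LESION_SIZES = (5, 10, 15, 20)
CC_INTEGRITIES = (0.5, 0.7, 0.9)
DEFAULT_NONUSE_EPOCHS = 10


@dataclass(frozen=True)
class LesionState:
    """Which nodes are silenced, the recovery stage, and callosal integrity."""

    size: int
    node_indices: tuple
    side: str = "left"
    stage: str = "acute"
    cc_integrity: float = 1.0
    seed: int = 0


def apply_lesion(model: BilateralNetwork, n: int) -> BilateralNetwork:
    """Silence nodes 1..n of the left half's penultimate layer (acute stroke).

    Returns a new model; the input model is untouched.  The same site is
    lesioned for every model so impairment is comparable across seeds.
    """
    n7 = model.config.fc_nodes[1]
    if not 0 <= n <= n7:
        raise ValueError(f"lesion size must be in [0, {n7}], got {n}")
    lesioned = model.copy()
    idx = tuple(range(n))
    lesioned.set_clamp("L", idx)
    lesioned.lesion_state = LesionState(size=n, node_indices=idx, stage="acute")
    return lesioned


def induce_chronic(
    model: BilateralNetwork,
    nonuse_dataset,
    nonuse_epochs: int = DEFAULT_NONUSE_EPOCHS,
    seed: int = 0,
) -> BilateralNetwork:
    """Model learned non-use: retrain on right-arm-only (HSP [0 1]) reaching.

    ``nonuse_dataset`` must contain only HSP [0 1] samples (right arm to the
    target, left arm to its home position).  All unclamped, unablated weights
    train during this phase — it models everyday use, not therapy.
    """
    if model.lesion_state is None:
        warnings.warn("inducing chronic non-use on an un-lesioned model", stacklevel=2)
    if np.any(nonuse_dataset.hsp[:, 0] != 0) or np.any(nonuse_dataset.hsp[:, 1] != 1):
        raise ValueError("non-use dataset must contain only HSP [0 1] samples")
    chronic = model.copy()
    if nonuse_epochs > 0:
        chronic.train(nonuse_dataset, epochs=nonuse_epochs, seed=seed)
    prev = chronic.lesion_state
    if prev is not None:
        chronic.lesion_state = LesionState(
            size=prev.size,
            node_indices=prev.node_indices,
            side=prev.side,
            stage="chronic",
            cc_integrity=prev.cc_integrity,
            seed=prev.seed,
        )
    return chronic


def degrade_cc(model: BilateralNetwork, integrity: float, seed: int = 0) -> BilateralNetwork:
    """Structurally zero a random (1 - integrity) fraction of the motor-side
    cross-connections (fc6 -> fc7 blocks, both directions).

    The zeroed weights are excluded from all subsequent retraining.  Only the
    motor-side callosal block is degraded; visual-side cross-connections are
    left intact.
    """
    if not 0.0 < integrity <= 1.0:
        raise ValueError("integrity must lie in (0, 1]")
    degraded = model.copy()
    sizes = [degraded.params[name].size for name in MOTOR_CROSS_PARAMS]
    total = int(sum(sizes))
    n_zero = int(np.floor((1.0 - integrity) * total))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_zero, replace=False)
    offset = 0
    for name, size in zip(MOTOR_CROSS_PARAMS, sizes):
        local = chosen[(chosen >= offset) & (chosen < offset + size)] - offset
        mask = np.zeros(size, dtype=bool)
        mask[local] = True
        mask = mask.reshape(degraded.params[name].shape)
        prev = degraded.cc_zero.get(name)
        degraded.cc_zero[name] = mask if prev is None else (mask | prev)
        offset += size
    degraded.enforce_structural_zeros()
    prev_state = degraded.lesion_state
    if prev_state is not None:
        degraded.lesion_state = LesionState(
            size=prev_state.size,
            node_indices=prev_state.node_indices,
            side=prev_state.side,
            stage=prev_state.stage,
            cc_integrity=integrity,
            seed=seed,
        )
    return degraded
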