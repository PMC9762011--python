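"""Two-link arm kinematics: muscle activations -> joint angles -> hand position.

Each arm has three degrees of freedom (shoulder flexion, shoulder rotation,
elbow flexion), each driven by an agonist/antagonist muscle pair.  The map
from the six activations of one arm to the 3D hand endpoint is closed-form
trigonometry; an analytic Jacobian is provided so that endpoint error can be
backpropagated through the arm into the controlling network.

Conventions
-----------
* Workspace origin at the hollow of the neck; shoulders at x = +/-0.15,
  upper arm and forearm 0.3 units each (total arm length 0.6).
* Joint angle theta = (MN_ag - MN_an) * pi/2 + pi/2 for every degree of
  freedom, so activations in [0, 1] give angles in [0, pi] and equal
  activations give the neutral pi/2.
* Rotations compose shoulder-relatively in row-vector order
  ``[(H_o-E_o)RotE + (E_o-S_o)] RotS1 RotS2 + S_o`` so that zero angles
  reproduce the rest configuration (hand at (+/-0.15, 0, 0.6)).
* Shoulder flexion is measured toward the front of the workspace (+y); see
  docs/methods.md for why this sign convention is the self-consistent one.
  At neutral activations (all 0.5) the hand sits at the home position
  (+/-0.15, 0.3, 0.3).

Activation vector layout per arm: ``[ag_S1, an_S1, ag_S2, an_S2, ag_E, an_E]``;
angle vector layout: ``[theta_S1, theta_S2, theta_E]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UPPER_ARM_LENGTH = 0.3
FOREARM_LENGTH = 0.3
ARM_LENGTH = UPPER_ARM_LENGTH + FOREARM_LENGTH
SHOULDER_HALF_WIDTH = 0.15

SIDES = ("left", "right")


def _side_sign(side: str) -> float:
    if side == "right":
        return 1.0
    if side == "left":
        return -1.0
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(frozen=True)
class ArmGeometry:
    """Rest configuration of one arm (all segment vectors in workspace units)."""

    side: str
    shoulder_origin: np.ndarray = field(default=None)
    elbow_rest: np.ndarray = field(default=None)
    hand_rest: np.ndarray = field(default=None)
    upper_arm_length: float = UPPER_ARM_LENGTH
    forearm_length: float = FOREARM_LENGTH

    def __post_init__(self):
        s = _side_sign(self.side)
        if self.shoulder_origin is None:
            object.__setattr__(self, "shoulder_origin", np.array([s * SHOULDER_HALF_WIDTH, 0.0, 0.0]))
        if self.elbow_rest is None:
            object.__setattr__(self, "elbow_rest", self.shoulder_origin + [0.0, 0.0, self.upper_arm_length])
        if self.hand_rest is None:
            object.__setattr__(self, "hand_rest", self.elbow_rest + [0.0, 0.0, self.forearm_length])

    @classmethod
    def for_side(cls, side: str) -> "ArmGeometry":
        return cls(side=side)


@dataclass(frozen=True)
class ArmPose:
    """Joint angles plus resulting elbow and hand positions for one arm."""

    angles: np.ndarray
    elbow_position: np.ndarray
    hand_position: np.ndarray


def activations_to_angles(activations: np.ndarray) -> np.ndarray:
    """Map the six muscle activations of one arm to its three joint angles.

    theta = (ag - an) * pi/2 + pi/2, elementwise over the three
    agonist/antagonist pairs.  Accepts any leading batch shape; the last axis
    must be 6 and all values must lie in [0, 1].
    """
    act = np.asarray(activations, dtype=float)
    if act.shape[-1] != 6:
        raise ValueError(f"expected 6 activations per arm, got shape {act.shape}")
    if np.any(act < 0.0) or np.any(act > 1.0):
        raise ValueError("muscle activations must lie in [0, 1]")
    ag = act[..., 0::2]
    an = act[..., 1::2]
    return (ag - an) * (np.pi / 2) + np.pi / 2


def _rel_positions(angles: np.ndarray, geometry: ArmGeometry):
    """Hand and elbow positions relative to the shoulder, vectorised."""
    th = np.asarray(angles, dtype=float)
    s1, c1 = np.sin(th[..., 0]), np.cos(th[..., 0])
    s2, c2 = np.sin(th[..., 1]), np.cos(th[..., 1])
    se, ce = np.sin(th[..., 2]), np.cos(th[..., 2])
    lf, lu = geometry.forearm_length, geometry.upper_arm_length
    sign = _side_sign(geometry.side)

    # forearm rotated about the elbow, expressed in the shoulder frame
    p = lf * se
    q = lu + lf * ce
    # shoulder flexion (toward +y front), then shoulder rotation about z
    a = p * c1 - q * s1
    c = p * s1 + q * c1
    hand = np.stack([sign * a * c2, -a * s2, c], axis=-1)
    ae = -lu * s1
    ce_ = lu * c1
    elbow = np.stack([sign * ae * c2, -ae * s2, ce_], axis=-1)
    return hand, elbow


def forward_kinematics(angles: np.ndarray, geometry: ArmGeometry) -> ArmPose:
    """Compute elbow and hand positions from joint angles (batched).

    Angles outside [0, pi] violate the activation contract and are rejected.
    """
    th = np.asarray(angles, dtype=float)
    if th.shape[-1] != 3:
        raise ValueError(f"expected 3 joint angles, got shape {th.shape}")
    if np.any(th < -1e-12) or np.any(th > np.pi + 1e-12):
        raise ValueError("joint angles must lie in [0, pi]")
    hand_rel, elbow_rel = _rel_positions(th, geometry)
    return ArmPose(
        angles=th,
        elbow_position=elbow_rel + geometry.shoulder_origin,
        hand_position=hand_rel + geometry.shoulder_origin,
    )


def hand_jacobian(angles: np.ndarray, geometry: ArmGeometry) -> np.ndarray:
    """Analytic Jacobian d(hand)/d(angles), shape (..., 3, 3).

    Row i is the hand coordinate, column j the joint angle
    (theta_S1, theta_S2, theta_E).  Used to backpropagate endpoint error
    through the arm during network training.
    """
    th = np.asarray(angles, dtype=float)
    s1, c1 = np.sin(th[..., 0]), np.cos(th[..., 0])
    s2, c2 = np.sin(th[..., 1]), np.cos(th[..., 1])
    se, ce = np.sin(th[..., 2]), np.cos(th[..., 2])
    lf, lu = geometry.forearm_length, geometry.upper_arm_length
    sign = _side_sign(geometry.side)

    p = lf * se
    q = lu + lf * ce
    a = p * c1 - q * s1
    c = p * s1 + q * c1
    dp_de = lf * ce
    dq_de = -lf * se
    da_d1 = -c
    dc_d1 = a
    da_de = dp_de * c1 - dq_de * s1
    dc_de = dp_de * s1 + dq_de * c1

    zeros = np.zeros_like(a)
    jac = np.stack(
        [
            np.stack([sign * da_d1 * c2, sign * (-a) * s2, sign * da_de * c2], axis=-1),
            np.stack([-da_d1 * s2, -a * c2, -da_de * s2], axis=-1),
            np.stack([dc_d1, zeros, dc_de], axis=-1),
        ],
        axis=-2,
    )
    return jac


def reaching_error(target: np.ndarray, hand: np.ndarray) -> np.ndarray:
    """Euclidean distance between target and achieved hand position (batched)."""
    t = np.asarray(target, dtype=float)
    x = np.asarray(hand, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValueError("reaching_error requires finite coordinates")
    return np.linalg.norm(t - x, axis=-1)


def home_endpoint(side: str) -> np.ndarray:
    """Hand position at neutral activations (all 0.5): the arm's home pose."""
    geom = ArmGeometry.for_side(side)
    angles = activations_to_angles(np.full(6, 0.5))
    return forward_kinematics(angles, geom).hand_position


HOME_LEFT = home_endpoint("left")
HOME_RIGHT = home_endpoint("right")
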