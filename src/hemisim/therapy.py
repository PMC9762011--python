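"""Rehabilitation protocols: the complexity x hand-mode x plasticity grid.

Movement complexity contrasts a *stereotypic* workspace (a small box of M
unique targets, each presented N times — task-oriented repetitive practice)
with an *exploratory* workspace (the paretic arm's full workspace,
300 distinct targets).  Hand-selection mode contrasts CIMT (HSP [1 0], only
the paretic left arm moves) with BMT (HSP [1 1], both arms reach the same
target).  Plasticity extent contrasts *local* retraining (only the afferent
connections of the lesioned penultimate layer) with *global* retraining (the
whole network).  Both protocols present P = 300 targets in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MOTOR_CROSS_PARAMS, BilateralNetwork, PlasticityMask, TrainingReport
from .scene import SceneConfig, ReachingDataset, TargetSpec, render_stereo, required_endpoints

# Printed therapy workspace bounds per side.
STEREOTYPIC_BOUNDS = {
    "left": ((-0.3, -0.2), (0.25, 0.35), (0.05, 0.15)),
    "right": ((0.1, 0.2), (0.25, 0.35), (0.05, 0.15)),
}
EXPLORATORY_BOUNDS = {
    "left": ((-0.6, 0.0), (0.0, 0.6), (-0.1, 0.5)),
    "right": ((0.0, 0.6), (0.0, 0.6), (-0.1, 0.5)),
}

HAND_MODE_HSP = {"cimt": (1, 0), "bmt": (1, 1)}


@dataclass(frozen=True)
class TherapyConfig:
    complexity: str = "exploratory"       # 'stereotypic' | 'exploratory'
    hand_mode: str = "cimt"               # 'cimt' (HSP [1 0]) | 'bmt' (HSP [1 1])
    plasticity: str = "local"             # 'local' | 'global'
    total_points: int = 300               # P: presentations per protocol
    unique_points: int = 30               # M (stereotypic only)
    repetitions: int = 10                 # N (stereotypic only); M*N must equal P
    rehab_epochs: int = 10
    seed: int = 0
    side: str = "left"                    # paretic side whose workspace is used

    def __post_init__(self):
        if self.complexity not in ("stereotypic", "exploratory"):
            raise ValueError(f"unknown complexity {self.complexity!r}")
        if self.hand_mode not in HAND_MODE_HSP:
            raise ValueError(f"unknown hand mode {self.hand_mode!r}")
        if self.plasticity not in ("local", "global"):
            raise ValueError(f"unknown plasticity {self.plasticity!r}")

    @property
    def hsp(self):
        return HAND_MODE_HSP[self.hand_mode]


def sample_therapy_targets(config: TherapyConfig) -> np.ndarray:
    """Target presentations for one protocol, shape (P, 3).

    Stereotypic: M unique positions in the small stereotypic box, each repeated N
    times (M*N = P).  Exploratory: P distinct positions over the full exploratory
    workspace of the paretic side.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    if config.complexity == "stereotypic":
        if config.unique_points * config.repetitions != config.total_points:
            raise ValueError("stereotypic therapy requires unique_points * repetitions == total_points")
        box = np.asarray(STEREOTYPIC_BOUNDS[config.side], dtype=float)
        unique = rng.uniform(box[:, 0], box[:, 1], size=(config.unique_points, 3))
        return np.tile(unique, (config.repetitions, 1))
    box = np.asarray(EXPLORATORY_BOUNDS[config.side], dtype=float)
    return rng.uniform(box[:, 0], box[:, 1], size=(config.total_points, 3))


def build_plasticity_mask(model: BilateralNetwork, extent: str) -> PlasticityMask:
    """Parameter blocks retrained during therapy.

    ``local``: only the afferent connections of the lesioned (penultimate)
    layer — the ipsilateral and cross fc6->fc7 weight blocks and the fc7
    bias of the lesioned half.  ``global``: every parameter.  Structurally
    ablated callosal entries stay frozen in either case (enforced
    elementwise during the update).
    """
    if extent == "global":
        return PlasticityMask(model.params.keys())
    if extent != "local":
        raise ValueError(f"unknown plasticity extent {extent!r}")
    side = "left" if model.lesion_state is None else model.lesion_state.side
    h = {"left": "L", "right": "R"}[side]
    names = [f"fc7_{h}_{kind}" for kind in ("ipsi_W", "cross_W", "b")]
    assert any(n in MOTOR_CROSS_PARAMS for n in names)
    return PlasticityMask(names)


def build_therapy_dataset(config: TherapyConfig, scene: SceneConfig) -> ReachingDataset:
    """Render the therapy presentations with the protocol's fixed HSP.

    Colour/size variants cycle over presentations so therapy, like training,
    is not tied to one sphere appearance.
    """
    targets = sample_therapy_targets(config)
    n = len(targets)
    variants = np.arange(n) % scene.n_variants
    hsp = np.tile(np.asarray(config.hsp, dtype=int), (n, 1))
    req_l = np.empty((n, 3))
    req_r = np.empty((n, 3))
    images = np.empty((n, 2, scene.resolution, scene.resolution))
    for i in range(n):
        req_l[i], req_r[i] = required_endpoints(config.hsp, targets[i])
        spec = TargetSpec(position=targets[i], colour_id=int(variants[i]), size_id=int(variants[i]))
        images[i] = render_stereo(spec, scene)
    if config.complexity == "stereotypic":
        position_ids = np.arange(n) % config.unique_points
    else:
        position_ids = np.arange(n)
    return ReachingDataset(
        positions=targets,
        position_ids=position_ids,
        variants=variants,
        hsp=hsp,
        required_left=req_l,
        required_right=req_r,
        image_index=np.arange(n),
        images=images,
        config=scene,
    )


def rehabilitate(
    model: BilateralNetwork,
    config: TherapyConfig,
    scene: SceneConfig,
) -> tuple[BilateralNetwork, TrainingReport]:
    """Retrain a lesioned model under one therapy protocol.

    The lesion clamp and any callosal ablation are preserved; only the
    parameters selected by the plasticity extent change.  Returns a new
    model and the training report.
    """
    rehabbed = model.copy()
    mask = build_plasticity_mask(rehabbed, config.plasticity)
    if config.rehab_epochs == 0:
        return rehabbed, TrainingReport(seed=config.seed, config_hash=rehabbed.config.hash())
    dataset = build_therapy_dataset(config, scene)
    report = rehabbed.train(
        dataset, epochs=config.rehab_epochs, seed=config.seed, plasticity=mask
    )
    return rehabbed, report
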