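"""High-level experiment plumbing: profiles, seeded contexts, sweep cells.

A *profile* bundles the scene and network configuration with the dataset
sizes and epoch budgets that define one experimental scale.  The default
profile mirrors the study conditions (64x64 stereo views, 1174 training and
450 test positions, 30 healthy epochs); the desk profile is a documented
scaled-down replica (smaller images, fewer targets) whose relative effects —
lesion-size monotonicity, therapy orderings — reproduce the full-scale ones
at workstation cost.

The target grids are fixed study conditions (their seeds live in the
profile); model weight initialisation and every retraining phase derive
their randomness from the per-model base seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .lesion import DEFAULT_NONUSE_EPOCHS, apply_lesion, degrade_cc, induce_chronic
from .network import BilateralNetwork, NetworkConfig
from .scene import (
    ALL_HSP_MODES,
    DEFAULT_N_TEST,
    DEFAULT_N_TRAIN,
    HSP_RIGHT,
    TRAINING_BOUNDS,
    SceneConfig,
    build_dataset,
    sample_target_grid,
)
from .therapy import TherapyConfig, rehabilitate

HEALTHY_EPOCHS = 30


def _mix(seed: int, tag: int) -> int:
    """Derive a sub-seed < 2**31 from a base seed and a phase tag."""
    return (seed * 1_000_003 + tag * 7919 + 12345) % (2**31)


@dataclass(frozen=True)
class Profile:
    scene: SceneConfig = field(default_factory=SceneConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_train: int = DEFAULT_N_TRAIN
    n_test: int = DEFAULT_N_TEST
    healthy_epochs: int = HEALTHY_EPOCHS
    nonuse_epochs: int = DEFAULT_NONUSE_EPOCHS
    train_grid_seed: int = 1000
    test_grid_seed: int = 2000

    def __post_init__(self):
        if self.scene.resolution != self.network.resolution:
            raise ValueError("scene and network resolutions must match")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def default_profile() -> Profile:
    """The full-scale study conditions."""
    return Profile()


def desk_profile(resolution: int = 16, n_train: int = 150, n_test: int = 150) -> Profile:
    """Scaled-down replica for workstation-speed experiments and tests.

    Images shrink to 16x16 and the grids to 150 positions; the epoch budgets
    and their ratios (30 healthy / 10 non-use / 10 rehab) are unchanged.  The
    Adam step size is raised to 1e-3 because the scaled grid offers roughly
    an eighth of the full profile's gradient steps per epoch; see
    docs/methods.md.
    """
    return Profile(
        scene=SceneConfig(resolution=resolution),
        network=NetworkConfig(resolution=resolution, learning_rate=1e-3),
        n_train=n_train,
        n_test=n_test,
    )


def build_training_set(profile: Profile, render: bool = True):
    positions = sample_target_grid(profile.n_train, TRAINING_BOUNDS, seed=profile.train_grid_seed)
    return build_dataset(positions, profile.scene.n_variants, ALL_HSP_MODES, profile.scene, render=render)


def build_test_set(profile: Profile, render: bool = True):
    positions = sample_target_grid(profile.n_test, TRAINING_BOUNDS, seed=profile.test_grid_seed)
    return build_dataset(positions, profile.scene.n_variants, ALL_HSP_MODES, profile.scene, render=render)


def train_healthy(profile: Profile, seed: int, dataset=None) -> BilateralNetwork:
    """Train a healthy model from a seeded random initialisation."""
    if dataset is None:
        dataset = build_training_set(profile)
    model = BilateralNetwork(profile.network, seed=seed)
    model.train(dataset, epochs=profile.healthy_epochs, seed=_mix(seed, 1))
    return model


@dataclass
class SeedContext:
    """Everything one base seed needs: healthy model, datasets, model cache."""

    profile: Profile
    seed: int
    healthy: BilateralNetwork
    train_set: object
    test_set: object
    nonuse_set: object
    _impaired: dict = field(default_factory=dict)

    @classmethod
    def create(cls, profile: Profile, seed: int) -> "SeedContext":
        train_set = build_training_set(profile)
        test_set = build_test_set(profile)
        healthy = train_healthy(profile, seed, dataset=train_set)
        nonuse = train_set.subset(
            (train_set.hsp[:, 0] == HSP_RIGHT[0]) & (train_set.hsp[:, 1] == HSP_RIGHT[1])
        )
        return cls(
            profile=profile,
            seed=seed,
            healthy=healthy,
            train_set=train_set,
            test_set=test_set,
            nonuse_set=nonuse,
        )

    def impaired(self, stage: str, n_lesion: int, integrity: float) -> BilateralNetwork:
        """Lesioned (and possibly chronic / CC-degraded) model, cached per condition."""
        key = (stage, n_lesion, round(integrity, 6))
        if key not in self._impaired:
            model = apply_lesion(self.healthy, n_lesion)
            if integrity < 1.0:
                model = degrade_cc(model, integrity, seed=_mix(self.seed, 2))
            if stage == "chronic":
                model = induce_chronic(
                    model,
                    self.nonuse_set,
                    nonuse_epochs=self.profile.nonuse_epochs,
                    seed=_mix(self.seed, 3),
                )
            elif stage != "acute":
                raise ValueError(f"unknown stage {stage!r}")
            self._impaired[key] = model
        return self._impaired[key]


def run_cell(ctx: SeedContext, stage: str, n_lesion: int, integrity: float, therapy: TherapyConfig) -> dict:
    """Rehabilitate one impaired model under one therapy and score it."""
    from .evaluation import evaluate

    impaired = ctx.impaired(stage, n_lesion, integrity)
    therapy = dataclasses.replace(therapy, seed=_mix(ctx.seed, 4))
    rehabbed, _ = rehabilitate(impaired, therapy, ctx.profile.scene)
    result = evaluate(rehabbed, ctx.test_set)
    _, n_inaccessible = result.accessibility("left")
    return {
        "seed": ctx.seed,
        "stage": stage,
        "lesion_size": n_lesion,
        "cc_integrity": integrity,
        "complexity": therapy.complexity,
        "hand_mode": therapy.hand_mode,
        "plasticity": therapy.plasticity,
        "mean_re_left": result.mean_re_left,
        "mean_re_right": result.mean_re_right,
        "n_inaccessible": n_inaccessible,
    }
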