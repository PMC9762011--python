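"""Synthetic stereo scenes: a shaded sphere at a 3D target position.

Replaces an external 3D renderer with an analytic pinhole model while keeping
the visual cues that carry the target position: image-plane location of the
sphere, perspective size scaling with distance, binocular disparity between
the two laterally shifted cameras, and a diffuse shading gradient standing in
for glare/shadow.  Colour is encoded as a per-variant intensity level (each
view is a single grey channel).

The module also assembles datasets: each sample couples a stereo image pair
with the two binary hand-selection parameters (HSPs) and the endpoint each
arm is required to reach (the target for an active arm, the arm's home
position otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import HOME_LEFT, HOME_RIGHT

# Printed exploratory workspace bounds, (x, y, z) intervals per side.
LEFT_EXPLORATORY_BOUNDS = ((-0.6, 0.0), (0.0, 0.6), (-0.1, 0.5))
RIGHT_EXPLORATORY_BOUNDS = ((0.0, 0.6), (0.0, 0.6), (-0.1, 0.5))
#: Default training/test region: union of the left and right workspaces.
TRAINING_BOUNDS = (LEFT_EXPLORATORY_BOUNDS, RIGHT_EXPLORATORY_BOUNDS)

# Hand-selection parameters (hsp1 gates the left arm, hsp2 the right arm).
HSP_REST = (0, 0)
HSP_RIGHT = (0, 1)
HSP_LEFT = (1, 0)
HSP_BIMANUAL = (1, 1)
ALL_HSP_MODES = (HSP_REST, HSP_RIGHT, HSP_LEFT, HSP_BIMANUAL)
ACTIVE_HSP_MODES = (HSP_RIGHT, HSP_LEFT, HSP_BIMANUAL)

DEFAULT_N_TRAIN = 1174
DEFAULT_N_TEST = 450


@dataclass(frozen=True)
class CameraConfig:
    """Two pinhole cameras looking along +y from behind the shoulder plane."""

    baseline: float = 0.06          # interocular distance; cameras at x = +/- baseline/2
    y_position: float = -0.5
    z_position: float = 0.2
    focal_scale: float = 0.375      # focal length in pixels = focal_scale * image width


@dataclass(frozen=True)
class SceneConfig:
    resolution: int = 64
    n_variants: int = 3
    sphere_radii: tuple = (0.06, 0.08, 0.10)
    colour_levels: tuple = (1.0, 0.75, 0.5)
    camera: CameraConfig = field(default_factory=CameraConfig)
    light_direction: tuple = (-0.45, -0.6, 0.66)
    ambient: float = 0.3


@dataclass(frozen=True)
class TargetSpec:
    position: np.ndarray
    colour_id: int = 0
    size_id: int = 0


def project_target(position, camera_x: float, config: SceneConfig):
    """Pinhole projection of a 3D point onto one camera's image plane.

    Returns (u, v, depth) in pixel units; u grows rightward, v downward, the
    principal point is the image centre.  Raises if the point is at or behind
    the camera plane.
    """
    x, y, z = np.asarray(position, dtype=float)
    cam = config.camera
    depth = y - cam.y_position
    if depth <= 1e-6:
        raise ValueError("target lies at or behind the camera plane")
    f = cam.focal_scale * config.resolution
    half = (config.resolution - 1) / 2.0
    u = half + f * (x - camera_x) / depth
    v = half - f * (z - cam.z_position) / depth
    return u, v, depth


def projected_radius(position, camera_x: float, config: SceneConfig, size_id: int) -> float:
    """Apparent sphere radius in pixels (perspective scaling ~ 1/depth)."""
    _, _, depth = project_target(position, camera_x, config)
    f = config.camera.focal_scale * config.resolution
    return f * config.sphere_radii[size_id % len(config.sphere_radii)] / depth


def _render_view(target: TargetSpec, camera_x: float, config: SceneConfig) -> np.ndarray:
    u, v, depth = project_target(target.position, camera_x, config)
    r_px = projected_radius(target.position, camera_x, config, target.size_id)
    level = config.colour_levels[target.colour_id % len(config.colour_levels)]
    n = config.resolution
    vv, uu = np.mgrid[0:n, 0:n].astype(float)
    du, dv = uu - u, vv - v
    dist = np.hypot(du, dv)
    coverage = np.clip(r_px - dist + 0.5, 0.0, 1.0)  # antialiased disc edge
    # Lambert shading of the visible hemisphere for a distant light source.
    rho = np.clip(dist / max(r_px, 1e-9), 0.0, 1.0)
    nx = np.where(dist > 0, du / np.maximum(dist, 1e-9), 0.0) * rho
    ny = np.where(dist > 0, dv / np.maximum(dist, 1e-9), 0.0) * rho
    nz = np.sqrt(np.clip(1.0 - rho**2, 0.0, 1.0))
    light = np.asarray(config.light_direction, dtype=float)
    light = light / np.linalg.norm(light)
    lambert = np.clip(nx * light[0] + ny * light[1] + nz * light[2], 0.0, 1.0)
    shade = config.ambient + (1.0 - config.ambient) * lambert
    return (level * shade * coverage).astype(np.float64)


def render_stereo(target: TargetSpec, config: SceneConfig = SceneConfig()) -> np.ndarray:
    """Render the left/right camera views of one target, shape (2, H, W)."""
    cam = config.camera
    left = _render_view(target, -cam.baseline / 2.0, config)
    right = _render_view(target, +cam.baseline / 2.0, config)
    return np.stack([left, right])


def sample_target_grid(n_positions: int, bounds=TRAINING_BOUNDS, seed: int = 0) -> np.ndarray:
    """Draw target positions uniformly inside one box or a union of boxes.

    ``bounds`` is either a single ((x0,x1),(y0,y1),(z0,z1)) box or a sequence
    of such boxes; boxes are chosen with probability proportional to volume.
    Deterministic for a fixed seed.
    """
    if n_positions < 0:
        raise ValueError("n_positions must be >= 0")
    boxes = np.asarray(bounds, dtype=float)
    if boxes.ndim == 2:
        boxes = boxes[None, :, :]
    if boxes.shape[1:] != (3, 2) or np.any(boxes[:, :, 1] <= boxes[:, :, 0]):
        raise ValueError("bounds must be well-ordered (lo < hi) on every axis")
    if n_positions == 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(seed)
    volumes = np.prod(boxes[:, :, 1] - boxes[:, :, 0], axis=1)
    choice = rng.choice(len(boxes), size=n_positions, p=volumes / volumes.sum())
    u = rng.uniform(size=(n_positions, 3))
    lo, hi = boxes[choice, :, 0], boxes[choice, :, 1]
    return lo + u * (hi - lo)


def required_endpoints(hsp, position):
    """Table of hand-selection semantics: target for an active arm, home otherwise."""
    hsp1, hsp2 = hsp
    left = np.asarray(position, dtype=float) if hsp1 else HOME_LEFT
    right = np.asarray(position, dtype=float) if hsp2 else HOME_RIGHT
    return left, right


def fold_to_side(positions: np.ndarray, side: str) -> np.ndarray:
    """Reflect targets across the midsagittal plane into one arm's workspace.

    The left and right workspaces are exact x-mirror images, so a
    unimanual task presents its target on the active arm's side: x -> -|x|
    for the left arm, x -> +|x| for the right.  y and z are unchanged.
    """
    p = np.array(positions, dtype=float, copy=True)
    if side == "left":
        p[..., 0] = -np.abs(p[..., 0])
    elif side == "right":
        p[..., 0] = np.abs(p[..., 0])
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return p


@dataclass
class ReachingDataset:
    """Samples = target positions x colour/size variants x HSP modes.

    ``positions`` holds each sample's *scene* target (after any side-folding
    for unimanual modes); ``position_ids`` identifies the underlying grid
    position.  Images are stored once per distinct (scene target, variant)
    and shared across samples through ``image_index``.
    """

    positions: np.ndarray        # (n_samples, 3)
    position_ids: np.ndarray     # (n_samples,)
    variants: np.ndarray         # (n_samples,)
    hsp: np.ndarray              # (n_samples, 2)
    required_left: np.ndarray    # (n_samples, 3)
    required_right: np.ndarray   # (n_samples, 3)
    image_index: np.ndarray      # (n_samples,)
    images: np.ndarray | None    # (n_images, 2, H, W) or None if not rendered
    config: SceneConfig

    def __len__(self) -> int:
        return len(self.positions)

    def batch_images(self, idx) -> np.ndarray:
        if self.images is None:
            raise ValueError("dataset was built without rendered images")
        return self.images[self.image_index[idx]]

    def subset(self, mask) -> "ReachingDataset":
        idx = np.flatnonzero(mask)
        return ReachingDataset(
            positions=self.positions[idx],
            position_ids=self.position_ids[idx],
            variants=self.variants[idx],
            hsp=self.hsp[idx],
            required_left=self.required_left[idx],
            required_right=self.required_right[idx],
            image_index=self.image_index[idx],
            images=self.images,
            config=self.config,
        )

    def without_rest_mode(self) -> "ReachingDataset":
        """Drop HSP [0 0] samples (both arms at rest), as in the stroke analyses."""
        return self.subset(~np.all(self.hsp == 0, axis=1))

    def manifest(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": np.arange(len(self)),
                "position_id": self.position_ids,
                "target_x": self.positions[:, 0],
                "target_y": self.positions[:, 1],
                "target_z": self.positions[:, 2],
                "variant": self.variants,
                "colour_id": self.variants % len(self.config.colour_levels),
                "size_id": self.variants % len(self.config.sphere_radii),
                "hsp1": self.hsp[:, 0],
                "hsp2": self.hsp[:, 1],
            }
        )
        for name, arr in (("req_left", self.required_left), ("req_right", self.required_right)):
            for j, ax in enumerate("xyz"):
                df[f"{name}_{ax}"] = arr[:, j]
        return df

    def save(self, directory):
        """Write the manifest as CSV and (if rendered) images as an .npz array."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.manifest().to_csv(d / "manifest.csv", index=False)
        if self.images is not None:
            np.savez_compressed(
                d / "images.npz",
                images=self.images.astype(np.float32),
                image_index=self.image_index,
            )


def build_dataset(
    positions: np.ndarray,
    n_variants: int = 3,
    hsp_modes=ALL_HSP_MODES,
    config: SceneConfig = SceneConfig(),
    render: bool = True,
) -> ReachingDataset:
    """Assemble the full cartesian dataset |positions| x n_variants x |modes|.

    Variant v jointly selects the v-th colour level and the v-th sphere
    radius, so datasets built with different palettes share identical target
    positions and required endpoints.
    """
    positions = np.asarray(positions, dtype=float)
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    hsp_modes = list(hsp_modes)
    if not hsp_modes:
        raise ValueError("hsp_modes must be non-empty")

    n_pos, n_modes = len(positions), len(hsp_modes)
    pos_idx = np.repeat(np.arange(n_pos), n_variants * n_modes)
    var_idx = np.tile(np.repeat(np.arange(n_variants), n_modes), n_pos)
    mode_idx = np.tile(np.arange(n_modes), n_pos * n_variants)

    hsp = np.asarray(hsp_modes, dtype=int)[mode_idx]
    # scene target: unimanual tasks present the sphere on the active arm's
    # side; rest and bimanual-joint tasks present the grid position as-is.
    sample_pos = positions[pos_idx].copy()
    uni_left = (hsp[:, 0] == 1) & (hsp[:, 1] == 0)
    uni_right = (hsp[:, 0] == 0) & (hsp[:, 1] == 1)
    sample_pos[uni_left] = fold_to_side(sample_pos[uni_left], "left")
    sample_pos[uni_right] = fold_to_side(sample_pos[uni_right], "right")
    req_l = np.where(hsp[:, :1] == 1, sample_pos, HOME_LEFT[None, :])
    req_r = np.where(hsp[:, 1:2] == 1, sample_pos, HOME_RIGHT[None, :])

    # one rendered image per distinct (grid position, mirrored?, variant)
    mirrored = np.sign(sample_pos[:, 0]) != np.sign(positions[pos_idx][:, 0])
    keys = pos_idx * (2 * n_variants) + mirrored.astype(int) * n_variants + var_idx
    unique_keys, image_index = np.unique(keys, return_inverse=True)

    images = None
    if render:
        images = np.empty((len(unique_keys), 2, config.resolution, config.resolution))
        first_sample = np.zeros(len(unique_keys), dtype=int)
        first_sample[image_index] = np.arange(len(keys))
        for j, s in enumerate(first_sample):
            spec = TargetSpec(position=sample_pos[s], colour_id=int(var_idx[s]), size_id=int(var_idx[s]))
            images[j] = render_stereo(spec, config)

    return ReachingDataset(
        positions=sample_pos,
        position_ids=pos_idx,
        variants=var_idx,
        hsp=hsp,
        required_left=req_l,
        required_right=req_r,
        image_index=image_index,
        images=images,
        config=config,
    )
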