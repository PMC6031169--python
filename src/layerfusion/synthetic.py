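"""Synthetic multiview depth-scene generator.

Emulates the capture geometry the recognition model assumes: two or
more uncalibrated depth cameras mounted at 2 m height, tilted 30 deg
below horizontal, a single subject at 3-5.5 m, each sequence opening
with >= 40 background-only frames. Frames are 8-bit depth images
(0 = near, 255 = far; background plane at 240).

No true 3-D rendering is done: the feature model consumes only binary
silhouettes and 8-bit depth values, so each action is composed
directly in image space from axis-aligned body segments whose
projected widths and depth offsets depend on the actor's orientation
relative to the camera:

* standing/walking — tall narrow column, near-uniform per-layer area,
  mild top-to-bottom depth ramp from the camera tilt;
* sitting          — lower half widened by the thighs when seen from
  the side; seen front-on the silhouette collapses onto the standing
  column but the thigh band sits at a nearer depth (hidden volume);
* stooping         — mass concentrated in the upper layers with a
  strong depth gradient along the bent torso;
* lying            — horizontal silhouette at floor level with
  width/height ratio >= 1.5.

Noise is a per-pixel mask flip (rate p) plus Gaussian depth jitter
(sigma in 8-bit steps). All randomness flows from one seeded
generator recorded in the corpus manifest, so regeneration from the
manifest is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    DatasetManifest,
    DepthFrame,
    SequenceEntry,
    ViewStream,
    write_sequence,
)

ACTIONS = ("standing_walking", "sitting", "stooping", "lying")

BACKGROUND_DEPTH = 240  # far plane, ~just beyond the operational range
FOCAL_PX = 140.0        # px per unit (cm of stature / cm of distance)

#: linear map from real distance (cm) to 8-bit depth codes; the subject
#: range 300-550 cm lands well inside [0, BACKGROUND_DEPTH)
_DIST_NEAR_CM, _DIST_FAR_CM = 200.0, 620.0


def distance_to_code(dist_cm: float | np.ndarray) -> np.ndarray:
    """Map real distance to the sensor's 8-bit near-to-far code."""
    t = (np.asarray(dist_cm, dtype=np.float64) - _DIST_NEAR_CM) / (
        _DIST_FAR_CM - _DIST_NEAR_CM
    )
    return np.clip(np.round(t * (BACKGROUND_DEPTH - 5)), 0, 255)


@dataclass(frozen=True)
class BodyParams:
    """Anthropometrics and facing direction of the synthetic actor."""

    stature_cm: float = 170.0
    shoulder_width_cm: float = 45.0
    torso_depth_cm: float = 25.0
    orientation_deg: int = 0  # actor azimuth: 0 front, 45 slant, 90 side, ...

    ORIENTATIONS = (0, 45, 90, 135, 180)

    def __post_init__(self) -> None:
        if min(self.stature_cm, self.shoulder_width_cm, self.torso_depth_cm) <= 0:
            raise ValueError("body dimensions must be positive")
        if self.orientation_deg % 360 not in (0, 45, 90, 135, 180, 225, 270, 315):
            raise ValueError("orientation must be a multiple of 45 degrees")


@dataclass(frozen=True)
class SceneConfig:
    """Capture geometry, noise levels and sequence layout of a corpus."""

    view_angles_deg: tuple[float, ...] = (0.0, 90.0)
    camera_height_m: float = 2.0
    camera_tilt_deg: float = 30.0
    subject_distance_m: tuple[float, float] = (3.0, 5.5)
    frame_size: tuple[int, int] = (160, 120)  # (width, height)
    background_frames: int = 40
    frames_per_action: int = 1
    mask_flip_rate: float = 0.005
    depth_jitter_sigma: float = 1.0
    identical_geometry: bool = False  # ablation: every action renders as standing
    fixed_orientation: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.view_angles_deg) < 1:
            raise ValueError("need at least one view")
        if len(set(self.view_angles_deg)) != len(self.view_angles_deg):
            raise ValueError("view angles must be distinct")
        if not 0.0 <= self.mask_flip_rate <= 0.05:
            raise ValueError("mask flip rate must be in [0, 0.05]")
        if self.background_frames < 1:
            raise ValueError("need at least one background frame")

    @property
    def view_ids(self) -> list[str]:
        return [f"view{i}" for i in range(len(self.view_angles_deg))]


@dataclass(frozen=True)
class Posture:
    """Within-class pose variability drawn per frame.

    These draws are what keeps the classes from being trivially
    separable: a sitter with tucked legs (`thigh_prominence` near 0)
    seen front-on is genuinely hard to tell from a short stander, just
    as in real recordings.
    """

    tilt_spread_cm: float = 30.0     # head-to-feet distance span from camera tilt
    sit_height_jitter: float = 0.0   # additive tweak to the seated height factor
    thigh_prominence: float = 1.0    # 0 = legs tucked aside, 1 = knees at camera
    sit_widen_jitter: float = 0.0    # tweak to the side-view thigh widening
    stoop_depth_cm: float = 45.0     # how far the bent back leans toward camera

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "Posture":
        return cls(
            tilt_spread_cm=rng.uniform(15.0, 45.0),
            sit_height_jitter=rng.uniform(-0.06, 0.06),
            thigh_prominence=rng.uniform(0.1, 1.2),
            sit_widen_jitter=rng.uniform(-0.15, 0.15),
            stoop_depth_cm=rng.uniform(30.0, 60.0),
        )


def _relative_angle(orientation_deg: float, view_angle_deg: float) -> float:
    """Actor orientation relative to a camera, folded to [0, 180]."""
    phi = abs((orientation_deg - view_angle_deg) % 360.0)
    if phi > 180.0:
        phi = 360.0 - phi
    return phi


def _projected_width_cm(body: BodyParams, phi_deg: float) -> float:
    r = math.radians(phi_deg)
    return abs(math.cos(r)) * body.shoulder_width_cm + abs(
        math.sin(r)
    ) * body.torso_depth_cm


def _paint(
    depth_cm: np.ndarray,
    x0: int, x1: int, y0: int, y1: int,
    top_cm: float, bottom_cm: float,
) -> None:
    """Paint a body segment as a vertical distance ramp; nearest surface wins."""
    h, w = depth_cm.shape
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    if x1 <= x0 or y1 <= y0:
        return
    ramp = np.linspace(top_cm, bottom_cm, y1 - y0)[:, None]
    block = np.broadcast_to(ramp, (y1 - y0, x1 - x0))
    region = depth_cm[y0:y1, x0:x1]
    depth_cm[y0:y1, x0:x1] = np.minimum(region, block)


def _silhouette_distance_map(
    action: str,
    body: BodyParams,
    phi_deg: float,
    dist_cm: float,
    frame_size: tuple[int, int],
    x_center: float,
    posture: Posture = Posture(),
) -> np.ndarray:
    """Per-pixel real distance (cm) of the actor surface; inf off-body."""
    width_px, height_px = frame_size
    scale = FOCAL_PX / dist_cm  # px per cm
    canvas = np.full((height_px, width_px), np.inf)

    w_body = max(3, round(_projected_width_cm(body, phi_deg) * scale))
    floor_y = height_px - 8
    near = dist_cm - posture.tilt_spread_cm / 2.0  # head end, tilted camera
    far = dist_cm + posture.tilt_spread_cm / 2.0   # feet end

    def col(x_c: float, w: int, y_top: int, y_bot: int, d_top: float, d_bot: float):
        x0 = round(x_c - w / 2.0)
        _paint(canvas, x0, x0 + w, y_top, y_bot, d_top, d_bot)

    if action == "standing_walking":
        h = round(body.stature_cm * scale)
        col(x_center, w_body, floor_y - h, floor_y, near, far)
    elif action == "sitting":
        # front-on the knees point at the camera: the silhouette keeps
        # almost the standing column's height and the thigh only shows
        # as a nearer-depth band; side-on the thighs widen the outline
        h_factor = (0.72 + 0.2 * abs(math.cos(math.radians(phi_deg)))
                    + posture.sit_height_jitter)
        h = round(h_factor * body.stature_cm * scale)
        top = floor_y - h
        split = top + round(0.55 * h)
        # torso keeps the standing column
        col(x_center, w_body, top, split, near, dist_cm)
        # thighs: widen the silhouette when seen side-on, pull the depth
        # nearer when seen front-on (the "hidden volume" of the thigh)
        widen = 1.0 + (0.9 + posture.sit_widen_jitter) * abs(
            math.sin(math.radians(phi_deg))
        )
        thigh_near = (40.0 * posture.thigh_prominence
                      * abs(math.cos(math.radians(phi_deg))))
        thigh_bot = split + round(0.45 * (floor_y - split))
        col(x_center, round(w_body * widen), split, thigh_bot,
            dist_cm - thigh_near, dist_cm - thigh_near)
        # lower legs
        col(x_center, w_body, thigh_bot, floor_y, dist_cm, far)
    elif action == "stooping":
        h = round(0.62 * body.stature_cm * scale)
        top = floor_y - h
        split = top + round(0.45 * h)
        # bent torso: wide mass, strong near-to-far depth gradient
        col(x_center, round(w_body * 1.5), top, split,
            dist_cm - posture.stoop_depth_cm, dist_cm)
        col(x_center, round(w_body * 0.55), split, floor_y, dist_cm, far)
    elif action == "lying":
        length_cm = body.stature_cm * (0.5 + 0.5 * abs(math.sin(math.radians(phi_deg))))
        length = max(6, round(length_cm * scale))
        thickness = max(2, round(30.0 * scale))
        x0 = round(x_center - length / 2.0)
        _paint(canvas, x0, x0 + length, floor_y - thickness, floor_y,
               dist_cm - 10.0, dist_cm)
    else:
        raise ValueError(f"unknown action {action!r}")
    return canvas


def render_background(
    config: SceneConfig, rng: np.random.Generator, n_frames: int,
    view_id: str = "view0", start_index: int = 0,
) -> list[DepthFrame]:
    """Empty-scene frames: far plane plus sensor jitter."""
    width, height = config.frame_size
    frames = []
    for i in range(n_frames):
        img = np.full((height, width), float(BACKGROUND_DEPTH))
        if config.depth_jitter_sigma > 0:
            img += rng.normal(0.0, config.depth_jitter_sigma, img.shape)
        frames.append(
            DepthFrame(
                pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                frame_index=start_index + i, view_id=view_id,
            )
        )
    return frames


def render_action(
    action: str,
    body: BodyParams,
    view_angle_deg: float,
    config: SceneConfig,
    rng: np.random.Generator,
    dist_cm: Optional[float] = None,
    x_center: Optional[float] = None,
    n_frames: Optional[int] = None,
    view_id: str = "view0",
    start_index: int = 0,
    posture: Optional[Posture] = None,
) -> list[DepthFrame]:
    """Render one view's action frames for one actor placement.

    Distance and horizontal placement default to draws from the scene's
    operating range; consecutive frames get small placement jitter and
    a fresh :class:`Posture` draw (pass ``posture`` to pin the pose) to
    mimic subject motion.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")
    geometry = "standing_walking" if config.identical_geometry else action
    width, height = config.frame_size
    lo, hi = config.subject_distance_m
    if dist_cm is None:
        dist_cm = rng.uniform(lo, hi) * 100.0
    if x_center is None:
        x_center = rng.uniform(0.3 * width, 0.7 * width)
    if n_frames is None:
        n_frames = config.frames_per_action
    phi = _relative_angle(body.orientation_deg, view_angle_deg)

    frames = []
    for i in range(n_frames):
        d = dist_cm + rng.uniform(-5.0, 5.0)
        xc = x_center + rng.uniform(-2.0, 2.0)
        # drawn unconditionally so the random stream is identical
        # across actions (the identical-geometry ablation relies on it)
        drawn = Posture.draw(rng)
        surface = _silhouette_distance_map(
            geometry, body, phi, d, config.frame_size, xc,
            posture=posture or drawn,
        )
        on_body = np.isfinite(surface)
        img = np.full((height, width), float(BACKGROUND_DEPTH))
        img[on_body] = distance_to_code(surface[on_body])
        if config.mask_flip_rate > 0:
            flips = rng.random(img.shape) < config.mask_flip_rate
            flip_to_fg = flips & ~on_body
            flip_to_bg = flips & on_body
            img[flip_to_fg] = distance_to_code(
                rng.uniform(250.0, 550.0, int(flip_to_fg.sum()))
            )
            img[flip_to_bg] = BACKGROUND_DEPTH
        if config.depth_jitter_sigma > 0:
            img += rng.normal(0.0, config.depth_jitter_sigma, img.shape)
        frames.append(
            DepthFrame(
                pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                frame_index=start_index + i, view_id=view_id,
            )
        )
    return frames


@dataclass
class SyntheticSample:
    """One labeled multiview recording: per-view streams, shared actor."""

    sequence_id: str
    label: str
    streams: dict[str, ViewStream]
    body: BodyParams
    dist_cm: float


def generate_samples(
    config: SceneConfig,
    samples_per_class: int,
    seed: Optional[int] = None,
    actions: Sequence[str] = ACTIONS,
) -> list[SyntheticSample]:
    """Generate an in-memory labeled corpus of multiview sequences.

    Each sample is one actor placement recorded by every view:
    ``background_frames`` empty frames then ``frames_per_action``
    action frames per view. Per-view distances differ slightly (the
    cameras are not equidistant from the subject).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.subject_distance_m
    samples = []
    for action in actions:
        for i in range(samples_per_class):
            body = BodyParams(
                stature_cm=rng.uniform(155.0, 190.0),
                shoulder_width_cm=rng.uniform(38.0, 50.0),
                torso_depth_cm=rng.uniform(20.0, 30.0),
                orientation_deg=(
                    config.fixed_orientation
                    if config.fixed_orientation is not None
                    else int(rng.choice(BodyParams.ORIENTATIONS))
                ),
            )
            base_dist = rng.uniform(lo + 0.1, hi - 0.1) * 100.0
            streams = {}
            for view_id, angle in zip(config.view_ids, config.view_angles_deg):
                view_dist = float(np.clip(
                    base_dist + rng.uniform(-30.0, 30.0), lo * 100.0, hi * 100.0
                ))
                bg = render_background(
                    config, rng, config.background_frames, view_id=view_id
                )
                act = render_action(
                    action, body, angle, config, rng,
                    dist_cm=view_dist, view_id=view_id,
                    start_index=config.background_frames,
                )
                streams[view_id] = ViewStream(
                    frames=bg + act, view_id=view_id, view_angle_deg=angle,
                    background_count=config.background_frames,
                )
            samples.append(
                SyntheticSample(
                    sequence_id=f"{action}_{i:04d}", label=action,
                    streams=streams, body=body, dist_cm=base_dist,
                )
            )
    return samples


def generate_corpus(
    config: SceneConfig,
    samples_per_class: int,
    out_dir: Path | str,
    seed: Optional[int] = None,
    fmt: str = "pgm",
) -> DatasetManifest:
    """Write a corpus to disk: frames, per-sequence labels CSV, YAML manifest.

    Layout: ``<out>/<sequence_id>/<view_id>/<frame %06d>.pgm`` plus
    ``<out>/<sequence_id>/labels.csv`` and ``<out>/manifest.yaml``. The
    manifest records every generation parameter and the seed, so
    regenerating from it reproduces the corpus byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    used_seed = config.seed if seed is None else seed
    samples = generate_samples(config, samples_per_class, seed=used_seed)
    entries = []
    for sample in samples:
        seq_dir = out_dir / sample.sequence_id
        rows = []
        for view_id, stream in sample.streams.items():
            write_sequence(stream, seq_dir / view_id, fmt=fmt)
        for t in range(config.background_frames):
            rows.append({"frame_index": t, "label": "background"})
        for t in range(config.frames_per_action):
            rows.append(
                {"frame_index": config.background_frames + t, "label": sample.label}
            )
        labels_file = seq_dir / "labels.csv"
        pd.DataFrame(rows).to_csv(labels_file, index=False)
        entries.append(
            SequenceEntry(
                sequence_id=sample.sequence_id,
                view_dirs={
                    v: str(Path(sample.sequence_id) / v) for v in sample.streams
                },
                background_count=config.background_frames,
                labels_file=str(Path(sample.sequence_id) / "labels.csv"),
                label=sample.label,
            )
        )
    manifest = DatasetManifest(
        views=config.view_ids,
        view_angles_deg={
            v: float(a) for v, a in zip(config.view_ids, config.view_angles_deg)
        },
        background_count=config.background_frames,
        sequences=entries,
        parameters={
            "seed": used_seed,
            "samples_per_class": samples_per_class,
            "frame_size": list(config.frame_size),
            "frames_per_action": config.frames_per_action,
            "mask_flip_rate": config.mask_flip_rate,
            "depth_jitter_sigma": config.depth_jitter_sigma,
            "subject_distance_m": list(config.subject_distance_m),
            "camera_height_m": config.camera_height_m,
            "camera_tilt_deg": config.camera_tilt_deg,
            "identical_geometry": config.identical_geometry,
            "fixed_orientation": config.fixed_orientation,
            "format": fmt,
        },
    )
    manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest


def config_from_manifest(manifest: DatasetManifest) -> SceneConfig:
    """Rebuild the SceneConfig recorded in a corpus manifest."""
    p = manifest.parameters
    return SceneConfig(
        view_angles_deg=tuple(
            manifest.view_angles_deg[v] for v in manifest.views
        ),
        camera_height_m=p.get("camera_height_m", 2.0),
        camera_tilt_deg=p.get("camera_tilt_deg", 30.0),
        subject_distance_m=tuple(p.get("subject_distance_m", (3.0, 5.5))),
        frame_size=tuple(p.get("frame_size", (160, 120))),
        background_frames=manifest.background_count,
        frames_per_action=p.get("frames_per_action", 1),
        mask_flip_rate=p.get("mask_flip_rate", 0.005),
        depth_jitter_sigma=p.get("depth_jitter_sigma", 1.0),
        identical_geometry=p.get("identical_geometry", False),
        fixed_orientation=p.get("fixed_orientation"),
        seed=p.get("seed", 0),
    )
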