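"""Full ray-casting renders: camera, sampling backend, classification, compositing.

For each output pixel the renderer builds an orthographic ray, clips it to
the volume box, enumerates regular sample positions, samples optical
properties with the selected backend (per-point trilinear or
plane-cluster) and composites front to back.  Rays that miss contribute
the background value 0.

Classification order is configurable: *pre*-classification maps gray
values to optical properties at the grid vertexes and interpolates those
fields (the literal assign-then-sample pipeline, the default);
*post*-classification interpolates gray and classifies each sample.  The
two commute exactly wherever the transfer function is linear over the
gray values spanned by a voxel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import planes, trilinear
from .compositing import composite_arrays
from .rays import DEFAULT_STEP_MM, clip_to_volume, orthographic_rays, sample_positions
from .volume import TransferFunction, Volume

__all__ = ["RenderConfig", "run_render", "image_nrmse"]

SAMPLERS = ("traditional", "plane")


@dataclass(frozen=True)
class RenderConfig:
    """Everything that determines a render (and hence its config hash)."""

    sampler: str = "plane"
    axis: str = "auto"  # plane-cluster axis override: auto|x|y|z
    view_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    image_size: tuple[int, int] = (64, 64)  # (width, height) pixels
    pixel_pitch: float = 0.5  # mm between adjacent ray origins
    step: float = DEFAULT_STEP_MM  # sampling distance along the ray, mm
    transfer_function: TransferFunction = field(
        default_factory=lambda: TransferFunction.from_points(
            [(0.0, 0.0, 0.0), (3000.0, 1.0, 0.05)]
        )
    )
    classification: str = "pre"  # pre|post
    early_termination: bool = False
    back_to_front: bool = False  # composite in reversed sample order
    output_max: float = 1.0  # image normalisation maximum for writing

    def __post_init__(self) -> None:
        if self.sampler not in SAMPLERS:
            raise ValueError(f"sampler must be one of {SAMPLERS}, got {self.sampler!r}")
        if self.axis not in ("auto", "x", "y", "z"):
            raise ValueError(f"axis must be auto|x|y|z, got {self.axis!r}")
        if self.classification not in ("pre", "post"):
            raise ValueError(f"classification must be pre|post, got {self.classification!r}")
        if self.step <= 0:
            raise ValueError("sampling distance must be > 0 mm")
        if self.image_size[0] < 1 or self.image_size[1] < 1:
            raise ValueError("output size must be >= 1x1")

    def config_hash(self) -> str:
        tf = self.transfer_function
        payload = json.dumps(
            {
                "sampler": self.sampler,
                "axis": self.axis,
                "view_direction": list(self.view_direction),
                "image_size": list(self.image_size),
                "pixel_pitch": self.pixel_pitch,
                "step": self.step,
                "classification": self.classification,
                "early_termination": self.early_termination,
                "back_to_front": self.back_to_front,
                "output_max": self.output_max,
                "tf": [tf.grays.tolist(), tf.colors.tolist(), tf.opacities.tolist()],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sample_fields(config: RenderConfig, volume: Volume, fields, ray, positions, geom_cache):
    """Sample each vertex field along one ray with the configured backend."""
    if config.sampler == "traditional":
        pts = ray.at(positions)
        return [trilinear.sample_field(f, volume.spacing, pts) for f in fields]
    axis = config.axis if config.axis != "auto" else planes.choose_axis(ray.direction)
    geom = planes.ray_plane_geometry(ray, volume, axis)
    if geom is None or geom["t"].size == 0:
        pts = ray.at(positions)
        return [trilinear.sample_field(f, volume.spacing, pts) for f in fields]
    out = []
    for f in fields:
        vals = planes.face_values(f, geom)
        if geom["t"].size == 1:
            out.append(np.full(positions.shape, float(vals[0])))
        else:
            out.append(np.interp(positions, geom["t"], vals))
    return out


def run_render(config: RenderConfig, volume: Volume) -> tuple[np.ndarray, dict]:
    """Render a volume; returns ``(image, log)``.

    The image has shape ``(height, width)`` for a single-channel transfer
    function, ``(height, width, channels)`` otherwise.  The log records
    the sampler, axis rule, step, ray/sample tallies and a config hash so
    identical configurations are verifiably identical runs.
    """
    tf = config.transfer_function
    width, height = config.image_size
    rays = orthographic_rays(
        volume, config.view_direction, width, height, config.pixel_pitch, step=config.step
    )
    n_channels = tf.n_channels
    if config.classification == "pre":
        vertex_colors, vertex_alpha = tf.map_array(volume.values)
        fields = [vertex_colors[..., ch] for ch in range(n_channels)] + [vertex_alpha]
    else:
        fields = [volume.values]

    image = np.zeros((height, width, n_channels))
    n_hit = 0
    n_samples = 0
    for pixel, ray in enumerate(rays):
        segment = clip_to_volume(ray, volume)
        if segment is None:
            continue
        positions = sample_positions(segment, ray)
        if positions.size == 0:
            continue
        n_hit += 1
        n_samples += positions.size
        sampled = _sample_fields(config, volume, fields, ray, positions, None)
        if config.classification == "pre":
            colors = np.stack(sampled[:-1], axis=-1)
            alphas = np.clip(sampled[-1], 0.0, 1.0)
        else:
            colors, alphas = tf.map_array(sampled[0])
        if config.back_to_front:
            colors, alphas = colors[::-1], alphas[::-1]
        iy, ix = divmod(pixel, width)
        image[iy, ix] = composite_arrays(
            colors, alphas, early_termination=config.early_termination
        )
    if n_channels == 1:
        image = image[..., 0]
    log = {
        "sampler": config.sampler,
        "axis": config.axis,
        "step_mm": config.step,
        "classification": config.classification,
        "n_rays": len(rays),
        "n_rays_hit": n_hit,
        "n_samples": n_samples,
        "config_hash": config.config_hash(),
    }
    return image, log


def image_nrmse(image: np.ndarray, reference: np.ndarray) -> float:
    """RMS difference normalised by the reference dynamic range."""
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {reference.shape}")
    span = float(reference.max() - reference.min())
    if span == 0.0:
        span = 1.0
    return float(np.sqrt(np.mean((image - reference) ** 2)) / span)
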