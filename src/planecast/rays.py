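"""Ray construction, box clipping and regular sample enumeration.

World-space rays are parameterised ``P(t) = O + t * zeta`` with ``zeta``
unit length, so the ray parameter ``t`` is a metric distance in mm.  The
renderer uses an orthographic camera: one ray per output pixel, all
sharing the view direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = ["Ray", "RaySegment", "clip_to_volume", "sample_positions", "orthographic_rays"]

#: Default sampling distance along the ray, mm.
DEFAULT_STEP_MM = 0.3


@dataclass(frozen=True)
class Ray:
    """A view ray: origin (mm), unit direction, sampling step (mm).

    The direction is normalized at construction; a zero vector is an error.
    """

    origin: np.ndarray
    direction: np.ndarray
    step: float = DEFAULT_STEP_MM

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if origin.shape != (3,) or direction.shape != (3,):
            raise ValueError("origin and direction must be 3-vectors")
        norm = float(np.linalg.norm(direction))
        if norm == 0.0:
            raise ValueError("ray direction must be nonzero")
        direction = direction / norm
        if self.step <= 0:
            raise ValueError(f"sampling step must be > 0 mm, got {self.step}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "step", float(self.step))

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """World position(s) at ray distance(s) ``t``."""
        t = np.asarray(t, dtype=float)
        return self.origin + t[..., None] * self.direction


@dataclass(frozen=True)
class RaySegment:
    """The [t_enter, t_exit] span (mm) over which a ray traverses the box."""

    t_enter: float
    t_exit: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_enter) and np.isfinite(self.t_exit)):
            raise ValueError("segment bounds must be finite")
        if self.t_enter > self.t_exit:
            raise ValueError(f"t_enter {self.t_enter} > t_exit {self.t_exit}")


def clip_to_volume(ray: Ray, volume: Volume) -> RaySegment | None:
    """Clip a ray against the volume bounding box (slab method).

    The box is ``[0, (Ex-1)dx] x [0, (Ey-1)dy] x [0, (Ez-1)dz]``.  Returns
    the entry/exit distances with ``t_enter`` clamped to >= 0, or ``None``
    when the ray misses the box.
    """
    box_max = volume.box_max
    t_near, t_far = 0.0, np.inf
    for axis in range(3):
        o, d = ray.origin[axis], ray.direction[axis]
        if d == 0.0:
            if not 0.0 <= o <= box_max[axis]:
                return None
            continue
        t0 = (0.0 - o) / d
        t1 = (box_max[axis] - o) / d
        if t0 > t1:
            t0, t1 = t1, t0
        t_near = max(t_near, t0)
        t_far = min(t_far, t1)
    if t_near > t_far:
        return None
    return RaySegment(t_enter=t_near, t_exit=float(t_far))


def sample_positions(segment: RaySegment, ray: Ray) -> np.ndarray:
    """Regular sample distances ``t_enter, t_enter+step, ...`` within the segment.

    The first sample sits exactly at ``t_enter``; the last is the largest
    ``t_enter + n*step <= t_exit`` (a relative tolerance absorbs float
    noise so an exact multiple of the step lands on ``t_exit``).
    """
    span = segment.t_exit - segment.t_enter
    eps = 1e-9 * max(1.0, abs(segment.t_exit))
    n = int(np.floor((span + eps) / ray.step))
    return segment.t_enter + ray.step * np.arange(n + 1, dtype=float)


def camera_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal axes (u, v) for a view direction.

    ``u = normalize(zeta x a)`` with ``a = +z`` unless ``|zeta . z| > 0.9``
    (near-axial view), in which case ``a = +x``; then ``v = zeta x u``.
    """
    zeta = np.asarray(direction, dtype=float)
    zeta = zeta / np.linalg.norm(zeta)
    a = np.array([1.0, 0.0, 0.0]) if abs(zeta[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(zeta, a)
    u /= np.linalg.norm(u)
    v = np.cross(zeta, u)
    return u, v


def orthographic_rays(
    volume: Volume,
    view_direction,
    width: int,
    height: int,
    pixel_pitch: float,
    step: float = DEFAULT_STEP_MM,
) -> list[Ray]:
    """One ray per pixel of a ``width x height`` image, all parallel.

    Origins form a regular grid (spacing = ``pixel_pitch`` mm) on a plane
    outside the volume box, centered on the volume center, with in-plane
    axes from :func:`camera_frame`.  Rays are returned row-major
    (``iy`` outer, ``ix`` inner).
    """
    zeta = np.asarray(view_direction, dtype=float)
    if np.linalg.norm(zeta) == 0.0:
        raise ValueError("view direction must be nonzero")
    zeta = zeta / np.linalg.norm(zeta)
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    center = volume.box_max / 2.0
    # Plane distance: past the half-diagonal so every origin is outside the box.
    standoff = float(np.linalg.norm(volume.box_max)) / 2.0 + 1.0
    u, v = camera_frame(zeta)
    rays = []
    for iy in range(height):
        dv = (iy - (height - 1) / 2.0) * pixel_pitch
        for ix in range(width):
            du = (ix - (width - 1) / 2.0) * pixel_pitch
            origin = center - standoff * zeta + du * u + dv * v
            rays.append(Ray(origin=origin, direction=zeta, step=step))
    return rays
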