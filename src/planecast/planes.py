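"""Plane-cluster sampling: the fast alternative to per-point trilinear lookup.

Instead of locating a voxel for every sample point, the ray is intersected
once with the cluster of equidistant grid-aligned planes perpendicular to
one axis (``X_i = i*dx``, ``Y_j = j*dy`` or ``Z_k = k*dz``).  For a cluster
along y the intersection with plane ``j`` sits at ray distance

    t_j = (j*dy - yo) / m,

with the other coordinates ``Vi = xo + r*t_j`` and ``Vk = zo + n*t_j``
(axis-permuted analogously for x- and z-clusters).  The scalar property at
an intersection is interpolated from just **three** vertexes of the face it
lies on — the base vertex and its two in-plane neighbours::

    I_E = I0 + (I1 - I0)*(Vi/dx - i) + (I3 - I0)*(Vk/dz - k)

This is a planar (affine) reconstruction, deliberately *not* bilinear: the
face's diagonal corner is unused, which drops the in-plane cross term but
also its cost.  Sample points between two consecutive intersections E and Q
are then filled by linear interpolation in ray distance (the
definite-proportion, or section, formula)::

    I_S = I_E + (t - t_j)/(t_{j+1} - t_j) * (I_Q - I_E)

Sample positions falling before the first or after the last intersection
(the sliver between the box boundary and the nearest cluster plane) clamp
to that nearest intersection's value — continuous and cheap; the choice
only affects sub-plane-spacing slivers at the box edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rays import Ray, clip_to_volume
from .trilinear import locate_axis, trilinear_sample
from .volume import Volume

__all__ = [
    "IntersectionPoint",
    "PlaneSegment",
    "choose_axis",
    "plane_intersections",
    "face_interpolate",
    "segment_sample",
    "plane_sample_ray",
    "definite_proportion",
]

_AXES = "xyz"


@dataclass(frozen=True)
class IntersectionPoint:
    """A ray/plane intersection with its ray distance and owning voxel."""

    point: np.ndarray  # world mm (Vi, Vj, Vk)
    t: float  # ray distance from the origin, mm
    plane_index: int  # index j of the plane within its cluster
    voxel: tuple[int, int, int]  # owning voxel (cluster component clamped)


@dataclass(frozen=True)
class PlaneSegment:
    """Consecutive entry/exit intersections with their interpolated values."""

    entry: IntersectionPoint
    exit: IntersectionPoint
    value_entry: float
    value_exit: float


def choose_axis(direction) -> str:
    """Cluster axis for a ray direction: largest |component|, ties x -> y -> z.

    The dominant axis is guaranteed nonzero, so the plane-intersection
    formula never divides by zero; it also yields the densest bracketing of
    the ray by planes.  When one or two direction components vanish this
    rule automatically falls back to a valid axis.
    """
    zeta = np.asarray(direction, dtype=float)
    if np.linalg.norm(zeta) == 0.0:
        raise ValueError("direction must be nonzero")
    return _AXES[int(np.argmax(np.abs(zeta)))]


def _cross_axes(ax: int) -> tuple[int, int]:
    """In-plane axes for a cluster axis, in x<y<z order (y-cluster -> (x, z))."""
    return tuple(a for a in range(3) if a != ax)  # type: ignore[return-value]


def ray_plane_geometry(ray: Ray, volume: Volume, axis: str):
    """Array-form intersection geometry of one ray with one plane cluster.

    Returns ``None`` if the ray misses the box, else a dict with plane
    indices ``j``, sorted ray distances ``t``, intersection ``points``
    (n, 3), owning ``voxel`` vertex indices (n, 3) and in-plane fractional
    offsets ``frac1``/``frac2`` along the two cross axes.
    """
    ax = _AXES.index(axis)
    d = float(ray.direction[ax])
    if d == 0.0:
        raise ValueError(
            f"ray direction has zero {axis}-component; pick the cluster axis "
            "with choose_axis()"
        )
    segment = clip_to_volume(ray, volume)
    if segment is None:
        return None
    delta = volume.spacing[ax]
    extent = volume.extents[ax]
    j = np.arange(extent, dtype=np.int64)
    t = (j * delta - ray.origin[ax]) / d
    eps = 1e-9 * max(1.0, abs(segment.t_exit), abs(segment.t_enter))
    keep = (t >= segment.t_enter - eps) & (t <= segment.t_exit + eps)
    j, t = j[keep], t[keep]
    order = np.argsort(t, kind="stable")
    j, t = j[order], t[order]
    points = ray.origin + t[:, None] * ray.direction
    points[:, ax] = j * delta  # exact plane coordinate by construction

    c1, c2 = _cross_axes(ax)
    voxel = np.empty((j.size, 3), dtype=np.int64)
    frac = {}
    for c in (c1, c2):
        scaled = points[:, c] / volume.spacing[c]
        idx = np.clip(np.floor(scaled).astype(np.int64), 0, volume.extents[c] - 2)
        voxel[:, c] = idx
        frac[c] = scaled - idx
    voxel[:, ax] = np.minimum(j, extent - 2)
    return {
        "axis": ax,
        "cross": (c1, c2),
        "j": j,
        "t": t,
        "points": points,
        "voxel": voxel,
        "frac1": frac[c1],
        "frac2": frac[c2],
    }


def face_values(field: np.ndarray, geom: dict) -> np.ndarray:
    """Three-vertex planar interpolation of a vertex field at all intersections."""
    ax = geom["axis"]
    c1, c2 = geom["cross"]
    base = geom["voxel"].copy()
    base[:, ax] = geom["j"]  # face vertexes live on the plane itself
    plus1 = base.copy()
    plus1[:, c1] += 1
    plus2 = base.copy()
    plus2[:, c2] += 1
    i0 = field[base[:, 0], base[:, 1], base[:, 2]]
    i1 = field[plus1[:, 0], plus1[:, 1], plus1[:, 2]]
    i3 = field[plus2[:, 0], plus2[:, 1], plus2[:, 2]]
    return i0 + (i1 - i0) * geom["frac1"] + (i3 - i0) * geom["frac2"]


def plane_intersections(ray: Ray, volume: Volume, axis: str) -> list[IntersectionPoint]:
    """All in-box intersections of a ray with one plane cluster, sorted by t.

    For rays travelling against the cluster axis the raw ``t_j`` decrease
    with plane index; sorting by ``t`` restores ray order, so entry/exit
    roles always follow the direction of travel.
    """
    geom = ray_plane_geometry(ray, volume, axis)
    if geom is None:
        return []
    return [
        IntersectionPoint(
            point=geom["points"][n].copy(),
            t=float(geom["t"][n]),
            plane_index=int(geom["j"][n]),
            voxel=tuple(int(v) for v in geom["voxel"][n]),
        )
        for n in range(geom["j"].size)
    ]


def face_interpolate(volume: Volume, p: IntersectionPoint, axis: str) -> float:
    """Scalar at one intersection from the three face vertexes (I0, I1, I3)."""
    ax = _AXES.index(axis)
    box_max = volume.box_max
    for a in range(3):
        tol = 1e-9 * max(1.0, box_max[a])
        if p.point[a] < -tol or p.point[a] > box_max[a] + tol:
            raise ValueError(f"intersection point outside the box on axis {_AXES[a]}")
    c1, c2 = _cross_axes(ax)
    base = list(p.voxel)
    base[ax] = p.plane_index
    i0 = float(volume.values[tuple(base)])
    p1 = base.copy()
    p1[c1] += 1
    p2 = base.copy()
    p2[c2] += 1
    i1 = float(volume.values[tuple(p1)])
    i3 = float(volume.values[tuple(p2)])
    f1 = p.point[c1] / volume.spacing[c1] - p.voxel[c1]
    f2 = p.point[c2] / volume.spacing[c2] - p.voxel[c2]
    return i0 + (i1 - i0) * f1 + (i3 - i0) * f2


def definite_proportion(value_entry, value_exit, t_entry, t_exit, t):
    """The section formula: linear interpolation in ray distance.

    Generic over the scalar type; the operation counter re-runs this with
    counting cells.
    """
    return value_entry + ((t - t_entry) / (t_exit - t_entry)) * (value_exit - value_entry)


def segment_sample(t: float, seg: PlaneSegment) -> float:
    """Value at ray distance ``t`` between a segment's entry and exit."""
    t0, t1 = seg.entry.t, seg.exit.t
    if t1 == t0:
        raise ZeroDivisionError("degenerate segment: entry and exit at the same distance")
    eps = 1e-9 * max(1.0, abs(t0), abs(t1))
    lo, hi = min(t0, t1), max(t0, t1)
    if t < lo - eps or t > hi + eps:
        raise ValueError(f"t={t} outside segment [{t0}, {t1}]")
    return float(definite_proportion(seg.value_entry, seg.value_exit, t0, t1, t))


def plane_sample_ray(volume: Volume, ray: Ray, positions) -> np.ndarray:
    """Plane-cluster sampling of a volume at given ray distances.

    Chooses the cluster axis from the ray direction, computes all
    intersections once, interpolates the volume at each (three-vertex face
    formula) and fills the requested positions by the section formula;
    positions outside the intersection span clamp to the nearest
    intersection's value.  A ray whose in-box segment crosses no cluster
    plane (a short grazing corner clip) falls back to trilinear sampling.
    """
    positions = np.asarray(positions, dtype=float)
    axis = choose_axis(ray.direction)
    geom = ray_plane_geometry(ray, volume, axis)
    if geom is None or geom["t"].size == 0:
        return np.array([trilinear_sample(volume, ray.at(t)) for t in np.atleast_1d(positions)])
    vals = face_values(volume.values, geom)
    if geom["t"].size == 1:
        return np.full(np.atleast_1d(positions).shape, float(vals[0]))
    # np.interp brackets each position and clamps beyond the span -- exactly
    # the section formula plus the sliver rule.
    return np.interp(positions, geom["t"], vals)
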