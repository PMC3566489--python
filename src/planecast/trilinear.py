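"""Traditional trilinear sampling: voxel location plus the nested-lerp chain.

Sampling one world point proceeds in two steps.  First the owning voxel
``(i, j, k)`` and local coordinates ``(xn, yn, zn) in [0, 1]^3`` are found
by floor division of each world coordinate by the spacing.  Then the value
is reconstructed from the voxel's eight corner scalars ``I0..I7`` by three
rounds of linear interpolation: four lerps along z (F1..F4), two along x
(F5, F6), one along y (F).

The corner layout is the unique assignment consistent with that chain::

    I0=(i,j,k)    I1=(i+1,j,k)    I2=(i+1,j,k+1)    I3=(i,j,k+1)
    I4=(i,j+1,k)  I5=(i+1,j+1,k)  I6=(i+1,j+1,k+1)  I7=(i,j+1,k+1)

The scalar helpers here are written in plain arithmetic (no numpy ufuncs)
on purpose: the operation counter re-runs them with counting scalars, so
the tallied costs are the costs of the code that actually executes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = ["VoxelLocation", "locate_voxel", "trilinear_sample", "sample_field"]

_AXES = "xyz"

#: Corner index offsets (di, dj, dk) for I0..I7 in chain-consistent order.
CORNER_OFFSETS = (
    (0, 0, 0),  # I0
    (1, 0, 0),  # I1
    (1, 0, 1),  # I2
    (0, 0, 1),  # I3
    (0, 1, 0),  # I4
    (1, 1, 0),  # I5
    (1, 1, 1),  # I6
    (0, 1, 1),  # I7
)


@dataclass(frozen=True)
class VoxelLocation:
    """Owning voxel index and local coordinates of a world point."""

    index: tuple[int, int, int]
    local: tuple[float, float, float]


def _check_inside(volume: Volume, point) -> None:
    box_max = volume.box_max
    for axis in range(3):
        x = float(point[axis])
        hi = box_max[axis]
        tol = 1e-9 * max(1.0, hi)
        if x < -tol or x > hi + tol:
            raise ValueError(
                f"point coordinate {x} outside volume box [0, {hi}] on axis {_AXES[axis]}"
            )


def locate_axis(x, delta, extent: int):
    """Floor-divide one coordinate: returns ``(i, xn)``.

    Generic over the scalar type of ``x``/``delta``.  The upper box
    boundary clamps to the last voxel (index ``extent - 2``) with local
    coordinate 1, since the bare floor rule would index a voxel that does
    not exist there.
    """
    i = math.floor(x / delta)
    if i < 0:
        i = 0
    elif i > extent - 2:
        i = extent - 2
    xi = i * delta
    xn = (x - xi) / delta
    return i, xn


def interp_chain(corners, xn, yn, zn):
    """Evaluate the nested-lerp chain on eight corner scalars I0..I7.

    Generic over the scalar type (floats, arrays, counting cells).
    """
    i0, i1, i2, i3, i4, i5, i6, i7 = corners
    f1 = i0 + zn * (i3 - i0)
    f2 = i1 + zn * (i2 - i1)
    f3 = i5 + zn * (i6 - i5)
    f4 = i4 + zn * (i7 - i4)
    f5 = f1 + xn * (f2 - f1)
    f6 = f4 + xn * (f3 - f4)
    return f5 + yn * (f6 - f5)


def locate_voxel(volume: Volume, point) -> VoxelLocation:
    """Locate the voxel of a world point (mm) and its local coordinates.

    Raises ``ValueError`` for points outside the volume box (inclusive
    boundaries, with a 1e-9 relative tolerance for float noise).
    """
    _check_inside(volume, point)
    idx, loc = [], []
    for axis in range(3):
        i, xn = locate_axis(float(point[axis]), volume.spacing[axis], volume.extents[axis])
        # Box-check tolerance can leave the local coordinate marginally
        # outside [0, 1]; pin it so downstream convexity holds exactly.
        idx.append(i)
        loc.append(min(1.0, max(0.0, xn)))
    return VoxelLocation(index=tuple(idx), local=tuple(loc))


def corner_values(volume: Volume, index: tuple[int, int, int]) -> list[float]:
    """The eight corner scalars I0..I7 of voxel ``index`` in chain order."""
    i, j, k = index
    return [float(volume.values[i + di, j + dj, k + dk]) for di, dj, dk in CORNER_OFFSETS]


def trilinear_sample(volume: Volume, point) -> float:
    """Trilinearly interpolated scalar at a world point inside the box."""
    loc = locate_voxel(volume, point)
    xn, yn, zn = loc.local
    return float(interp_chain(corner_values(volume, loc.index), xn, yn, zn))


def sample_field(values: np.ndarray, spacing, points: np.ndarray) -> np.ndarray:
    """Vectorized trilinear sampling of a vertex field at ``(N, 3)`` points.

    Same contract as :func:`trilinear_sample` per row but evaluated with
    array arithmetic; used by the renderer.  Points must lie inside the
    box (1e-9 relative tolerance).
    """
    values = np.asarray(values, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    extents = np.array(values.shape)
    box_max = (extents - 1) * spacing
    tol = 1e-9 * np.maximum(1.0, box_max)
    if np.any(points < -tol) or np.any(points > box_max + tol):
        raise ValueError("sample point outside volume box")
    scaled = points / spacing
    idx = np.minimum(np.floor(scaled).astype(np.int64), extents - 2)
    idx = np.maximum(idx, 0)
    local = np.clip(scaled - idx, 0.0, 1.0)
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    xn, yn, zn = local[:, 0], local[:, 1], local[:, 2]
    corners = [values[i + di, j + dj, k + dk] for di, dj, dk in CORNER_OFFSETS]
    return np.asarray(interp_chain(corners, xn, yn, zn))
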