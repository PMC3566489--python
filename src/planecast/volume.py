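"""Scalar volume container and gray-value transfer function.

A :class:`Volume` is a regular 3D grid of scalar values (CT gray values in
the motivating application) with per-axis voxel spacing in millimetres.
Values live at grid *vertexes*; the cell between eight neighbouring
vertexes is a *voxel*.  The world origin coincides with vertex ``(0, 0, 0)``
so vertex ``(i, j, k)`` sits at ``(i*dx, j*dy, k*dz)`` exactly.

A :class:`TransferFunction` maps gray values to optical properties (color
and opacity) by piecewise-linear interpolation between control points,
clamped outside the covered gray range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Volume",
    "TransferFunction",
    "OpticalSample",
    "vertex_value",
    "apply_transfer",
]

_AXES = "xyz"


class ConfigurationError(ValueError):
    """Raised for malformed configuration (transfer functions, metadata...)."""


@dataclass(frozen=True)
class Volume:
    """A regular 3D scalar grid.

    Parameters
    ----------
    values
        Array of shape ``(Ex, Ey, Ez)`` indexed ``(i, j, k)``; each axis
        must have at least 2 vertexes (one voxel).
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be a 3D array, got ndim={values.ndim}")
        if any(e < 2 for e in values.shape):
            raise ValueError(
                f"each axis needs >= 2 vertexes (one voxel), got extents {values.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values in mm, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def extents(self) -> tuple[int, int, int]:
        """Vertex counts ``(Ex, Ey, Ez)``."""
        return self.values.shape

    @property
    def box_max(self) -> np.ndarray:
        """Upper world corner ``((Ex-1)dx, (Ey-1)dy, (Ez-1)dz)`` in mm."""
        return (np.array(self.extents, dtype=float) - 1.0) * np.asarray(self.spacing)

    def vertex_position(self, index: Sequence[int]) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.asarray(self.spacing)


def vertex_value(volume: Volume, index: Sequence[int]) -> float:
    """Return the scalar stored at vertex ``(i, j, k)``.

    Raises ``IndexError`` naming the offending axis for out-of-range
    indices (negative indexing is deliberately not supported).
    """
    idx = tuple(int(v) for v in index)
    for axis, (v, extent) in enumerate(zip(idx, volume.extents)):
        if not 0 <= v < extent:
            raise IndexError(
                f"vertex index {v} out of range [0, {extent}) on axis {_AXES[axis]}"
            )
    return float(volume.values[idx])


@dataclass(frozen=True)
class OpticalSample:
    """Per-sample optical properties: color (scalar or per-channel) and opacity."""

    color: np.ndarray
    opacity: float

    def __post_init__(self) -> None:
        color = np.atleast_1d(np.asarray(self.color, dtype=float))
        opacity = float(self.opacity)
        if not 0.0 <= opacity <= 1.0:
            raise ValueError(f"opacity must be in [0, 1], got {opacity}")
        object.__setattr__(self, "color", color)
        object.__setattr__(self, "opacity", opacity)


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise-linear gray → (color, opacity) map.

    ``grays`` are strictly increasing control-point gray values; ``colors``
    has shape ``(n_points, n_channels)`` with components in [0, 1] and
    ``opacities`` shape ``(n_points,)`` with values in [0, 1].  Evaluation
    clamps to the first/last control point outside the covered range.
    Single-channel (luminance) by default; 3-channel RGB works identically
    per channel.
    """

    grays: np.ndarray
    colors: np.ndarray
    opacities: np.ndarray

    def __post_init__(self) -> None:
        grays = np.asarray(self.grays, dtype=float)
        colors = np.atleast_2d(np.asarray(self.colors, dtype=float))
        if colors.shape[0] != grays.size:
            colors = colors.T
        opacities = np.asarray(self.opacities, dtype=float)
        if grays.ndim != 1 or grays.size < 2:
            raise ConfigurationError("a transfer function needs >= 2 control points")
        if np.any(np.diff(grays) <= 0):
            raise ConfigurationError("control-point gray values must be strictly increasing")
        if colors.shape[0] != grays.size or opacities.shape != grays.shape:
            raise ConfigurationError("colors/opacities must match the number of control points")
        if np.any((opacities < 0) | (opacities > 1)):
            raise ConfigurationError("control-point opacities must lie in [0, 1]")
        if np.any((colors < 0) | (colors > 1)):
            raise ConfigurationError("control-point color components must lie in [0, 1]")
        object.__setattr__(self, "grays", grays)
        object.__setattr__(self, "colors", colors)
        object.__setattr__(self, "opacities", opacities)

    @property
    def n_channels(self) -> int:
        return self.colors.shape[1]

    @classmethod
    def from_points(
        cls, points: Sequence[tuple[float, float | Sequence[float], float]]
    ) -> "TransferFunction":
        """Build from ``(gray, color, opacity)`` triples; color scalar or RGB."""
        if len(points) < 2:
            raise ConfigurationError("a transfer function needs >= 2 control points")
        grays = [p[0] for p in points]
        colors = [np.atleast_1d(np.asarray(p[1], dtype=float)) for p in points]
        if len({c.size for c in colors}) != 1:
            raise ConfigurationError("all control points must have the same channel count")
        opacities = [p[2] for p in points]
        return cls(np.asarray(grays), np.vstack(colors), np.asarray(opacities))

    @classmethod
    def from_config(cls, source: str | Path | dict | list) -> "TransferFunction":
        """Load from a YAML/JSON file or an already-parsed config structure.

        Accepts either a bare list of ``{gray, color, opacity}`` records or a
        mapping with a ``transfer_function`` key holding that list.
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                source = yaml.safe_load(fh)
        if isinstance(source, dict):
            source = source.get("transfer_function", source.get("control_points"))
        if not isinstance(source, list):
            raise ConfigurationError("expected a list of {gray, color, opacity} records")
        return cls.from_points([(rec["gray"], rec["color"], rec["opacity"]) for rec in source])

    def map_array(self, gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized evaluation: returns ``(colors, opacities)``.

        ``colors`` has an extra trailing channel axis.  ``np.interp`` clamps
        to the end control points outside the gray range, matching the
        scalar contract.
        """
        gray = np.asarray(gray, dtype=float)
        colors = np.stack(
            [np.interp(gray, self.grays, self.colors[:, ch]) for ch in range(self.n_channels)],
            axis=-1,
        )
        opacities = np.interp(gray, self.grays, self.opacities)
        return colors, opacities

    def __call__(self, gray: float) -> OpticalSample:
        colors, opacity = self.map_array(np.float64(gray))
        return OpticalSample(color=colors, opacity=float(opacity))


def apply_transfer(tf: TransferFunction, gray: float) -> OpticalSample:
    """Evaluate the transfer function at one gray value."""
    return tf(gray)
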