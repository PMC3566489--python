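"""Volume and image I/O.

The canonical on-disk volume format is a raw binary voxel file plus a
YAML sidecar describing extents, spacing (mm), scalar type, byte order and
axis order.  Slice stacks (one grayscale PNG/TIFF per z-slice) cover the
sequential-image acquisition path.  Rendered images are written as 8- or
16-bit grayscale PNG/PGM (or 8-bit RGB PNG) with a configured, not
auto-scaled, normalisation maximum so images stay comparable across
samplers and runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .volume import ConfigurationError, Volume

__all__ = [
    "VolumeMetadata",
    "CorruptFileError",
    "InconsistentStackError",
    "read_raw_volume",
    "write_raw_volume",
    "read_slice_stack",
    "write_image",
]

SCALAR_TYPES = {
    "uint8": np.uint8,
    "int16": np.int16,
    "uint16": np.uint16,
    "float32": np.float32,
}
_BYTE_ORDERS = {"little": "<", "big": ">"}


class CorruptFileError(IOError):
    """Raw file length does not match the sidecar metadata."""


class InconsistentStackError(IOError):
    """Slice stack with mismatched dimensions or too few slices."""


@dataclass(frozen=True)
class VolumeMetadata:
    """Sidecar description of a raw voxel file.

    ``axis_order`` lists axes fastest-varying first; the default ``"xyz"``
    means x varies fastest in the flat file (Fortran order of the
    ``(i, j, k)`` array).
    """

    extents: tuple[int, int, int]
    spacing: tuple[float, float, float]
    scalar_type: str = "float32"
    byte_order: str = "little"
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        if self.scalar_type not in SCALAR_TYPES:
            raise ConfigurationError(
                f"unknown scalar type {self.scalar_type!r}; choose from {sorted(SCALAR_TYPES)}"
            )
        if self.byte_order not in _BYTE_ORDERS:
            raise ConfigurationError(f"byte order must be little|big, got {self.byte_order!r}")
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ConfigurationError(f"axis order must permute 'xyz', got {self.axis_order!r}")
        object.__setattr__(self, "extents", tuple(int(e) for e in self.extents))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def dtype(self) -> np.dtype:
        base = np.dtype(SCALAR_TYPES[self.scalar_type])
        return base.newbyteorder(_BYTE_ORDERS[self.byte_order]) if base.itemsize > 1 else base

    @classmethod
    def from_file(cls, path: str | Path) -> "VolumeMetadata":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                extents=tuple(raw["extents"]),
                spacing=tuple(raw["spacing"]),
                scalar_type=raw.get("scalar_type", "float32"),
                byte_order=raw.get("byte_order", "little"),
                axis_order=raw.get("axis_order", "xyz"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed volume metadata in {path}: {exc}") from exc

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "extents": list(self.extents),
                    "spacing": list(self.spacing),
                    "scalar_type": self.scalar_type,
                    "byte_order": self.byte_order,
                    "axis_order": self.axis_order,
                },
                fh,
            )


def read_raw_volume(data_path: str | Path, metadata_path: str | Path) -> Volume:
    """Read a raw voxel file with its sidecar into a :class:`Volume`."""
    meta = VolumeMetadata.from_file(metadata_path)
    raw = Path(data_path).read_bytes()
    expected = int(np.prod(meta.extents)) * meta.dtype.itemsize
    if len(raw) != expected:
        raise CorruptFileError(
            f"{data_path}: expected {expected} bytes for extents {meta.extents} "
            f"({meta.scalar_type}), found {len(raw)}"
        )
    flat = np.frombuffer(raw, dtype=meta.dtype)
    # axis_order is fastest-first: reshape slowest-first, then transpose to (x, y, z).
    order_idx = ["xyz".index(a) for a in meta.axis_order]  # fastest -> slowest
    shape = tuple(meta.extents[a] for a in reversed(order_idx))
    arr = flat.reshape(shape)
    # arr axes are (slowest, ..., fastest) = reversed(axis_order); move to (x, y, z).
    src_axes = list(reversed(order_idx))
    arr = np.transpose(arr, axes=[src_axes.index(a) for a in range(3)])
    return Volume(values=arr.astype(np.float64), spacing=meta.spacing)


def write_raw_volume(
    volume: Volume,
    data_path: str | Path,
    metadata_path: str | Path,
    scalar_type: str = "float32",
    byte_order: str = "little",
) -> VolumeMetadata:
    """Write a volume as raw binary + sidecar (x-fastest layout); returns metadata."""
    meta = VolumeMetadata(
        extents=volume.extents,
        spacing=volume.spacing,
        scalar_type=scalar_type,
        byte_order=byte_order,
        axis_order="xyz",
    )
    arr = volume.values.astype(meta.dtype)
    # x-fastest flat layout = Fortran order of the (i, j, k) array.
    Path(data_path).write_bytes(np.asfortranarray(arr).tobytes(order="F"))
    meta.to_file(metadata_path)
    return meta


def _natural_key(path: Path) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", path.name)]


def read_slice_stack(directory: str | Path, spacing, pattern: str = "*.png") -> Volume:
    """Stack per-slice grayscale images into a volume (natural filename order).

    Slice k of the stack becomes the ``k``-th z-plane; image column -> x,
    image row -> y.  All slices must share dimensions and there must be at
    least two (one voxel along z).
    """
    files = sorted(Path(directory).glob(pattern), key=_natural_key)
    if len(files) < 2:
        raise InconsistentStackError(
            f"need >= 2 slices matching {pattern!r} in {directory}, found {len(files)}"
        )
    slices = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB(A) to luminance if a color file sneaks in
            img = img[..., :3].mean(axis=-1)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InconsistentStackError(
                f"slice {f.name} has shape {img.shape}, expected {shape}"
            )
        slices.append(img.astype(np.float64))
    values = np.stack(slices, axis=-1)  # (rows=y, cols=x, z)
    values = np.transpose(values, (1, 0, 2))  # -> (x, y, z)
    return Volume(values=values, spacing=tuple(spacing))


def write_image(
    image: np.ndarray,
    path: str | Path,
    max_value: float = 1.0,
    bit_depth: int = 8,
) -> None:
    """Write a rendered image, linearly mapping [0, max_value] to full scale.

    Grayscale goes to PNG or PGM; 3-channel images to 8-bit RGB PNG.
    Values outside the range clamp; non-finite pixels are an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[-1] == 1:
        image = image[..., 0]
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixel values")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    if bit_depth not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    full = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scaled = np.clip(image / max_value, 0.0, 1.0)
    quantised = np.round(scaled * full).astype(dtype)
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        if quantised.ndim != 2:
            raise ValueError("PGM output supports grayscale images only")
        with open(path, "w") as fh:
            fh.write(f"P2\n{quantised.shape[1]} {quantised.shape[0]}\n{full}\n")
            for row in quantised:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
    else:
        if quantised.ndim == 3 and bit_depth == 16:
            raise ValueError("RGB output is 8-bit only")
        iio.imwrite(path, quantised)
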