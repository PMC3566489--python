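"""Synthetic test volumes with known closed forms.

Every sampler and the full renderer are exercised against phantoms whose
defining function is known analytically, so expected values at arbitrary
off-grid points come from :func:`closed_form` rather than from the code
under test.  Default extents and spacing mimic clinical head-CT geometry
at reduced scale (64 x 64 x 37 vertexes at 0.486 x 0.486 x 0.700 mm), so
anisotropic-spacing behaviour is exercised; gray values roughly follow CT
conventions (0-3000) so default transfer functions are meaningful.

Kinds
-----
``constant``       uniform value (default 1000)
``affine``         a + b*x + c*y + d*z — both samplers reproduce it exactly
``trilinear``      full 8-coefficient form incl. cross terms xy, yz, xz, xyz;
                   exact for the trilinear sampler, *not* for the
                   three-vertex face formula (which drops in-plane cross
                   terms) — the discriminating fixture
``sphere``         binary ball (inside/outside values)
``shell``          ellipsoidal shell ("bone") over a background
``gaussian_blob``  smooth isotropic Gaussian bump — the image-similarity fixture
``head_like``      deterministic bone-shell + soft-interior composition with
                   seeded low-frequency texture; no closed form
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .volume import ConfigurationError, Volume

__all__ = ["PhantomSpec", "generate", "closed_form", "ANALYTIC_KINDS"]

#: Reduced-scale head-CT-like geometry.
DEFAULT_EXTENTS = (64, 64, 37)
DEFAULT_SPACING = (0.486, 0.486, 0.700)

ANALYTIC_KINDS = frozenset(
    {"constant", "affine", "trilinear", "sphere", "shell", "gaussian_blob"}
)
_ALL_KINDS = ANALYTIC_KINDS | {"head_like"}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic volume; identical specs yield identical volumes."""

    kind: str
    extents: tuple[int, int, int] = DEFAULT_EXTENTS
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _ALL_KINDS:
            raise ConfigurationError(
                f"unknown phantom kind {self.kind!r}; choose from {sorted(_ALL_KINDS)}"
            )

    @property
    def box_max(self) -> np.ndarray:
        return (np.array(self.extents, dtype=float) - 1.0) * np.asarray(self.spacing)


def _evaluate(spec: PhantomSpec, x, y, z):
    """Vectorized defining function; shared by generation and the oracle."""
    p = spec.params
    kind = spec.kind
    if kind == "constant":
        return np.broadcast_to(float(p.get("value", 1000.0)), np.shape(x)).copy()
    if kind == "affine":
        a, b, c, d = p.get("coeffs", (1.0, 2.0, 3.0, 5.0))
        return a + b * x + c * y + d * z
    if kind == "trilinear":
        a, b, c, d, e, f, g, h = p.get("coeffs", (1.0, 2.0, 3.0, 5.0, 0.7, 1.1, 1.3, 1.7))
        return a + b * x + c * y + d * z + e * x * y + f * y * z + g * x * z + h * x * y * z
    center = np.asarray(p.get("center", spec.box_max / 2.0), dtype=float)
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    if kind == "sphere":
        radius = float(p.get("radius", float(np.min(spec.box_max)) / 4.0))
        inside = float(p.get("inside", 1000.0))
        outside = float(p.get("outside", 0.0))
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        return np.where(r <= radius, inside, outside)
    if kind == "shell":
        radii = np.asarray(p.get("radii", spec.box_max * 0.4), dtype=float)
        thickness = float(p.get("thickness", 0.15))
        value = float(p.get("value", 2500.0))
        background = float(p.get("background", 0.0))
        rho = np.sqrt((dx / radii[0]) ** 2 + (dy / radii[1]) ** 2 + (dz / radii[2]) ** 2)
        return np.where(np.abs(rho - 1.0) <= thickness, value, background)
    if kind == "gaussian_blob":
        sigma = float(p.get("sigma", float(np.min(spec.box_max)) / 6.0))
        amplitude = float(p.get("amplitude", 3000.0))
        return amplitude * np.exp(-(dx * dx + dy * dy + dz * dz) / (2.0 * sigma * sigma))
    raise ConfigurationError(f"no closed form for phantom kind {kind!r}")


def _head_like(spec: PhantomSpec) -> np.ndarray:
    """Bone-like ellipsoidal shell around a smooth soft-tissue interior."""
    p = spec.params
    ex, ey, ez = spec.extents
    x, y, z = np.meshgrid(
        np.arange(ex) * spec.spacing[0],
        np.arange(ey) * spec.spacing[1],
        np.arange(ez) * spec.spacing[2],
        indexing="ij",
    )
    center = spec.box_max / 2.0
    radii = np.asarray(p.get("radii", spec.box_max * 0.42), dtype=float)
    rho = np.sqrt(
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    )
    bone = float(p.get("bone", 2500.0))
    soft = float(p.get("soft", 1000.0))
    thickness = float(p.get("thickness", 0.12))
    values = np.zeros_like(rho)
    interior = rho < 1.0 - thickness
    shell = (rho >= 1.0 - thickness) & (rho <= 1.0 + thickness)
    # Smooth seeded low-frequency texture inside the "skull".
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amps = rng.uniform(50.0, 150.0, size=3)
    span = np.maximum(spec.box_max, 1e-9)
    texture = (
        amps[0] * np.cos(2.0 * np.pi * x / span[0] + phases[0])
        + amps[1] * np.cos(2.0 * np.pi * y / span[1] + phases[1])
        + amps[2] * np.cos(2.0 * np.pi * z / span[2] + phases[2])
    )
    values[interior] = soft + texture[interior]
    values[shell] = bone
    return values


def generate(spec: PhantomSpec) -> Volume:
    """Materialise a phantom: vertex (i,j,k) holds f(i*dx, j*dy, k*dz)."""
    if spec.kind == "head_like":
        return Volume(values=_head_like(spec), spacing=spec.spacing)
    ex, ey, ez = spec.extents
    x, y, z = np.meshgrid(
        np.arange(ex) * spec.spacing[0],
        np.arange(ey) * spec.spacing[1],
        np.arange(ez) * spec.spacing[2],
        indexing="ij",
    )
    return Volume(values=np.asarray(_evaluate(spec, x, y, z), dtype=float), spacing=spec.spacing)


def closed_form(spec: PhantomSpec, point) -> float:
    """Defining function at an arbitrary (off-grid) world point, mm.

    Only analytic kinds support this; ``head_like`` raises.
    """
    if spec.kind not in ANALYTIC_KINDS:
        raise ConfigurationError(f"phantom kind {spec.kind!r} has no closed form")
    x, y, z = (float(point[i]) for i in range(3))
    return float(_evaluate(spec, np.float64(x), np.float64(y), np.float64(z)))
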