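"""Front-to-back opacity compositing.

The pixel color is the transparency-weighted sum over the ordered samples

    c_out = sum_i c_i * prod_{j<i} (1 - a_j),

with index 0 the viewer-nearest sample: its color arrives undimmed and
every later sample is attenuated by the accumulated transparency of the
samples in front of it.  :func:`composite` evaluates this in a single pass;
:func:`composite_bruteforce` is the literal O(n^2) double loop kept as an
independent oracle.  No opacity correction for the sampling distance is
applied, so halving the step brightens semitransparent media — a
documented property, not a bug.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .volume import OpticalSample

__all__ = ["composite", "composite_bruteforce", "composite_arrays"]


def _split(samples: Sequence[OpticalSample | tuple]) -> tuple[np.ndarray, np.ndarray]:
    colors, alphas = [], []
    for s in samples:
        if isinstance(s, OpticalSample):
            colors.append(s.color)
            alphas.append(s.opacity)
        else:
            c, a = s
            colors.append(np.atleast_1d(np.asarray(c, dtype=float)))
            alphas.append(float(a))
    return np.array(colors, dtype=float), np.array(alphas, dtype=float)


def _validate_alphas(alphas: np.ndarray) -> None:
    if np.any((alphas < 0.0) | (alphas > 1.0)):
        bad = alphas[(alphas < 0.0) | (alphas > 1.0)][0]
        raise ValueError(f"opacity {bad} outside [0, 1]")


def composite(samples: Sequence[OpticalSample | tuple]):
    """Composite ordered samples into the output color (single pass).

    Accepts :class:`~planecast.volume.OpticalSample` objects or bare
    ``(color, opacity)`` pairs; an empty sequence yields 0.  Returns a
    scalar for single-channel colors, an array otherwise.
    """
    if len(samples) == 0:
        return 0.0
    colors, alphas = _split(samples)
    _validate_alphas(alphas)
    out = np.zeros(colors.shape[1])
    transparency = 1.0
    for c, a in zip(colors, alphas):
        out += transparency * c
        transparency *= 1.0 - a
    return float(out[0]) if out.size == 1 else out


def composite_bruteforce(samples: Sequence[OpticalSample | tuple]):
    """Literal double-loop evaluation of the compositing sum (test oracle)."""
    if len(samples) == 0:
        return 0.0
    colors, alphas = _split(samples)
    _validate_alphas(alphas)
    out = np.zeros(colors.shape[1])
    for i in range(len(samples)):
        weight = 1.0
        for j in range(i):
            weight *= 1.0 - alphas[j]
        out += colors[i] * weight
    return float(out[0]) if out.size == 1 else out


def composite_arrays(
    colors: np.ndarray,
    alphas: np.ndarray,
    early_termination: bool = False,
    transparency_cutoff: float = 1e-4,
) -> np.ndarray:
    """Vectorized compositing for the renderer.

    ``colors`` is ``(n, channels)``, ``alphas`` ``(n,)``, both ordered
    viewer-near first.  With ``early_termination`` the tail behind the
    first sample whose accumulated transparency drops below the cutoff is
    skipped (off by default so output matches the literal sum exactly).
    """
    colors = np.atleast_2d(np.asarray(colors, dtype=float))
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        return np.zeros(colors.shape[1] if colors.size else 1)
    _validate_alphas(alphas)
    transparency = np.concatenate([[1.0], np.cumprod(1.0 - alphas[:-1])])
    if early_termination:
        opaque = np.nonzero(transparency < transparency_cutoff)[0]
        if opaque.size:
            stop = opaque[0]
            transparency = transparency[:stop]
            colors = colors[:stop]
    return transparency @ colors
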