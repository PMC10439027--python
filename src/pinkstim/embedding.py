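"""Soft circular windows and signal embedding.

The oriented signal is blended into the unfiltered background through a
raised-cosine aperture: full signal on a plateau of radius ``r``, a half
cosine ramp of width ``w`` down to zero, background everywhere else.  The
composite is a pointwise convex combination, so embedding introduces no
overshoot and the seam carries no hard edge that could attract attention.

Positions and sizes are in degrees of visual angle, converted through
pixels-per-degree; distances are evaluated at real-valued (sub-pixel)
precision, the centre is never snapped to the pixel grid.  Image coordinates
follow the array convention: x increases with column index, y with row index
(downwards), and (0, 0) deg is the field centre.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .noise import NoiseField

__all__ = ["WindowSpec", "raised_cosine_window", "embed_signal"]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Raised-cosine aperture: centre, plateau radius ``r``, ramp width ``w``.

    All in degrees of visual angle. The plateau (weight 1) extends to
    distance ``r`` from the centre; the ramp spans (r, r + w); support ends
    at ``r + w``.
    """

    r: float
    w: float = 0.0
    center_x: float = 0.0
    center_y: float = 0.0

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"plateau radius r must be positive, got {self.r}")
        if self.w < 0:
            raise ValueError(f"ramp width w must be >= 0, got {self.w}")

    @property
    def support(self) -> float:
        return self.r + self.w


def _center_px(shape, spec: WindowSpec, ppd: float):
    height, width = shape
    cx = (width - 1) / 2.0 + spec.center_x * ppd
    cy = (height - 1) / 2.0 + spec.center_y * ppd
    return cx, cy


def raised_cosine_window(
    shape,
    spec: WindowSpec,
    ppd: float,
    require_support: bool = True,
) -> np.ndarray:
    """Evaluate the aperture weights on a pixel grid.

    weight = 1 for d <= r; 0.5 * (1 + cos(pi * (d - r) / w)) on the ramp;
    exactly 0 for d >= r + w (w = 0 gives a hard-edged disk).

    ``require_support=True`` (default) raises if the full support circle
    leaves the array.  With ``require_support=False`` only the plateau must
    fit and the ramp may be clipped by the field boundary — needed for
    narrow fields whose height is smaller than the window support.
    """
    if ppd <= 0:
        raise ValueError("pixels-per-degree must be positive")
    height, width = shape
    cx, cy = _center_px(shape, spec, ppd)
    reach = (spec.r if not require_support else spec.support) * ppd
    if (cx - reach < 0 or cx + reach > width - 1
            or cy - reach < 0 or cy + reach > height - 1):
        what = "support" if require_support else "plateau"
        raise ValueError(
            f"window {what} (radius {reach / ppd:.3f} deg at "
            f"({spec.center_x}, {spec.center_y}) deg) exceeds the "
            f"{width}x{height} px field at {ppd} px/deg"
        )
    y = np.arange(height, dtype=float)[:, None]
    x = np.arange(width, dtype=float)[None, :]
    d = np.hypot(x - cx, y - cy) / ppd
    weights = np.zeros((height, width))
    weights[d <= spec.r] = 1.0
    if spec.w > 0:
        ramp = (d > spec.r) & (d < spec.support)
        weights[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - spec.r) / spec.w))
    return weights


def embed_signal(
    background: NoiseField,
    signal: NoiseField,
    spec: WindowSpec,
    ppd: float,
    require_support: bool = True,
) -> NoiseField:
    """Blend ``signal`` into ``background`` through the aperture.

    composite = W * signal + (1 - W) * background, arranged so pixels outside
    the support equal the background bit-exactly and plateau pixels equal the
    signal bit-exactly.  ``signal`` is the whole-field filtered image (already
    amplitude-matched to the background); only the windowed subpart shows.
    """
    if background.shape != signal.shape:
        raise ValueError(
            f"background {background.shape} and signal {signal.shape} differ in shape"
        )
    weights = raised_cosine_window(background.shape, spec, ppd, require_support)
    bg, sig = background.pixels, signal.pixels
    composite = bg + weights * (sig - bg)
    plateau = weights >= 1.0
    composite[plateau] = sig[plateau]
    return dataclasses.replace(background, pixels=composite, seed=None)
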