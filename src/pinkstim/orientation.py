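"""Gaussian orientation filtering of pink-noise spectra.

The local discrimination signal is made by weighting the Fourier transform of
a pink-noise field with a Gaussian function of spectral orientation only:

    W(fx, fy) = exp(-(dphi)^2 / sigma^2),   dphi = fold(phi - phi0),

where ``phi0`` is the preferred orientation and ``sigma`` the filter width,
both in degrees.  The weight depends on orientation alone, so the radial 1/f
profile of the noise is untouched and the filtered patch keeps its pink-noise
character — the narrower ``sigma``, the more the spectral energy concentrates
around ``phi0`` and the stronger (more discriminable) the oriented structure.

The angular difference is folded to the axial range [-90, +90) (orientation is
180-degree periodic).  No wrap-around Gaussian summation is performed: for the
widths in use (sigma <= 70 deg) the single-Gaussian tail at the 90 deg fold is
exp(-(90/70)^2) ~ 0.19 and is accepted as part of the filter definition.  The
DC weight is 1, leaving the mean untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .noise import FrequencyGrid, NoiseField, fold_orientation, make_frequency_grid

__all__ = [
    "OrientationFilterSpec",
    "orientation_weight_map",
    "hermitian_symmetrize",
    "apply_orientation_filter",
    "match_amplitude_range",
]


@dataclasses.dataclass(frozen=True)
class OrientationFilterSpec:
    """Preferred orientation ``phi0`` and angular width ``sigma``, in degrees.

    ``phi0`` is interpreted modulo 180 (orientation, not direction); e.g. the
    experiments use +-40 deg from vertical.  ``sigma`` must be positive;
    typical task values range from 10 (strong signal) to 70 deg (weak).
    """

    phi0: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def orientation_weight_map(grid: FrequencyGrid, spec: OrientationFilterSpec) -> np.ndarray:
    """Gaussian orientation weights in [0, 1] on the FFT grid.

    ``weight = exp(-(dphi / sigma)^2)`` with ``dphi`` the minimal axial
    distance between the grid orientation and ``phi0``; the DC weight is
    defined as 1.  The map is symmetric under ``f -> -f``, so filtering a
    real image keeps it real.
    """
    dphi = fold_orientation(grid.phi - spec.phi0)
    with np.errstate(invalid="ignore"):
        weights = np.exp(-((dphi / spec.sigma) ** 2))
    weights = np.where(grid.dc_mask, 1.0, weights)
    return weights


def hermitian_symmetrize(weights: np.ndarray) -> np.ndarray:
    """Average a spectral weight map with its point reflection W(-f).

    On even-sized grids the Nyquist rows/columns are their own conjugate
    partners but their orientation is sign-ambiguous, so the raw orientation
    weights there are not Hermitian-symmetric; averaging assigns those bins
    the mean of the two candidate orientations' weights and guarantees a
    real-valued filter output.  Interior bins are unchanged (up to rounding).
    """
    reflected = np.roll(weights[::-1, ::-1], shift=(1, 1), axis=(0, 1))
    return 0.5 * (weights + reflected)


def apply_orientation_filter(field: NoiseField, spec: OrientationFilterSpec) -> NoiseField:
    """Filter a noise field's spectrum by the Gaussian orientation weights.

    Returns a real-valued field with the same target statistics metadata.
    The radial amplitude profile is preserved (the weights have no radial
    dependence); energy concentrates around ``spec.phi0``.
    """
    grid = make_frequency_grid(*field.shape)
    weights = hermitian_symmetrize(orientation_weight_map(grid, spec))
    filtered = np.fft.ifft2(np.fft.fft2(field.pixels) * weights)
    residue = np.abs(filtered.imag).max()
    rms = np.sqrt(np.mean(filtered.real**2))
    if rms > 0 and residue > 1e-8 * rms:
        raise FloatingPointError(
            f"imaginary residue {residue:.3g} too large relative to RMS {rms:.3g}"
        )
    return dataclasses.replace(field, pixels=filtered.real, seed=None)


def match_amplitude_range(filtered: NoiseField, reference: NoiseField) -> NoiseField:
    """Affinely rescale ``filtered`` to the pixel range of ``reference``.

    This is the normalization applied to the orientation-filtered image
    before embedding: output min and max equal the reference min and max
    exactly, and pixel ordering is preserved (the rescale is monotone).
    """
    if filtered.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {filtered.shape} vs {reference.shape}"
        )
    f_lo, f_hi = float(filtered.pixels.min()), float(filtered.pixels.max())
    if f_hi == f_lo:
        raise ValueError("filtered image is constant; amplitude range is degenerate")
    r_lo, r_hi = float(reference.pixels.min()), float(reference.pixels.max())
    scaled = r_lo + (filtered.pixels - f_lo) * ((r_hi - r_lo) / (f_hi - f_lo))
    return dataclasses.replace(filtered, pixels=scaled)
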