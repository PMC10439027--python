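"""Seeded 2-D pink-noise synthesis and spectral diagnostics.

Pink (1/f) noise is the luminance texture whose amplitude spectrum falls off
inversely with radial spatial frequency, the fall-off characteristic of natural
scenes.  Fields are synthesized in the frequency domain: a seeded white-noise
image is Fourier transformed (which yields complex-Gaussian coefficients with
uniformly random phases and exact Hermitian symmetry), the amplitudes are
scaled by 1/fr, and the inverse transform is renormalized to a target mean
luminance and RMS contrast.

Frequency convention (used throughout the package)
---------------------------------------------------
All spectral quantities live on the unshifted ``numpy.fft`` grid.  Frequencies
are expressed in cycles/pixel (``numpy.fft.fftfreq``), so the Nyquist frequency
is 0.5 in both directions and the radial frequency ``fr`` is isotropic for
square pixels, including non-square fields.  ``fx`` varies along axis 1
(columns, the image x direction) and ``fy`` along axis 0 (rows, y increasing
downwards).  Conversion to cycles/degree is ``f * pixels_per_degree`` and
happens only at the reporting layer.

Orientation ``phi = arctan(fy / fx)`` is axial (a grating and its 180 degree
rotation are the same orientation) and is folded to the canonical range
[-90, +90) degrees; ``phi`` is undefined (NaN) at DC.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

__all__ = [
    "NYQUIST",
    "FrequencyGrid",
    "NoiseField",
    "fold_orientation",
    "make_frequency_grid",
    "generate_pink_noise",
    "normalize_pixels",
    "rms_contrast",
    "radial_amplitude_profile",
    "spectral_slope",
    "band_energy",
    "octave_energy_ratio",
]

#: Nyquist frequency in cycles/pixel.
NYQUIST = 0.5


def fold_orientation(deg):
    """Fold angles (degrees) to the axial range [-90, +90).

    Orientation is 180-degree periodic: +100 and -80 describe the same axis.
    """
    return (np.asarray(deg, dtype=float) + 90.0) % 180.0 - 90.0


@dataclasses.dataclass(frozen=True)
class FrequencyGrid:
    """Spatial-frequency coordinates of an unshifted 2-D FFT grid.

    Attributes
    ----------
    fx, fy : ndarray
        Frequencies in cycles/pixel along the image x (axis 1) and y (axis 0)
        directions.
    fr : ndarray
        Radial frequency ``sqrt(fx**2 + fy**2)``; zero exactly once, at DC.
    phi : ndarray
        Orientation ``arctan(fy/fx)`` in degrees, folded to [-90, +90);
        NaN at DC where orientation is undefined.
    """

    fx: np.ndarray
    fy: np.ndarray
    fr: np.ndarray
    phi: np.ndarray

    @property
    def shape(self):
        return self.fr.shape

    @property
    def dc_mask(self):
        return self.fr == 0.0


def make_frequency_grid(height: int, width: int) -> FrequencyGrid:
    """Build the frequency grid for an ``(height, width)`` image.

    Parameters
    ----------
    height, width : int
        Image dimensions in pixels, both >= 2.
    """
    if height < 2 or width < 2:
        raise ValueError(f"grid dimensions must be >= 2, got ({height}, {width})")
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    fx, fy = np.broadcast_arrays(fx, fy)
    fr = np.hypot(fx, fy)
    with np.errstate(invalid="ignore"):
        phi = fold_orientation(np.degrees(np.arctan2(fy, fx)))
    phi = np.where(fr == 0.0, np.nan, phi)
    return FrequencyGrid(fx=fx, fy=fy, fr=fr, phi=phi)


@dataclasses.dataclass(frozen=True)
class NoiseField:
    """A 2-D luminance image with its target statistics.

    ``mean_luminance`` and ``contrast`` are the targets the pixels were (or
    will be) normalized to; ``contrast`` is RMS contrast, i.e. the pixel
    standard deviation divided by the mean luminance.  ``shape_mask`` is an
    optional field-level soft aperture in [0, 1] applied only at render time
    (a circular or rectangular field vignette); the raw pixels always carry
    the full-field statistics.
    """

    pixels: np.ndarray
    mean_luminance: float = 0.5
    contrast: float = 0.2
    seed: Optional[int] = None
    shape_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape

    def normalized(self) -> "NoiseField":
        """Return a copy whose sample statistics match the targets exactly."""
        return dataclasses.replace(
            self,
            pixels=normalize_pixels(self.pixels, self.mean_luminance, self.contrast),
        )


def rms_contrast(pixels: np.ndarray) -> float:
    """RMS contrast: pixel standard deviation over pixel mean."""
    pixels = np.asarray(pixels, dtype=float)
    return float(pixels.std() / pixels.mean())


def normalize_pixels(pixels: np.ndarray, mean_luminance: float, contrast: float) -> np.ndarray:
    """Affinely rescale ``pixels`` to an exact mean and RMS contrast.

    Idempotent: normalizing an already-conforming image is the identity up to
    floating-point rounding.
    """
    if mean_luminance <= 0:
        raise ValueError("mean_luminance must be positive")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    pixels = np.asarray(pixels, dtype=float)
    centered = pixels - pixels.mean()
    sd = centered.std()
    if sd == 0.0:
        raise ValueError("cannot normalize a constant image to nonzero contrast")
    return mean_luminance + centered * (contrast * mean_luminance / sd)


def generate_pink_noise(
    height: int,
    width: int,
    seed: Optional[int] = None,
    mean_luminance: float = 0.5,
    contrast: float = 0.2,
    rng: Optional[np.random.Generator] = None,
) -> NoiseField:
    """Generate a seeded pink-noise field.

    The amplitude spectrum is proportional to ``1/fr`` (the DC amplitude is
    set by the mean-luminance normalization; the 1/fr law is singular there),
    phases are uniformly random under the seed, and the output is real valued
    and normalized to ``mean_luminance`` / ``contrast`` exactly.

    Pass either ``seed`` (reproducible: identical seed and parameters give
    bit-identical pixels) or an existing ``rng``.
    """
    if height < 2 or width < 2:
        raise ValueError("image dimensions must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    spectrum = np.fft.fft2(white)
    grid = make_frequency_grid(height, width)
    scale = np.zeros_like(grid.fr)
    nonzero = ~grid.dc_mask
    scale[nonzero] = 1.0 / grid.fr[nonzero]
    pixels = np.fft.ifft2(spectrum * scale).real
    pixels = normalize_pixels(pixels, mean_luminance, contrast)
    return NoiseField(
        pixels=pixels, mean_luminance=mean_luminance, contrast=contrast, seed=seed
    )


def _amplitude_spectrum(field: NoiseField) -> np.ndarray:
    # Mean subtracted so the diagnostic ignores the DC normalization choice.
    return np.abs(np.fft.fft2(field.pixels - field.pixels.mean()))


def radial_amplitude_profile(field: NoiseField, n_bins: int = 32, spacing: str = "log"):
    """Radially averaged amplitude spectrum.

    Bins partition (0, Nyquist] in ``fr``; DC is excluded.  Returns
    ``(freq, amp)``: the per-bin mean radial frequency and mean amplitude,
    with empty bins dropped.

    Parameters
    ----------
    n_bins : int
        Number of bins, >= 4.
    spacing : {"log", "linear"}
        Bin-edge spacing.  Logarithmic spacing is the natural choice for a
        power-law spectrum.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    grid = make_frequency_grid(*field.shape)
    amp = _amplitude_spectrum(field)
    fr = grid.fr
    f_min = fr[~grid.dc_mask].min()
    if spacing == "log":
        edges = np.logspace(np.log10(f_min), np.log10(NYQUIST), n_bins + 1)
        edges[0] = np.nextafter(0.0, 1.0)  # include the lowest nonzero frequency
    elif spacing == "linear":
        edges = np.linspace(0.0, NYQUIST, n_bins + 1)
        edges[0] = np.nextafter(0.0, 1.0)
    else:
        raise ValueError("spacing must be 'log' or 'linear'")
    idx = np.digitize(fr, edges) - 1
    valid = (fr > 0) & (fr <= NYQUIST)
    freq = np.full(n_bins, np.nan)
    mean_amp = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = valid & (idx == b)
        if np.any(sel):
            freq[b] = fr[sel].mean()
            mean_amp[b] = amp[sel].mean()
    keep = np.isfinite(freq)
    return freq[keep], mean_amp[keep]


def spectral_slope(field: NoiseField, n_bins: int = 32) -> float:
    """Least-squares slope of log10(amplitude) against log10(frequency).

    The lowest and highest half-octave of the radial profile are excluded
    from the fit: the extreme bins are dominated by discretization (few
    modes per annulus at low fr, anisotropic corner coverage near Nyquist).
    Pink noise yields a slope near -1.
    """
    freq, amp = radial_amplitude_profile(field, n_bins=n_bins, spacing="log")
    f_lo = freq.min() * np.sqrt(2.0)
    f_hi = NYQUIST / np.sqrt(2.0)
    keep = (freq >= f_lo) & (freq <= f_hi) & (amp > 0)
    if keep.sum() < 3:
        raise ValueError("too few interior bins for a slope fit")
    slope, _ = np.polyfit(np.log10(freq[keep]), np.log10(amp[keep]), 1)
    return float(slope)


def band_energy(field: NoiseField, f_lo: float, f_hi: float) -> float:
    """Spectral energy (sum of squared amplitudes) with ``f_lo <= fr < f_hi``.

    Frequencies are cycles/pixel; the band must satisfy
    ``0 < f_lo < f_hi <= 0.5``.  DC never contributes.
    """
    if not (0.0 < f_lo < f_hi <= NYQUIST + 1e-12):
        raise ValueError(
            f"band must satisfy 0 < f_lo < f_hi <= Nyquist (0.5); got [{f_lo}, {f_hi})"
        )
    grid = make_frequency_grid(*field.shape)
    amp = _amplitude_spectrum(field)
    sel = (grid.fr >= f_lo) & (grid.fr < f_hi)
    return float(np.sum(amp[sel] ** 2))


def octave_energy_ratio(field: NoiseField, f_lo: float) -> float:
    """Energy ratio of the octave (f_lo, 2*f_lo) to the next octave up.

    For an ideal 1/f amplitude spectrum equal octaves carry equal energy, so
    the ratio is 1; this scale invariance is what makes the stimulus equally
    discriminable across retinal eccentricity under octave-bandwidth spatial
    frequency channels.
    """
    e1 = band_energy(field, f_lo, 2 * f_lo)
    e2 = band_energy(field, 2 * f_lo, 4 * f_lo)
    if e2 == 0.0:
        raise ValueError("upper octave carries no energy")
    return e1 / e2
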