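"""Synthetic naturalistic luminance textures.

The stimuli in this package are built from synthetic textures with
approximately power-law ("1/f") spatial amplitude spectra, the dominant
first-order statistic of natural scenes.  Textures are Gaussian fields
coloured in the Fourier domain, shifted to mid-gray, contrast-scaled to use
most of the 8-bit range, clipped and quantized to integer values in
[0, 255].  Long stimulus strips are assembled by concatenating independently
drawn blocks; the luminance discontinuities this introduces at block seams
are of the kind common in natural imagery.

Blocks whose saturated-pixel fraction (values of exactly 0 or 255) exceeds
15% are rejected and redrawn, mirroring the screening applied to
photographic source material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Texture1D",
    "Texture2D",
    "synth_texture_1d",
    "synth_texture_2d",
    "reject_saturated",
    "tile_texture_1d",
    "tile_texture_2d",
]

#: default luminance mean (mid-gray on the 8-bit scale)
MEAN_LUMINANCE = 128.0
#: default luminance standard deviation before clipping; +/-2.8 sigma spans
#: nearly the full 8-bit range while keeping the saturated fraction small
CONTRAST_SD = 45.0
#: saturation-rejection threshold (strictly more than this fraction at 0/255)
SATURATION_LIMIT = 0.15
#: default block length (pixels) for concatenated strips
BLOCK_LEN = 500


@dataclass
class Texture1D:
    """A 1-D strip of 8-bit-quantized luminance samples."""

    values: np.ndarray  # float array of integers in [0, 255]
    pixel_pitch: float  # degrees per pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("Texture1D requires a non-empty 1-D array")
        if self.values.min() < 0 or self.values.max() > 255:
            raise ValueError("luminance values must lie in [0, 255]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Texture2D:
    """A 2-D grid of 8-bit-quantized luminance samples."""

    values: np.ndarray  # (rows, cols)
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("Texture2D requires a non-empty 2-D array")
        if self.values.min() < 0 or self.values.max() > 255:
            raise ValueError("luminance values must lie in [0, 255]")


def _quantize(field: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Standardize a raw Gaussian field, scale to 8-bit range and quantize."""
    std = field.std()
    if std > 0:
        field = (field - field.mean()) / std
    else:
        field = field - field.mean()
    lum = mean + sd * field
    return np.clip(np.rint(lum), 0.0, 255.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synth_texture_1d(
    n_pixels: int,
    seed,
    spectral_exponent: float = 1.0,
    pixel_pitch: float = 0.01,
    mean: float = MEAN_LUMINANCE,
    contrast_sd: float = CONTRAST_SD,
) -> Texture1D:
    """Draw a 1-D texture with ~1/f**exponent amplitude spectrum.

    Parameters
    ----------
    n_pixels
        Strip length; must be positive.
    seed
        Integer seed or a ``numpy.random.Generator``.  The same seed always
        yields the same texture.
    spectral_exponent
        Slope of the amplitude spectrum on log-log axes is approximately
        ``-spectral_exponent``; 1.0 gives the canonical 1/f statistics.
    """
    if n_pixels <= 0:
        raise ValueError("n_pixels must be positive")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n_pixels)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spectral_exponent)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    field = np.fft.irfft(spec, n=n_pixels)
    return Texture1D(_quantize(field, mean, contrast_sd), pixel_pitch)


def synth_texture_2d(
    n_rows: int,
    n_cols: int,
    seed,
    spectral_exponent: float = 1.0,
    pixel_pitch: float = 0.01,
    mean: float = MEAN_LUMINANCE,
    contrast_sd: float = CONTRAST_SD,
) -> Texture2D:
    """Draw a 2-D texture with a radially isotropic ~1/f amplitude spectrum."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("texture dimensions must be positive")
    rng = _rng(seed)
    fy = np.fft.fftfreq(n_rows)[:, None]
    fx = np.fft.rfftfreq(n_cols)[None, :]
    fr = np.hypot(fy, fx)
    amp = np.zeros_like(fr)
    nz = fr > 0
    amp[nz] = fr[nz] ** (-spectral_exponent)
    spec = amp * (
        rng.standard_normal(fr.shape) + 1j * rng.standard_normal(fr.shape)
    )
    spec[0, 0] = 0.0
    field = np.fft.irfft2(spec, s=(n_rows, n_cols))
    return Texture2D(_quantize(field, mean, contrast_sd), pixel_pitch)


def reject_saturated(texture) -> bool:
    """Return True (reject) iff strictly more than 15% of samples are 0 or 255.

    Accepts a :class:`Texture1D`, :class:`Texture2D` or a bare array.
    """
    values = texture.values if hasattr(texture, "values") else np.asarray(texture)
    saturated = np.count_nonzero((values == 0) | (values == 255))
    return bool(saturated > SATURATION_LIMIT * values.size)


def tile_texture_1d(
    n_pixels: int,
    rng: np.random.Generator,
    block_len: int = BLOCK_LEN,
    spectral_exponent: float = 1.0,
    pixel_pitch: float = 0.01,
    max_redraws: int = 50,
) -> Texture1D:
    """Assemble a long strip by concatenating independently drawn blocks.

    Each block is screened with the saturation rule and redrawn if rejected.
    """
    blocks = []
    total = 0
    while total < n_pixels:
        n = min(block_len, n_pixels - total)
        for _ in range(max_redraws):
            tex = synth_texture_1d(n, rng, spectral_exponent, pixel_pitch)
            if not reject_saturated(tex):
                break
        blocks.append(tex.values)
        total += n
    return Texture1D(np.concatenate(blocks), pixel_pitch)


def tile_texture_2d(
    n_rows: int,
    n_cols: int,
    rng: np.random.Generator,
    block_rows: int = BLOCK_LEN,
    spectral_exponent: float = 1.0,
    pixel_pitch: float = 0.01,
    max_redraws: int = 50,
) -> Texture2D:
    """Assemble a tall 2-D texture by vertical concatenation of blocks."""
    blocks = []
    total = 0
    while total < n_rows:
        n = min(block_rows, n_rows - total)
        for _ in range(max_redraws):
            tex = synth_texture_2d(n, n_cols, rng, spectral_exponent, pixel_pitch)
            if not reject_saturated(tex):
                break
        blocks.append(tex.values)
        total += n
    return Texture2D(np.concatenate(blocks, axis=0), pixel_pitch)
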