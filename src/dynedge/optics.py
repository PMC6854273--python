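"""Compound-eye optics: Gaussian blur and downsampling to receptor drives.

The eye's optics are modelled by a Gaussian modulation transfer function
(MTF) ``K * exp(-r**2 / r0**2)`` whose full width at half maximum equals 1.4
times the inter-receptor viewing angle, truncated at ``+/- 2*r0`` and
normalized to unit sum.  A high-resolution luminance frame is convolved with
this kernel and sampled at the receptor viewing directions at every time
step, which both smooths edges as the eye would and prevents spatial
aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MTFKernel",
    "ReceptorDrive",
    "r0_from_spacing",
    "make_mtf_kernel",
    "receptor_positions",
    "blur_matrix",
    "blur_downsample",
]

#: nominal inter-receptor viewing angle (degrees)
INTER_RECEPTOR_ANGLE = 1.0
#: FWHM of the optical blur, in units of the inter-receptor angle
FWHM_FACTOR = 1.4


def r0_from_spacing(inter_receptor_angle: float = INTER_RECEPTOR_ANGLE) -> float:
    """Gaussian space constant from the receptor spacing.

    The FWHM of ``exp(-r**2/r0**2)`` is ``2*r0*sqrt(ln 2)``; setting it to
    1.4 times the spacing gives ``r0 = 1.4 * dphi / (2*sqrt(ln 2))``
    (~0.8407 deg for 1 deg spacing).
    """
    return FWHM_FACTOR * inter_receptor_angle / (2.0 * np.sqrt(np.log(2.0)))


@dataclass
class MTFKernel:
    """Discretized, truncated, unit-sum Gaussian blur kernel."""

    weights: np.ndarray
    offsets: np.ndarray  # angular offset of each tap from the kernel center [deg]
    r0: float
    pixel_pitch: float

    @property
    def support_radius(self) -> float:
        return 2.0 * self.r0


@dataclass
class ReceptorDrive:
    """Per-receptor luminance time series after optical blur."""

    luminance: np.ndarray  # (n_steps, n_receptors)
    dt: float
    inter_receptor_angle: float = INTER_RECEPTOR_ANGLE

    @property
    def n_receptors(self) -> int:
        return self.luminance.shape[1]


def _gaussian_weights(offsets: np.ndarray, r0: float) -> np.ndarray:
    """Truncated Gaussian taps, zero beyond ±2*r0, normalized to unit sum."""
    w = np.where(np.abs(offsets) <= 2.0 * r0, np.exp(-(offsets**2) / r0**2), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("kernel support contains no pixels; pitch too coarse")
    return w / total


def make_mtf_kernel(
    inter_receptor_angle: float = INTER_RECEPTOR_ANGLE,
    pixel_pitch: float = 0.01,
    half_pixel_centered: bool = False,
) -> MTFKernel:
    """Build the blur kernel on the pixel grid.

    With ``half_pixel_centered`` the taps sit at half-integer pixel offsets
    (used when a receptor's viewing direction falls exactly between two
    pixels, as happens for edge-centered scene grids); otherwise the kernel
    is centered on a pixel.
    """
    if pixel_pitch >= inter_receptor_angle:
        raise ValueError("pixel_pitch must be much finer than the receptor spacing")
    r0 = r0_from_spacing(inter_receptor_angle)
    m = int(np.floor(2.0 * r0 / pixel_pitch))
    if half_pixel_centered:
        offsets = (np.arange(-m, m) + 0.5) * pixel_pitch
    else:
        offsets = np.arange(-m, m + 1) * pixel_pitch
    return MTFKernel(_gaussian_weights(offsets, r0), offsets, r0, pixel_pitch)


def receptor_positions(n_receptors: int, inter_receptor_angle: float = INTER_RECEPTOR_ANGLE) -> np.ndarray:
    """Viewing directions of an evenly spaced array centered on 0 deg.

    For an even count the two central receptors straddle 0, so edges placed
    at 0 fall exactly midway between them.
    """
    return (np.arange(n_receptors) - (n_receptors - 1) / 2.0) * inter_receptor_angle


def blur_matrix(
    n_pixels: int,
    pixel_pitch: float,
    n_receptors: int,
    inter_receptor_angle: float = INTER_RECEPTOR_ANGLE,
) -> np.ndarray:
    """(n_pixels, n_receptors) matrix mapping a frame to receptor drives.

    Pixel centers sit at ``(j - n_pixels/2 + 0.5) * pitch`` so that 0 deg is
    a pixel *boundary*: an edge at the array center never straddles a pixel
    and mirror symmetry about the center is exact.
    """
    x = (np.arange(n_pixels) - n_pixels / 2.0 + 0.5) * pixel_pitch
    centers = receptor_positions(n_receptors, inter_receptor_angle)
    r0 = r0_from_spacing(inter_receptor_angle)
    M = np.zeros((n_pixels, n_receptors))
    for r, c in enumerate(centers):
        off = x - c
        if off[0] > -2.0 * r0 or off[-1] < 2.0 * r0:
            raise ValueError("scene is not wide enough to cover the receptor kernels")
        M[:, r] = _gaussian_weights(off, r0)
    return M


def blur_downsample(scene, kernel: MTFKernel, n_receptors: int) -> ReceptorDrive:
    """Blur and downsample a scene's frames to per-receptor drives.

    ``scene`` must expose ``frames`` (n_steps, n_pixels), ``pixel_pitch``
    and ``dt``.  Each receptor's drive is the kernel-weighted sum of
    high-resolution luminance centered on its viewing direction, applied at
    every time step.
    """
    frames = np.atleast_2d(np.asarray(scene.frames, dtype=np.float64))
    M = blur_matrix(frames.shape[1], scene.pixel_pitch, n_receptors)
    return ReceptorDrive(frames @ M, scene.dt)
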