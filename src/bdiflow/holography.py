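"""Numerical reconstruction of off-axis holograms.

An off-axis hologram records the interference of an object field ``O`` with a
tilted plane reference ``R``; the tilt places the object information on a
spatial carrier so that the 2-D Fourier transform of a frame shows the object
spectrum and its phase conjugate offset from the central autocorrelation
(DC) term. Demodulation selects one sideband with a circular aperture,
recenters it, and inverse-transforms back to the image plane. The intensity
``|field|²`` of the reconstructed object field is the surrogate observable:
its temporal fluctuations carry the intracellular dynamics.

No depth processing happens here — coherence gating is an acquisition-time
property and each frame is treated as a single, already-gated optical
section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HologramStack",
    "ReconstructedField",
    "NoSidebandError",
    "locate_sideband",
    "fourier_demodulate",
    "intensity_series",
    "guard_band_mask",
]


class NoSidebandError(ValueError):
    """Raised when no fringe carrier can be found outside the DC region."""


@dataclass
class HologramStack:
    """Time-ordered stack of 2-D interferogram frames for one well."""

    frames: np.ndarray  # (n_frames, rows, cols), real, nonnegative
    timestamps: np.ndarray  # seconds, strictly increasing
    pixel_pitch: float = 1.0
    carrier_hint: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("hologram intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ReconstructedField:
    """Complex object field demodulated from one hologram frame."""

    field: np.ndarray  # 2-D complex
    carrier_used: tuple[float, float]
    aperture_radius: float
    dc_overlap: bool = False

    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return fy, fx


def locate_sideband(
    spectrum_magnitude: np.ndarray, dc_exclusion_radius: float
) -> tuple[float, float]:
    """Estimate the fringe carrier from a Fourier magnitude image.

    Returns the (fy, fx) location (cycles/pixel) of the strongest peak
    outside a DC exclusion disk, resolved to the half-plane with positive
    first coordinate (ties broken toward positive second coordinate) since
    the two sidebands are conjugate.
    """
    mag = np.asarray(spectrum_magnitude, dtype=float)
    if mag.ndim != 2:
        raise ValueError("spectrum magnitude must be 2-D")
    if dc_exclusion_radius >= 0.5:
        raise ValueError("dc_exclusion_radius must be below the Nyquist half-width")
    fy, fx = _freq_grids(mag.shape)
    outside = fy**2 + fx**2 > dc_exclusion_radius**2
    if not np.any(outside):
        raise NoSidebandError("exclusion disk covers the whole spectrum")
    masked = np.where(outside, mag, -np.inf)
    peak = float(masked.max())
    floor = float(np.median(mag[outside]))
    if not np.isfinite(peak) or peak <= 10.0 * max(floor, np.finfo(float).tiny):
        raise NoSidebandError("no fringe carrier found outside the DC region")
    iy, ix = np.unravel_index(int(np.argmax(masked)), mag.shape)
    ky, kx = float(fy[iy, 0]), float(fx[0, ix])
    if ky < 0 or (ky == 0 and kx < 0):
        ky, kx = -ky, -kx
    return (ky, kx)


def fourier_demodulate(
    frame: np.ndarray,
    carrier: tuple[float, float],
    aperture_radius: float | None = None,
    dc_radius: float = 0.05,
) -> ReconstructedField:
    """Demodulate one off-axis hologram frame at a known carrier.

    The frame is Fourier transformed, a circular hard aperture centred on the
    carrier selects one sideband, the selection is rolled to the origin, and
    the inverse transform returns the complex object field on the image
    plane. ``aperture_radius`` (cycles/pixel) defaults to half the carrier
    magnitude. An aperture that reaches into the DC autocorrelation region
    triggers a warning and flags the result.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    ky, kx = float(carrier[0]), float(carrier[1])
    if abs(ky) >= 0.5 or abs(kx) >= 0.5:
        raise ValueError("carrier must be within the Nyquist limit")
    kmag = float(np.hypot(ky, kx))
    if aperture_radius is None:
        aperture_radius = 0.5 * kmag
    if aperture_radius <= 0:
        raise ValueError("aperture_radius must be positive")

    dc_overlap = kmag - aperture_radius < dc_radius
    if dc_overlap:
        warnings.warn(
            "demodulation aperture overlaps the DC autocorrelation term; "
            "reconstruction is flagged",
            RuntimeWarning,
            stacklevel=2,
        )

    rows, cols = frame.shape
    spec = np.fft.fft2(frame)
    fy, fx = _freq_grids(frame.shape)
    aperture = (fy - ky) ** 2 + (fx - kx) ** 2 <= aperture_radius**2
    # recenter on the nearest integer bin of the carrier
    by = int(np.round(ky * rows))
    bx = int(np.round(kx * cols))
    selected = np.roll(spec * aperture, shift=(-by, -bx), axis=(0, 1))
    fld = np.fft.ifft2(selected)
    return ReconstructedField(
        field=fld,
        carrier_used=(ky, kx),
        aperture_radius=float(aperture_radius),
        dc_overlap=bool(dc_overlap),
    )


def guard_band_mask(shape: tuple[int, int], guard_px: int = 8) -> np.ndarray:
    """Interior mask excluding a border guard band (wrap-around artifacts)."""
    mask = np.zeros(shape, dtype=bool)
    g = guard_px
    if 2 * g >= min(shape):
        raise ValueError("guard band leaves no interior pixels")
    mask[g : shape[0] - g, g : shape[1] - g] = True
    return mask


def intensity_series(
    stack: HologramStack,
    carrier: tuple[float, float] | None = None,
    aperture_radius: float | None = None,
    roi_mask: np.ndarray | None = None,
    guard_px: int = 8,
) -> np.ndarray:
    """Per-pixel intensity fluctuation series from one burst.

    Every frame is demodulated at the carrier (taken from the stack's hint or
    located on the first frame), and the reconstructed intensity of each
    masked pixel is collected over frames. Returns an array of shape
    ``(n_masked_pixels, n_frames)`` ordered as the mask's flat nonzero order;
    frame order matches the timestamps.
    """
    if carrier is None:
        carrier = stack.carrier_hint
    if carrier is None:
        mag = np.abs(np.fft.fft2(stack.frames[0]))
        carrier = locate_sideband(mag, dc_exclusion_radius=0.08)
    if roi_mask is None:
        roi_mask = guard_band_mask(stack.shape, guard_px)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.shape:
        raise ValueError("roi_mask shape must match the frames")
    if not roi_mask.any():
        raise ValueError("roi_mask selects no pixels")

    out = np.empty((int(roi_mask.sum()), stack.n_frames))
    for t in range(stack.n_frames):
        rec = fourier_demodulate(stack.frames[t], carrier, aperture_radius)
        out[:, t] = rec.intensity()[roi_mask]
    return out
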