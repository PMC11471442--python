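"""Fluctuation power spectra and differential spectrograms.

One acquisition burst (one ~40-minute time frame) yields, for every sample
pixel, an intensity time series. Each series is mean-subtracted, windowed,
and periodogram-transformed; the pixel periodograms are averaged into a
single spectrum per burst. Several pre-treatment bursts are averaged into
the sample's baseline, and every post-treatment spectrum is referenced to it
as a log10 power ratio, assembling a frequency × time map of relative
spectral change — the drug-response "fingerprint".

Normalization: with the default rectangular window, the one-sided
periodogram satisfies Parseval exactly — the sum of the (zero-excluded)
density bins equals the series variance. The zero-frequency bin is excluded
everywhere since mean subtraction makes it degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PowerSpectrum",
    "DifferentialSpectrogram",
    "burst_power_spectrum",
    "baseline_average",
    "differential_spectrogram",
]


@dataclass
class PowerSpectrum:
    """Pixel-averaged one-sided fluctuation power spectrum of one burst."""

    freqs: np.ndarray  # Hz, ascending, zero bin excluded
    density: np.ndarray  # nonnegative, same length as freqs
    burst_time_hr: float  # relative to treatment; negative = baseline
    n_pixels_averaged: int
    n_bursts_averaged: int = 1  # > 1 for baseline averages; sets per-bin dof

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.shape != self.density.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and density must be 1-D of equal length")
        if self.freqs.size and (np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0)):
            raise ValueError("freqs must be strictly positive and ascending")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


@dataclass
class DifferentialSpectrogram:
    """Baseline-referenced log10 relative spectral change on a time-frequency grid."""

    freqs: np.ndarray  # Hz
    frame_times_hr: np.ndarray  # post-treatment burst times, ascending
    values: np.ndarray  # (n_freqs, n_times), finite
    baseline: PowerSpectrum

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.frame_times_hr = np.asarray(self.frame_times_hr, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.freqs.size, self.frame_times_hr.size):
            raise ValueError("values must be (n_freqs, n_times)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")


def burst_power_spectrum(
    series_per_pixel: np.ndarray,
    frame_rate_hz: float,
    burst_time_hr: float,
    window: str = "rectangular",
) -> PowerSpectrum:
    """Pixel-averaged periodogram of one burst.

    ``series_per_pixel`` is ``(n_pixels, n_samples)`` (a single series is
    promoted). Each pixel is mean-subtracted and windowed; periodograms are
    scaled so that, for the rectangular window, the bin sum equals the
    series variance (Parseval); the pixel average is returned.
    """
    x = np.asarray(series_per_pixel, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("series_per_pixel must be (n_pixels, n_samples)")
    n_pix, n = x.shape
    if n < 64:
        raise ValueError(f"burst too short: {n} samples (minimum 64)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contain non-finite values")

    x = x - x.mean(axis=1, keepdims=True)
    if window == "rectangular":
        w = np.ones(n)
    elif window == "hann":
        w = np.hanning(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    # normalize so the rectangular window leaves Parseval exact
    xw = x * w / np.sqrt(np.mean(w**2))

    coeffs = np.fft.rfft(xw, axis=1)
    pgram = np.abs(coeffs) ** 2 / n**2
    pgram[:, 1:] *= 2.0
    if n % 2 == 0:
        pgram[:, -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate_hz)[1:]
    density = pgram[:, 1:].mean(axis=0)
    return PowerSpectrum(
        freqs=freqs,
        density=density,
        burst_time_hr=float(burst_time_hr),
        n_pixels_averaged=n_pix,
    )


def baseline_average(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Arithmetic per-frequency mean of pre-treatment spectra."""
    if len(spectra) < 2:
        raise ValueError("baseline requires at least 2 pre-treatment spectra")
    ref = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != ref.shape or not np.allclose(s.freqs, ref):
            raise ValueError("baseline spectra are on mismatched frequency grids")
    density = np.mean([s.density for s in spectra], axis=0)
    return PowerSpectrum(
        freqs=ref.copy(),
        density=density,
        burst_time_hr=float(np.mean([s.burst_time_hr for s in spectra])),
        n_pixels_averaged=min(s.n_pixels_averaged for s in spectra),
        n_bursts_averaged=sum(s.n_bursts_averaged for s in spectra),
    )


def differential_spectrogram(
    baseline: PowerSpectrum,
    post_spectra: list[PowerSpectrum],
    floor_fraction: float = 1e-4,
    debias: bool = False,
) -> DifferentialSpectrogram:
    """Assemble the log10 relative-change spectrogram.

    ``values[f, t] = log10((S_post(f, t) + ε) / (S_base(f) + ε))`` with
    ``ε = floor_fraction × median(S_base)``, which keeps the ratio finite on
    empty bins without biasing well-populated ones.

    With ``debias=True`` the chi-square log bias is removed: a periodogram
    bin averaged over ``k`` independent (complex-Gaussian) realizations has
    ``E[ln Ŝ] = ln S + ψ(k) − ln k``, so the log ratio of a single post
    burst against a multi-burst baseline average sits systematically below
    zero under the null; subtracting the known bias difference recenters it.
    The correction is zero whenever both sides average equally many
    periodograms, so exact-identity inputs still map to exactly zero.
    """
    if not post_spectra:
        raise ValueError("post_spectra must be non-empty")
    if floor_fraction <= 0:
        raise ValueError("floor_fraction must be positive")
    times = np.array([s.burst_time_hr for s in post_spectra], dtype=float)
    if np.any(np.diff(times) <= 0) and times.size > 1:
        raise ValueError("post burst times must be strictly ascending")
    for s in post_spectra:
        if s.freqs.shape != baseline.freqs.shape or not np.allclose(
            s.freqs, baseline.freqs
        ):
            raise ValueError("post spectrum grid does not match the baseline grid")

    eps = floor_fraction * float(np.median(baseline.density))
    if eps <= 0:
        eps = floor_fraction  # all-zero baseline: fall back to an absolute floor
    post = np.stack([s.density for s in post_spectra], axis=1)  # (n_freqs, n_times)
    values = np.log10((post + eps) / (baseline.density[:, None] + eps))
    if debias:
        from scipy.special import digamma

        def log10_bias(k: int) -> float:
            return (digamma(k) - np.log(k)) / np.log(10.0)

        k_base = baseline.n_pixels_averaged * baseline.n_bursts_averaged
        for t, s in enumerate(post_spectra):
            k_post = s.n_pixels_averaged * s.n_bursts_averaged
            values[:, t] -= log10_bias(k_post) - log10_bias(k_base)
    return DifferentialSpectrogram(
        freqs=baseline.freqs.copy(),
        frame_times_hr=times,
        values=values,
        baseline=baseline,
    )
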