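"""Time-frequency biomarkers of drug response.

A well's differential spectrogram is reduced to named scalars through
time-frequency masks: integrated relative power, band means, the fraction of
strongly inhibited bins, the log-frequency centroid shift (a proxy for
changed intracellular speeds), the collective fluctuation amplitude, and the
apoptosis concurrence index (simultaneous low- and high-band enhancement —
positive only when both bands rise). Well values aggregate to a patient ×
arm vector by the median, and the panel is narrowed to the ``k`` candidates
with the strongest Spearman correlation against the ordinal outcome grade.

The candidate panel deliberately exceeds the classifier's 20 inputs (each
family is evaluated over the whole post-treatment window and over its early
and late halves), so the selection step does real work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import DEFAULT_BANDS, HIGH_BAND, LOW_BAND, FrequencyBand
from .spectral import (
    DifferentialSpectrogram,
    PowerSpectrum,
    baseline_average,
    burst_power_spectrum,
    differential_spectrogram,
)
from .synthetic import GRADE_ORDINAL

__all__ = [
    "TimeFrequencyMask",
    "BiomarkerVector",
    "FeatureMatrix",
    "masked_mean",
    "integrated_power",
    "band_features",
    "inhibition_occurrence",
    "spectral_shift",
    "fluctuation_amplitude",
    "apoptosis_index",
    "well_candidates",
    "aggregate_patient",
    "select_biomarkers",
]


@dataclass(frozen=True)
class TimeFrequencyMask:
    """A rectangular band/window region of the differential spectrogram."""

    name: str
    freq_band: tuple[float, float]  # [f_lo, f_hi) Hz
    time_window: tuple[float, float]  # [t_lo, t_hi) hours post-treatment
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.freq_band[0] < self.freq_band[1]:
            raise ValueError(f"mask {self.name!r}: f_lo must be < f_hi")
        if not self.time_window[0] < self.time_window[1]:
            raise ValueError(f"mask {self.name!r}: t_lo must be < t_hi")


@dataclass
class BiomarkerVector:
    """Named biomarker scalars for one patient × arm, aggregated over wells."""

    patient_id: str
    arm: str
    values: dict[str, float]
    n_wells: int

    def __post_init__(self) -> None:
        if not (1 <= self.n_wells <= 32):
            raise ValueError("n_wells must lie in [1, 32]")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite biomarker values: {bad}")


@dataclass
class FeatureMatrix:
    """Standardized patient × biomarker matrix for the classifier.

    ``center``/``scale`` are the training-row statistics used for
    standardization; apply them to new rows with :meth:`transform`.
    """

    patient_ids: list[str]
    columns: list[str]
    values: np.ndarray  # standardized, (n_patients, n_columns)
    center: np.ndarray
    scale: np.ndarray

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Standardize raw candidate rows (same column order) with stored stats."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        return (raw - self.center) / self.scale


# ---------------------------------------------------------------------------
# scalar biomarkers
# ---------------------------------------------------------------------------


def masked_mean(dspec: DifferentialSpectrogram, mask: TimeFrequencyMask) -> float:
    """Weighted mean of spectrogram values inside the mask's band/window."""
    fsel = (dspec.freqs >= mask.freq_band[0]) & (dspec.freqs < mask.freq_band[1])
    tsel = (dspec.frame_times_hr >= mask.time_window[0]) & (
        dspec.frame_times_hr < mask.time_window[1]
    )
    if not (fsel.any() and tsel.any()):
        raise ValueError(f"mask {mask.name!r} does not overlap the spectrogram grid")
    return float(mask.weight * dspec.values[np.ix_(fsel, tsel)].mean())


def integrated_power(dspec: DifferentialSpectrogram) -> float:
    """Mean relative spectral change over the whole post-treatment grid."""
    return float(dspec.values.mean())


def band_features(
    dspec: DifferentialSpectrogram,
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    time_window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Per-band mean relative change (over all post times unless windowed)."""
    if time_window is None:
        t = dspec.frame_times_hr
        time_window = (float(t.min()), float(t.max()) + 1e-9)
    out = {}
    for band in bands:
        m = TimeFrequencyMask(band.name, (band.low_hz, band.high_hz), time_window)
        out[band.name] = masked_mean(dspec, m)
    return out


def inhibition_occurrence(dspec: DifferentialSpectrogram, threshold: float = 0.2) -> float:
    """Fraction of grid bins showing strong inhibition (value < −threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(dspec.values < -threshold))


def spectral_shift(baseline: PowerSpectrum, post: PowerSpectrum) -> float:
    """Signed shift of the log-frequency spectral centroid (decades).

    The centroid is ``Σ log10(f)·S(f) / Σ S(f)``; positive means the
    fluctuation power moved to higher frequencies. Invariant under global
    scaling of either spectrum.
    """
    if baseline.freqs.shape != post.freqs.shape or not np.allclose(
        baseline.freqs, post.freqs
    ):
        raise ValueError("spectra are on mismatched frequency grids")

    def centroid(s: PowerSpectrum) -> float:
        total = s.density.sum()
        if total <= 0:
            raise ValueError("spectrum has no power; centroid undefined")
        return float((np.log10(s.freqs) * s.density).sum() / total)

    return centroid(post) - centroid(baseline)


def fluctuation_amplitude(series_per_pixel: np.ndarray) -> float:
    """Collective fluctuation amplitude: pixel-averaged std/mean of intensity."""
    x = np.asarray(series_per_pixel, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    means = x.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("normalized fluctuation requires strictly positive means")
    return float(np.mean(x.std(axis=1) / means))


def apoptosis_index(
    dspec: DifferentialSpectrogram,
    low_band: FrequencyBand = LOW_BAND,
    high_band: FrequencyBand = HIGH_BAND,
    time_window: tuple[float, float] | None = None,
) -> float:
    """Concurrence of low- and high-band enhancement.

    ``min(mean_low, mean_high)`` clipped below at 0 — positive only when BOTH
    bands are enhanced, the spectral signature of apoptosis.
    """
    if time_window is None:
        t = dspec.frame_times_hr
        time_window = (float(t.min()), float(t.max()) + 1e-9)
    lo = masked_mean(
        dspec, TimeFrequencyMask("low", (low_band.low_hz, low_band.high_hz), time_window)
    )
    hi = masked_mean(
        dspec,
        TimeFrequencyMask("high", (high_band.low_hz, high_band.high_hz), time_window),
    )
    return float(max(0.0, min(lo, hi)))


# ---------------------------------------------------------------------------
# per-well candidate panel and patient aggregation
# ---------------------------------------------------------------------------


def well_candidates(
    series: np.ndarray,
    burst_times_hr: np.ndarray,
    n_baseline: int,
    frame_rate_hz: float,
    floor_fraction: float = 1e-4,
    inhibition_threshold: float = 0.2,
) -> dict[str, float]:
    """Full candidate biomarker panel for one well.

    ``series`` is ``(n_bursts, n_pixels, n_samples)`` of detected intensity,
    baseline bursts first. Each family is evaluated over the whole
    post-treatment window and over its early and late halves (22 candidates),
    so downstream selection has real choices.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(burst_times_hr, dtype=float)
    if series.shape[0] != times.size:
        raise ValueError("one burst time per burst required")
    if not (2 <= n_baseline <= series.shape[0] - 2):
        raise ValueError("need >= 2 baseline and >= 2 post bursts")

    spectra = [
        burst_power_spectrum(series[b], frame_rate_hz, times[b])
        for b in range(series.shape[0])
    ]
    base = baseline_average(spectra[:n_baseline])
    post = spectra[n_baseline:]
    dspec = differential_spectrogram(base, post, floor_fraction, debias=True)

    t = dspec.frame_times_hr
    t_mid = float((t.min() + t.max()) / 2.0)
    whole = (float(t.min()), float(t.max()) + 1e-9)
    early = (float(t.min()), t_mid)
    late = (t_mid, float(t.max()) + 1e-9)

    def mean_post_spectrum(window: tuple[float, float]) -> PowerSpectrum:
        sel = [s for s in post if window[0] <= s.burst_time_hr < window[1]]
        return PowerSpectrum(
            freqs=base.freqs,
            density=np.mean([s.density for s in sel], axis=0),
            burst_time_hr=float(np.mean([s.burst_time_hr for s in sel])),
            n_pixels_averaged=min(s.n_pixels_averaged for s in sel),
        )

    feats: dict[str, float] = {"integrated_power": integrated_power(dspec)}
    for name, window in (("early", early), ("late", late)):
        m = TimeFrequencyMask(
            name, (float(dspec.freqs[0]), float(dspec.freqs[-1]) + 1e-9), window
        )
        feats[f"integrated_{name}"] = masked_mean(dspec, m)
    for name, val in band_features(dspec).items():
        feats[f"band_{name}"] = val
    for wname, window in (("early", early), ("late", late)):
        for name, val in band_features(dspec, time_window=window).items():
            feats[f"band_{name}_{wname}"] = val
    feats["inhibition_frac"] = inhibition_occurrence(dspec, inhibition_threshold)
    for wname, window in (("early", early), ("late", late)):
        tsel = (t >= window[0]) & (t < window[1])
        feats[f"inhibition_{wname}"] = float(
            np.mean(dspec.values[:, tsel] < -inhibition_threshold)
        )
    feats["spectral_shift"] = spectral_shift(base, mean_post_spectrum(whole))
    feats["spectral_shift_early"] = spectral_shift(base, mean_post_spectrum(early))
    feats["spectral_shift_late"] = spectral_shift(base, mean_post_spectrum(late))
    feats["apoptosis"] = apoptosis_index(dspec)
    feats["apoptosis_early"] = apoptosis_index(dspec, time_window=early)
    feats["apoptosis_late"] = apoptosis_index(dspec, time_window=late)
    post_series = series[n_baseline:].reshape(-1, series.shape[-1])
    feats["fluct_amplitude"] = fluctuation_amplitude(post_series)
    return feats


def aggregate_patient(
    per_well_vectors: Sequence[Mapping[str, float]], patient_id: str, arm: str
) -> BiomarkerVector:
    """Median across replicate wells, per biomarker (permutation-invariant)."""
    if not per_well_vectors:
        raise ValueError("at least one well vector required")
    keys = list(per_well_vectors[0].keys())
    for v in per_well_vectors[1:]:
        if list(v.keys()) != keys:
            raise ValueError("well vectors carry inconsistent biomarker names")
    values = {
        k: float(np.median([v[k] for v in per_well_vectors])) for k in keys
    }
    return BiomarkerVector(
        patient_id=patient_id, arm=arm, values=values, n_wells=len(per_well_vectors)
    )


def select_biomarkers(
    candidates: pd.DataFrame,
    outcomes: Mapping[str, str] | pd.Series,
    k: int = 20,
) -> tuple[list[str], FeatureMatrix, pd.DataFrame]:
    """Keep the ``k`` candidates most correlated with the ordinal grade.

    ``candidates`` is indexed by patient_id with one column per biomarker.
    Columns are ranked by absolute Spearman correlation against the ordinal
    grade (0 < 1 < 2/3); ties break by column name order; constant columns
    get correlation 0. The selected columns are standardized to zero
    mean / unit variance over the supplied (training) rows.
    """
    outcomes = pd.Series(dict(outcomes)) if not isinstance(outcomes, pd.Series) else outcomes
    common = [p for p in candidates.index if p in outcomes.index]
    if len(common) < 3:
        raise ValueError("selection requires at least 3 graded patients")
    if k > candidates.shape[1]:
        raise ValueError(
            f"k={k} exceeds the {candidates.shape[1]} available candidates"
        )
    x = candidates.loc[common]
    y = np.array([GRADE_ORDINAL[str(outcomes[p])] for p in common], dtype=float)

    rows = []
    for name in x.columns:
        col = x[name].to_numpy(dtype=float)
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(col, y).statistic)
            if not np.isfinite(rho):
                rho = 0.0
        rows.append({"name": name, "spearman_rho": rho, "abs_rho": abs(rho)})
    report = pd.DataFrame(rows).sort_values(
        ["abs_rho", "name"], ascending=[False, True], kind="stable"
    )
    report["rank"] = np.arange(1, len(report) + 1)
    selected = list(report["name"].iloc[:k])

    raw = x[selected].to_numpy(dtype=float)
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale[scale == 0] = 1.0
    fm = FeatureMatrix(
        patient_ids=list(common),
        columns=selected,
        values=(raw - center) / scale,
        center=center,
        scale=scale,
    )
    return selected, fm, report.reset_index(drop=True)
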