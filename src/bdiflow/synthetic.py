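"""Synthetic cohorts for the biodynamic-imaging chemosensitivity pipeline.

Real acquisitions interrogate living tumor biopsies: ~1 mm³ pieces immobilized
in 96-well plates (16–32 wells per patient), imaged for a 4-hour pre-treatment
baseline and 10 hours after drug application, with one spectral time frame
roughly every 40 minutes. Intracellular motion produces dynamic speckle whose
intensity-fluctuation spectrum is well described by a knee (Lorentzian-like)
spectrum ``S(f) = A / (1 + (f / f_k)^s)``.

This module emulates that phenomenology so every downstream stage is testable
without instrument data. Drug response is encoded through three effect
families, matching the qualitative signatures the method exploits:

* broadband **inhibition** of fluctuation power (cytoskeletal slow-down),
* concurrent **low- and high-band enhancement** (the apoptosis signature),
* a **knee-frequency shift** (change of characteristic intracellular speeds).

Three response phenotypes are generated: sensitive (Grade 0, full-strength
effects), mixed (Grade 1, half-strength), and resistant (Grade 2/3, near-null
response). Grades 2 and 3 are a single pooled phenotype.

All randomness flows through :class:`numpy.random.SeedSequence` keyed on
``(cohort seed, grade, patient, arm, well)``, so a cohort is byte-identical
for identical ``(spec, seed)`` regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bands import HIGH_BAND, LOW_BAND
from .holography import HologramStack

__all__ = [
    "GRADES",
    "GRADE_ORDINAL",
    "DEFAULT_ARMS",
    "AcquisitionConfig",
    "PhenotypeParams",
    "CohortSpec",
    "SyntheticCohort",
    "default_phenotypes",
    "analysis_freqs",
    "target_spectrum",
    "synthesize_intensity_series",
    "generate_cohort",
    "generate_hologram_stack",
    "speckle_field",
]

#: Pathological response grade tokens; grades 2 and 3 are pooled.
GRADES = ("0", "1", "23")

#: Ordinal position of each grade (0 = complete response ... 2 = partial/none).
GRADE_ORDINAL = {"0": 0, "1": 1, "23": 2}

#: The six in-vitro treatment arms: four single agents and the two clinical
#: combination regimens.
DEFAULT_ARMS = (
    "cisplatin",
    "carboplatin",
    "5fu",
    "paclitaxel",
    "cisplatin+5fu",
    "carboplatin+paclitaxel",
)

#: Mean detected intensity (arbitrary counts) about which fluctuations ride.
MEAN_INTENSITY = 100.0


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing.

    ``wavelength_nm`` and ``section_thickness_um`` are carried as metadata
    only (840 nm superluminescent diode; ~20 µm coherence-gated sections).
    The camera burst parameters define the fluctuation analysis band:
    25 Hz × 512 frames gives 0.049–12.5 Hz.
    """

    wavelength_nm: float = 840.0
    section_thickness_um: float = 20.0
    frame_rate_hz: float = 25.0
    frames_per_burst: int = 512
    burst_interval_min: float = 40.0
    baseline_duration_hr: float = 4.0
    post_duration_hr: float = 10.0
    image_size_px: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "burst_interval_min",
                     "baseline_duration_hr", "post_duration_hr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frames_per_burst < 64:
            raise ValueError("frames_per_burst must be at least 64")
        if self.n_baseline_bursts < 2:
            raise ValueError("baseline must contain at least 2 bursts")
        if self.n_post_bursts < 2:
            raise ValueError("post-treatment window must contain at least 2 bursts")
        if self.frame_rate_hz < 2.0 * HIGH_BAND.high_hz:
            raise ValueError(
                "frame_rate_hz must exceed twice the top analysis frequency "
                f"({HIGH_BAND.high_hz} Hz)"
            )

    @property
    def n_baseline_bursts(self) -> int:
        return int(self.baseline_duration_hr * 60.0 / self.burst_interval_min)

    @property
    def n_post_bursts(self) -> int:
        return int(self.post_duration_hr * 60.0 / self.burst_interval_min)

    def burst_times_hr(self) -> np.ndarray:
        """Burst centre times in hours relative to treatment (negative = baseline)."""
        dt = self.burst_interval_min / 60.0
        base = -self.baseline_duration_hr + (np.arange(self.n_baseline_bursts) + 0.5) * dt
        post = (np.arange(self.n_post_bursts) + 0.5) * dt
        return np.concatenate([base, post])


@dataclass(frozen=True)
class PhenotypeParams:
    """Drug-response phenotype in terms of the three spectral effect families.

    The baseline spectrum is ``S(f) = A / (1 + (f/f_k)^s)`` with knee
    ``knee_freq_hz`` and roll-off exponent ``knee_slope``. Post-treatment, the
    spectrum is multiplied broadband by ``inhibition_factor``, the low/high
    analysis bands by their gains, and the knee moves to
    ``knee_freq_hz × knee_shift_factor``. Effects ramp in linearly over
    ``onset_hr`` hours. ``well_variability_cv`` jitters effect strength
    across replicate wells.
    """

    grade_label: str = "0"
    knee_freq_hz: float = 0.3
    knee_slope: float = 2.0
    inhibition_factor: float = 1.0
    low_band_gain: float = 1.0
    high_band_gain: float = 1.0
    knee_shift_factor: float = 1.0
    onset_hr: float = 1.0
    well_variability_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.grade_label not in GRADES:
            raise ValueError(f"grade_label must be one of {GRADES}")
        if self.knee_freq_hz <= 0:
            raise ValueError("knee_freq_hz must be positive")
        if self.knee_slope <= 0:
            raise ValueError("knee_slope must be positive")
        if not (0.0 < self.inhibition_factor <= 1.0):
            raise ValueError("inhibition_factor must lie in (0, 1]")
        if self.low_band_gain <= 0 or self.high_band_gain <= 0:
            raise ValueError("band gains must be positive")
        if self.knee_shift_factor <= 0:
            raise ValueError("knee_shift_factor must be positive")
        if self.onset_hr <= 0:
            raise ValueError("onset_hr must be positive")
        if self.well_variability_cv < 0:
            raise ValueError("well_variability_cv must be nonnegative")

    def scaled(self, scale: float) -> "PhenotypeParams":
        """Phenotype with all treatment effects attenuated toward null.

        Multiplicative effects are raised to ``scale`` so that ``scale = 0``
        is exactly the null (untreated) phenotype and ``scale = 1`` is this
        one. The baseline spectrum (knee, slope) is untouched.
        """
        if scale < 0:
            raise ValueError("scale must be nonnegative")
        return replace(
            self,
            inhibition_factor=min(1.0, self.inhibition_factor ** scale),
            low_band_gain=self.low_band_gain ** scale,
            high_band_gain=self.high_band_gain ** scale,
            knee_shift_factor=self.knee_shift_factor ** scale,
        )


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """Default grade → phenotype map: sensitive / mixed / resistant.

    The sensitive phenotype carries full-strength effects; the mixed grade is
    its half-strength attenuation; the resistant grade retains a residual 10%
    response (real non-responders are rarely perfectly inert).
    """
    sensitive = PhenotypeParams(
        grade_label="0",
        inhibition_factor=0.45,
        low_band_gain=1.8,
        high_band_gain=1.7,
        knee_shift_factor=0.65,
    )
    return {
        "0": sensitive,
        "1": replace(sensitive.scaled(0.5), grade_label="1"),
        "23": replace(sensitive.scaled(0.1), grade_label="23"),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Size and composition of a synthetic cohort.

    ``arm_effect_scaling`` attenuates the drug effect per arm (1.0 = full
    effect, 0.0 = inert vehicle); arms absent from the map get 1.0.
    ``patient_variability_cv`` lognormally jitters each patient's baseline
    knee frequency and overall effect strength, so patients within a grade
    are similar but not identical.
    """

    n_patients_per_grade: tuple[int, int, int] = (6, 6, 6)
    wells_per_patient: int = 16
    arms: tuple[str, ...] = DEFAULT_ARMS
    arm_effect_scaling: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    n_pixels_per_well: int = 4
    patient_variability_cv: float = 0.1

    def __post_init__(self) -> None:
        if len(self.arms) == 0:
            raise ValueError("arms list must not be empty")
        if not (16 <= self.wells_per_patient <= 32):
            raise ValueError("wells_per_patient must lie in [16, 32]")
        for g, n in zip(GRADES, self.n_patients_per_grade):
            if n > 0 and n < 2:
                raise ValueError(
                    f"grade {g}: a represented grade needs at least 2 patients "
                    "(triplet formation requires 2 same-class members)"
                )
        if self.n_pixels_per_well < 1:
            raise ValueError("n_pixels_per_well must be at least 1")


# ---------------------------------------------------------------------------
# spectral model and time-series synthesis
# ---------------------------------------------------------------------------


def analysis_freqs(n_samples: int, frame_rate_hz: float) -> np.ndarray:
    """Positive one-sided frequency grid (Hz), zero bin excluded."""
    return np.fft.rfftfreq(n_samples, d=1.0 / frame_rate_hz)[1:]


def target_spectrum(
    phenotype: PhenotypeParams,
    phase: str,
    elapsed_hr: float = 0.0,
    freqs: np.ndarray | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Model fluctuation spectral density on a positive frequency grid.

    ``phase`` is ``"baseline"`` or ``"post"``. For the post phase the three
    effect families are applied at a strength that ramps linearly from 0 at
    treatment time to full effect at ``onset_hr``; baseline is independent of
    ``elapsed_hr``.
    """
    if freqs is None:
        freqs = analysis_freqs(512, 25.0)
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise ValueError("frequency grid must be strictly positive and ascending")
    if phase not in ("baseline", "post"):
        raise ValueError(f"phase must be 'baseline' or 'post', got {phase!r}")
    if phenotype.knee_freq_hz <= 0 or phenotype.knee_slope <= 0:
        raise ValueError("knee frequency and slope must be positive")

    base = amplitude / (1.0 + (f / phenotype.knee_freq_hz) ** phenotype.knee_slope)
    if phase == "baseline":
        return base

    fk_post = phenotype.knee_freq_hz * phenotype.knee_shift_factor
    effect = amplitude / (1.0 + (f / fk_post) ** phenotype.knee_slope)
    effect = effect * phenotype.inhibition_factor
    effect = np.where(LOW_BAND.mask(f), effect * phenotype.low_band_gain, effect)
    effect = np.where(HIGH_BAND.mask(f), effect * phenotype.high_band_gain, effect)

    ramp = float(np.clip(elapsed_hr / phenotype.onset_hr, 0.0, 1.0))
    return (1.0 - ramp) * base + ramp * effect


def _synthesize_batch(
    density: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase Fourier synthesis of zero-mean series, batched.

    ``density`` has shape ``(..., n_bins)`` sampled on
    ``analysis_freqs(n_samples, fs)``; the output has shape
    ``(..., n_samples)`` and an expected one-sided periodogram equal to the
    target density (complex-Gaussian spectral coefficients, exact zero DC).
    """
    density = np.asarray(density, dtype=float)
    if not np.all(np.isfinite(density)):
        raise ValueError("target spectrum contains non-finite values")
    if np.any(density < 0):
        raise ValueError("target spectrum must be nonnegative")
    n_bins = density.shape[-1]
    if n_bins != n_samples // 2:
        raise ValueError(
            f"density must be sampled on the {n_samples // 2} positive rfft bins"
        )
    shape = density.shape[:-1]
    coeffs = np.zeros(shape + (n_bins + 1,), dtype=complex)
    # interior bins: complex Gaussian, E|X_k|^2 = d_k N^2 / 2
    g = rng.standard_normal(shape + (n_bins - 1, 2))
    coeffs[..., 1:-1] = (
        np.sqrt(density[..., :-1] * n_samples**2 / 4.0) * (g[..., 0] + 1j * g[..., 1])
    )
    # Nyquist bin (real): E|X|^2 = d N^2
    coeffs[..., -1] = np.sqrt(density[..., -1]) * n_samples * rng.standard_normal(shape)
    return np.fft.irfft(coeffs, n=n_samples, axis=-1)


def synthesize_intensity_series(
    spectrum: np.ndarray,
    n_samples: int,
    frame_rate_hz: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One zero-mean real series whose expected periodogram matches ``spectrum``.

    ``spectrum`` is a density sampled on ``analysis_freqs(n_samples,
    frame_rate_hz)``. A fixed integer seed gives bit-identical output.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    del frame_rate_hz  # the grid is implied by (n_samples, fs); synthesis is per-bin
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return _synthesize_batch(np.asarray(spectrum, dtype=float), n_samples, rng)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """In-memory synthetic dataset.

    ``series[(patient_id, arm)]`` is an array of shape
    ``(n_wells, n_bursts, n_pixels, n_samples)`` of detected intensity
    (baseline bursts first). ``grades`` has one row per patient with columns
    ``patient_id``, ``grade`` and the administered ``arm``.
    """

    acquisition: AcquisitionConfig
    spec: CohortSpec
    phenotypes: dict[str, PhenotypeParams]
    burst_times_hr: np.ndarray
    n_baseline_bursts: int
    series: dict[tuple[str, str], np.ndarray]
    grades: "object"  # pandas.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.grades["patient_id"])


def generate_cohort(
    spec: CohortSpec,
    acq: AcquisitionConfig | None = None,
    phenotypes: Mapping[str, PhenotypeParams] | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort of intensity series plus truth grades.

    Every patient receives ``spec.wells_per_patient`` wells in every arm; each
    well is imaged for the configured baseline and post-treatment bursts. The
    administered regimen of each patient is assigned round-robin over
    ``spec.arms`` (deterministic), mirroring that each clinical patient maps
    to exactly one representative analysis arm.
    """
    import pandas as pd

    acq = acq or AcquisitionConfig()
    phenos = dict(phenotypes or default_phenotypes())
    for g, n in zip(GRADES, spec.n_patients_per_grade):
        if n > 0 and g not in phenos:
            raise ValueError(f"no phenotype supplied for represented grade {g}")

    n = acq.frames_per_burst
    freqs = analysis_freqs(n, acq.frame_rate_hz)
    times = acq.burst_times_hr()
    n_base = acq.n_baseline_bursts

    series: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    pidx = 0
    for gi, grade in enumerate(GRADES):
        for pi in range(spec.n_patients_per_grade[gi]):
            pid = f"P{pidx:03d}"
            prng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, gi, pi, 0xC0])
            )
            cv = spec.patient_variability_cv
            knee_jitter = float(np.exp(cv * prng.standard_normal())) if cv else 1.0
            effect_jitter = max(0.0, 1.0 + cv * prng.standard_normal()) if cv else 1.0
            pheno_p = replace(
                phenos[grade],
                knee_freq_hz=phenos[grade].knee_freq_hz * knee_jitter,
            )
            administered = spec.arms[pidx % len(spec.arms)]
            rows.append({"patient_id": pid, "grade": grade, "arm": administered})

            for ai, arm in enumerate(spec.arms):
                arm_scale = float(spec.arm_effect_scaling.get(arm, 1.0))
                out = np.empty(
                    (spec.wells_per_patient, times.size, spec.n_pixels_per_well, n)
                )
                for wi in range(spec.wells_per_patient):
                    wrng = np.random.default_rng(
                        np.random.SeedSequence([spec.seed, gi, pi, ai, wi])
                    )
                    wcv = pheno_p.well_variability_cv
                    well_scale = (
                        max(0.0, 1.0 + wcv * wrng.standard_normal()) if wcv else 1.0
                    )
                    pheno_w = pheno_p.scaled(arm_scale * effect_jitter * well_scale)
                    dens = np.empty((times.size, freqs.size))
                    for bi, t in enumerate(times):
                        if bi < n_base:
                            dens[bi] = target_spectrum(pheno_w, "baseline", freqs=freqs)
                        else:
                            dens[bi] = target_spectrum(
                                pheno_w, "post", elapsed_hr=float(t), freqs=freqs
                            )
                        # one pixel-average target per burst; pixels share it
                    fluct = _synthesize_batch(
                        np.broadcast_to(
                            dens[:, None, :],
                            (times.size, spec.n_pixels_per_well, freqs.size),
                        ),
                        n,
                        wrng,
                    )
                    out[wi] = MEAN_INTENSITY + fluct
                series[(pid, arm)] = out
            pidx += 1

    grades = pd.DataFrame(rows, columns=["patient_id", "grade", "arm"])
    return SyntheticCohort(
        acquisition=acq,
        spec=spec,
        phenotypes=phenos,
        burst_times_hr=times,
        n_baseline_bursts=n_base,
        series=series,
        grades=grades,
    )


# ---------------------------------------------------------------------------
# hologram forward model
# ---------------------------------------------------------------------------


def speckle_field(
    shape: tuple[int, int],
    bandlimit: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bandlimited complex Gaussian speckle field of unit RMS amplitude.

    ``bandlimit`` is the spatial-frequency radius (cycles/pixel) retained;
    a fully developed speckle pattern from a finite imaging aperture is
    bandlimited in exactly this way.
    """
    white = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    keep = fy**2 + fx**2 <= bandlimit**2
    fieldf = np.fft.fft2(white) * keep
    fld = np.fft.ifft2(fieldf)
    rms = np.sqrt(np.mean(np.abs(fld) ** 2))
    return fld / rms


def generate_hologram_stack(
    object_field_series: np.ndarray,
    carrier: tuple[float, float],
    reference_amplitude: float,
    seed: int | None = None,
    shot_noise: bool = False,
    timestamps: np.ndarray | None = None,
) -> HologramStack:
    """Off-axis interference forward model.

    Each frame is ``|R|² + |O|² + 2·Re(R*·O·e^{i2π k·x})`` sampled on the
    pixel grid, where ``R`` is a plane reference wave of real amplitude
    ``reference_amplitude`` and ``k`` the spatial carrier in cycles/pixel.
    Optional shot noise replaces intensities with Poisson counts.
    """
    obj = np.asarray(object_field_series)
    if obj.ndim == 2:
        obj = obj[None]
    if obj.ndim != 3:
        raise ValueError("object_field_series must be (frames, rows, cols)")
    ky, kx = float(carrier[0]), float(carrier[1])
    if abs(ky) >= 0.5 or abs(kx) >= 0.5:
        raise ValueError(
            f"carrier {carrier} at or above the Nyquist limit of 0.5 cycles/pixel"
        )
    if reference_amplitude <= 0:
        raise ValueError("reference_amplitude must be positive")

    _, rows, cols = obj.shape
    y = np.arange(rows)[:, None]
    x = np.arange(cols)[None, :]
    phase = np.exp(2j * np.pi * (ky * y + kx * x))
    r = reference_amplitude
    frames = r**2 + np.abs(obj) ** 2 + 2.0 * np.real(r * obj * phase)
    frames = np.maximum(frames, 0.0)
    if shot_noise:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    if timestamps is None:
        timestamps = np.arange(frames.shape[0], dtype=float)
    return HologramStack(
        frames=frames,
        timestamps=np.asarray(timestamps, dtype=float),
        pixel_pitch=1.0,
        carrier_hint=(ky, kx),
        metadata={"seed": seed, "reference_amplitude": reference_amplitude},
    )
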