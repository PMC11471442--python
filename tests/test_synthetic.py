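"""Synthetic-cohort generator: spectral model, noise synthesis, forward optics."""

import numpy as np
import pytest

from bdiflow.holography import fourier_demodulate, guard_band_mask
from bdiflow.spectral import burst_power_spectrum
from bdiflow.synthetic import (
    AcquisitionConfig,
    CohortSpec,
    PhenotypeParams,
    analysis_freqs,
    default_phenotypes,
    generate_cohort,
    generate_hologram_stack,
    speckle_field,
    synthesize_intensity_series,
    target_spectrum,
)

FREQS = analysis_freqs(512, 25.0)


class TestTargetSpectrum:
    def test_null_effect_reduces_to_baseline(self):
        p = PhenotypeParams(inhibition_factor=1.0, low_band_gain=1.0,
                            high_band_gain=1.0, knee_shift_factor=1.0)
        base = target_spectrum(p, "baseline", freqs=FREQS)
        post = target_spectrum(p, "post", elapsed_hr=8.0, freqs=FREQS)
        np.testing.assert_allclose(post, base)

    def test_pure_inhibition_scales_uniformly(self):
        p = PhenotypeParams(inhibition_factor=0.5)
        base = target_spectrum(p, "baseline", freqs=FREQS)
        post = target_spectrum(p, "post", elapsed_hr=5.0, freqs=FREQS)
        np.testing.assert_allclose(post, 0.5 * base)

    def test_knee_closed_form(self):
        # S(f_k) / S(f→0) = 1 / (1 + 1) for s = 2, by the knee formula
        p = PhenotypeParams(knee_freq_hz=0.1, knee_slope=2.0)
        s = target_spectrum(p, "baseline", freqs=np.array([0.1]), amplitude=1.0)
        assert s[0] == pytest.approx(0.5)

    def test_baseline_independent_of_elapsed_time(self):
        p = PhenotypeParams(inhibition_factor=0.4)
        a = target_spectrum(p, "baseline", elapsed_hr=0.0, freqs=FREQS)
        b = target_spectrum(p, "baseline", elapsed_hr=9.0, freqs=FREQS)
        np.testing.assert_array_equal(a, b)

    def test_strictly_positive_output(self):
        p = default_phenotypes()["0"]
        for phase, t in (("baseline", 0.0), ("post", 0.2), ("post", 9.0)):
            assert np.all(target_spectrum(p, phase, t, FREQS) > 0)

    @pytest.mark.parametrize("bad", [dict(knee_freq_hz=-1.0), dict(knee_slope=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PhenotypeParams(**bad)

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError):
            target_spectrum(PhenotypeParams(), "baseline", freqs=np.array([0.0, 0.1]))

    def test_effect_monotonic_in_inhibition(self):
        # expected integrated post/baseline power ratio strictly decreases
        ratios = []
        for inh in (1.0, 0.8, 0.5, 0.3):
            p = PhenotypeParams(inhibition_factor=inh)
            base = target_spectrum(p, "baseline", freqs=FREQS)
            post = target_spectrum(p, "post", elapsed_hr=8.0, freqs=FREQS)
            ratios.append(post.sum() / base.sum())
        assert np.all(np.diff(ratios) < 0)


class TestIntensitySynthesis:
    def test_same_seed_bit_identical(self):
        dens = target_spectrum(PhenotypeParams(), "baseline", freqs=FREQS)
        a = synthesize_intensity_series(dens, 512, 25.0, seed=9)
        b = synthesize_intensity_series(dens, 512, 25.0, seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.mean() == pytest.approx(0.0, abs=1e-12)

    def test_flat_target_gives_flat_average_periodogram(self):
        n = 256
        dens = np.full(n // 2, 0.5)
        rng = np.random.default_rng(3)
        acc = np.zeros(n // 2)
        reps = 200
        for _ in range(reps):
            x = synthesize_intensity_series(dens, n, 25.0, rng)
            acc += burst_power_spectrum(x, 25.0, 0.0).density
        acc /= reps
        # band-averaged flatness (thirds of the grid)
        for chunk in np.array_split(acc, 3):
            assert chunk.mean() == pytest.approx(0.5, rel=0.10)

    def test_delta_target_yields_tone_at_that_bin(self):
        n = 512
        dens = np.zeros(n // 2)
        dens[40] = 1.0
        x = synthesize_intensity_series(dens, n, 25.0, seed=4)
        ps = burst_power_spectrum(x, 25.0, 0.0)
        assert int(np.argmax(ps.density)) == 40
        assert ps.density[40] / ps.density.sum() > 0.999

    def test_expected_power_matches_target_sum(self):
        dens = target_spectrum(PhenotypeParams(), "baseline", freqs=FREQS)
        rng = np.random.default_rng(11)
        var = np.mean(
            [synthesize_intensity_series(dens, 512, 25.0, rng).var() for _ in range(200)]
        )
        assert var == pytest.approx(dens.sum(), rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthesize_intensity_series(np.full(256, np.nan), 512, 25.0, 0)
        with pytest.raises(ValueError):
            synthesize_intensity_series(np.ones(16), 32, 25.0, 0)


class TestAcquisitionConfig:
    def test_default_timeline(self):
        acq = AcquisitionConfig()
        assert acq.n_baseline_bursts == 6
        assert acq.n_post_bursts == 15
        t = acq.burst_times_hr()
        assert t[0] < 0 < t[-1] and np.all(np.diff(t) > 0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(baseline_duration_hr=0.5),  # < 2 baseline bursts
            dict(post_duration_hr=0.5),
            dict(frame_rate_hz=10.0),  # below twice the top analysis band
            dict(frames_per_burst=32),
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            AcquisitionConfig(**bad)


class TestCohort:
    def test_counts_and_shapes(self, tiny_cohort):
        assert len(tiny_cohort.grades) == 6
        assert sorted(tiny_cohort.grades["grade"].value_counts().to_dict().items()) == [
            ("0", 2), ("1", 2), ("23", 2)
        ]
        arr = tiny_cohort.series[("P000", "cisplatin")]
        assert arr.shape == (16, 5, 4, 128)

    def test_identical_spec_and_seed_identical_dataset(self, tiny_acq):
        spec = CohortSpec(n_patients_per_grade=(2, 0, 2), arms=("a",), seed=5)
        c1 = generate_cohort(spec, tiny_acq)
        c2 = generate_cohort(spec, tiny_acq)
        for key in c1.series:
            np.testing.assert_array_equal(c1.series[key], c2.series[key])
        assert c1.grades.equals(c2.grades)

    def test_inert_arm_statistically_null(self, tiny_acq):
        spec = CohortSpec(
            n_patients_per_grade=(2, 0, 0),
            arms=("drug", "vehicle"),
            arm_effect_scaling={"vehicle": 0.0},
            seed=13,
        )
        co = generate_cohort(spec, tiny_acq)
        fs = tiny_acq.frame_rate_hz
        nb = co.n_baseline_bursts

        def band_ratio(arr):
            # mean post/baseline total power over wells
            ratios = []
            for w in range(arr.shape[0]):
                base = np.mean(
                    [burst_power_spectrum(arr[w, b], fs, 0).density.sum() for b in range(nb)]
                )
                post = np.mean(
                    [
                        burst_power_spectrum(arr[w, b], fs, 0).density.sum()
                        for b in range(nb, arr.shape[1])
                    ]
                )
                ratios.append(post / base)
            return np.asarray(ratios)

        null = band_ratio(co.series[("P000", "vehicle")])
        treated = band_ratio(co.series[("P000", "drug")])
        assert abs(null.mean() - 1.0) < 3 * null.std(ddof=1) / np.sqrt(null.size)
        assert treated.mean() < 0.85  # strong-effect sensitive phenotype inhibits

    @pytest.mark.parametrize(
        "bad",
        [
            dict(arms=()),
            dict(wells_per_patient=8),
            dict(wells_per_patient=40),
            dict(n_patients_per_grade=(1, 2, 2)),
        ],
    )
    def test_spec_invariants(self, bad):
        with pytest.raises(ValueError):
            CohortSpec(**bad)


class TestHologramForward:
    def test_zero_object_gives_constant_frame(self):
        O = np.zeros((1, 32, 32), dtype=complex)
        stack = generate_hologram_stack(O, (0.25, 0.2), reference_amplitude=3.0)
        np.testing.assert_allclose(stack.frames[0], 9.0)

    def test_constant_object_gives_carrier_fringes(self):
        O = np.full((1, 64, 64), 0.5 + 0j)
        stack = generate_hologram_stack(O, (0.25, 0.125), reference_amplitude=1.0)
        spec = np.abs(np.fft.fft2(stack.frames[0] - stack.frames[0].mean()))
        iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
        fy = np.fft.fftfreq(64)[iy]
        fx = np.fft.fftfreq(64)[ix]
        assert (abs(fy), abs(fx)) == (0.25, 0.125)

    def test_carrier_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_hologram_stack(np.zeros((1, 16, 16), complex), (0.5, 0.1), 1.0)

    def test_demodulation_round_trip(self, rng):
        O = 0.4 * speckle_field((64, 64), 0.06, rng)
        stack = generate_hologram_stack(O, (0.3, 0.3), reference_amplitude=2.0)
        rec = fourier_demodulate(stack.frames[0], (0.3, 0.3), aperture_radius=0.12)
        m = guard_band_mask((64, 64), 8)
        amp = np.sqrt(rec.intensity()[m])
        truth = np.abs(O[m])
        scale = np.sum(amp * truth) / np.sum(truth**2)
        rel_rms = np.sqrt(np.mean((amp - scale * truth) ** 2) / np.mean((scale * truth) ** 2))
        assert rel_rms < 0.05
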