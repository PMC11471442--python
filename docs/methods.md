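# Methods

## Signal model

The observable is the temporal fluctuation of reconstructed speckle
intensity in coherence-gated optical sections (~20 µm) of living biopsy
tissue. The baseline fluctuation spectral density is modeled as a knee
spectrum

    S(f) = A / (1 + (f / f_k)^s),

flat below the knee frequency `f_k` (default 0.3 Hz) and rolling off as
`f^-s` above it (default exponent `s = 2`). This is the generic spectrum of
exponentially correlated intracellular motion and is the shape the
fluctuation-spectroscopy literature fits to dynamic tissue speckle.

Drug response is expressed through exactly three effect families, because
these are the signatures the biomarker stage exploits:

| effect | parameter | sensitive default | meaning |
|---|---|---|---|
| broadband inhibition | `inhibition_factor` ∈ (0, 1] | 0.45 | overall slow-down of intracellular motion |
| band enhancement | `low_band_gain`, `high_band_gain` > 0 | 1.8, 1.7 | concurrent low+high-band rise — the apoptosis signature |
| knee shift | `knee_shift_factor` > 0 | 0.65 | change of characteristic intracellular speeds |

Post-treatment the spectrum interpolates linearly from baseline to the
fully affected spectrum over `onset_hr` (default 1 h). Effects compose
multiplicatively and are attenuated toward null by raising them to a power
(`PhenotypeParams.scaled`): the mixed phenotype (Grade 1) is the sensitive
one at scale 0.5; the resistant phenotype (Grade 2/3, generated as one
pooled class) at scale 0.1 — resistant tissue is rarely perfectly inert.
Effect magnitudes have no published values; they were fixed once at values
giving clearly separable but overlapping grades and are configuration, not
claims.

Per-well heterogeneity multiplies the effect scale by
`max(0, 1 + cv·N(0,1))` with `well_variability_cv = 0.15`; per-patient
heterogeneity (`patient_variability_cv = 0.1`) jitters the baseline knee
frequency lognormally and the overall effect strength, so patients within
a grade are similar but not identical.

## Acquisition emulation

Defaults follow the clinical protocol where stated: a 4-hour baseline,
10 hours post-treatment, one burst per ~40-minute interval (6 baseline +
15 post bursts), 16–32 wells per patient, six treatment arms, λ = 840 nm
and ~20 µm sections carried as metadata. Camera parameters are not part of
the protocol record; the generator adopts 25 Hz × 512-frame bursts, giving
an analysis band of 0.049–12.5 Hz that comfortably spans the three
analysis bands (low 0.05–0.5, mid 0.5–3, high 3–12.5 Hz, half-open
edges). Each well contributes `n_pixels_per_well = 4` independent pixel
series per burst; real acquisitions average thousands of sample pixels,
and 4 is an economy that the well-level median absorbs (see
*Limitations*).

Time series are synthesized by random-phase Fourier synthesis with
complex-Gaussian spectral coefficients scaled so the expected one-sided
periodogram equals the target density; the DC coefficient is zero, so
series are exactly zero-mean. A fixed seed is bit-reproducible; every
series draws its generator from a `SeedSequence` keyed on
(cohort seed, grade, patient, arm, well), making the dataset identical
regardless of generation order.

The hologram forward model is plain off-axis interference,
`|R|² + |O|² + 2 Re(R*·O·e^{i2πk·x})`, with optional Poisson shot noise
(off by default). Synthetic object fields are bandlimited speckle; keeping
the object bandwidth inside the demodulation aperture is what makes the
round trip exact, mirroring a real imaging system whose aperture sets the
speckle grain.

## Reconstruction

Demodulation selects one sideband with a circular hard aperture (default
radius: half the carrier magnitude), rolls the nearest carrier bin to the
origin, and inverse-transforms. The conjugate ambiguity is resolved to the
half-plane of positive first frequency coordinate; intensities are
conjugation-invariant so the choice is cosmetic. Apertures reaching into
the DC autocorrelation disk raise a warning and flag the result rather
than failing. All intensity statistics exclude a border guard band
(default 8 px) to avoid wrap-around artifacts. No depth processing is
performed: coherence gating happens at acquisition time and each frame is
one already-gated section.

## Spectra and differential spectrograms

Per burst, pixel series are mean-subtracted, optionally windowed
(rectangular default; Hann available) and periodogram-transformed with a
normalization that keeps Parseval exact for the rectangular window (bin
sum = series variance); pixel periodograms are averaged on linear power.
The zero-frequency bin is excluded everywhere. Baselines are arithmetic
means of ≥ 2 pre-treatment spectra. The differential spectrogram is

    D(f, t) = log10( (S_post(f, t) + ε) / (S_base(f) + ε) ),
    ε = floor_fraction × median(S_base),   floor_fraction = 1e-4,

a symmetric measure of enhancement vs inhibition with a floored
denominator.

One statistical subtlety: a periodogram bin averaged over `k` independent
Gaussian realizations has `E[ln Ŝ] = ln S + ψ(k) − ln k`, so the log ratio
of a single post burst (k = 4 pixels) against a 6-burst baseline average
(k = 24) sits ≈ 0.05 log₁₀-units below zero under the null. The candidate
pipeline therefore applies the known chi-square log-bias correction
(`debias=True` in `differential_spectrogram`), which recenters null wells
on zero and vanishes whenever both sides average equally many
periodograms — exact-identity inputs still map to exactly zero. The
correction assumes Gaussian fluctuations, which the generator satisfies by
construction.

## Biomarkers and selection

The per-well candidate panel evaluates each biomarker family over the
whole post-treatment window and over its early and late halves — 22
candidates, deliberately more than the classifier's 20 inputs so selection
does real work. Wells aggregate to the patient × arm level by the median
(robust to occasional dead wells, permutation-invariant). Each patient
contributes the arm matching their administered regimen; concatenating all
arms before selection is available as a configuration. Candidates are
ranked by |Spearman ρ| against the ordinal grade (Spearman, because grades
are ordinal; constant columns get ρ = 0; ties break by name order), the
top 20 kept, and standardization (zero mean, unit variance) is computed on
training rows only, after selection on raw aggregated values.

## Classifier

The embedding network is fixed at 20-20-10-3 (two tanh hidden layers,
linear 3-D output; tanh chosen as a bounded activation suited to
small-sample metric learning, ReLU available). It is trained with Adam
(lr 1e-3, β = 0.9/0.999, 500 epochs, 128 uniformly sampled valid triplets
per epoch) on the squared-distance triplet loss with margin m = 1. The
network, gradients and optimizer are implemented directly in NumPy — at
this size an autodiff framework adds dependency weight without benefit.
Classes with one member cannot anchor triplets and are excluded from
anchor sampling with a warning; a training run whose mean loss does not
decrease raises a non-convergence warning.

k-means (k = 3, k-means++ with 10 restarts, via scikit-learn) clusters
the training embeddings; each cluster takes the majority grade of its
members, ties toward the lower grade. Likelihoods are the softmax of
negative squared centroid distances with temperature τ = mean
within-cluster squared distance of the training fold — scale-adaptive, so
assignments harden as clusters tighten. The dominant likelihood is the
prediction, exact ties toward the lower grade.

One-left-out validation refits everything — selection, standardization,
embedding, clustering — on the remaining patients for every fold; the
held-out row is provably never read during fold fitting (`fit_fold`
receives only the training ids, and a poison test asserts the fold model
is unchanged when the held-out row is corrupted). Ungraded patients are
scored by every fold's model and averaged, never trained on, never
counted in metrics. Selection inside the fold is the default; a flag
reproduces the selection-outside protocol at the cost of selection
leakage.

## Evaluation

All metrics derive from the 3×3 predicted-vs-actual confusion matrix and
are carried as exact integer fractions; a zero-denominator metric is
reported as not-applicable, never silently zero. ROC curves are built by a
threshold sweep over unique two-class scores (Σ p_positive − Σ p_negative,
classes outside the comparison contribute zero and such patients are
dropped), with trapezoid AUC; tests pin this to the Mann–Whitney pairwise
statistic at 1e-10. The Wald interval (normal approximation, clipped) is
provided because it is the interval used in trial planning; the
Clopper–Pearson interval (beta quantiles) is the reporting interval. The
per-subject table distributed with the package is synthetic: it is
constrained only by the published 3×3 cell counts, as the subject-level
appendix is not public.

## Problem sizes in the shipped runs

The analysis scripts and acceptance run use a 6/6/6-patient cohort with 16
wells, one treatment arm, and the full 6 + 15-burst timeline; the
synthetic-recovery check repeats this over ten seeds plus ten
label-permuted nulls. The pipeline-determinism check uses a 2/2/2 cohort
with a shortened (2 + 3-burst, 128-frame) timeline. These sizes were
chosen so a complete run stays in the minutes range on one CPU while
keeping every stage statistically meaningful.

## Known limitations

* 4 pixel series per well stand in for full-frame pixel averages; per-well
  spectra are accordingly noisier than instrument data, which the well
  median absorbs.
* The generator produces Gaussian, stationary-per-burst fluctuations;
  real tissue shows drift within bursts, non-Gaussian heavy tails,
  motility bursts, and arm-correlated responses within a patient, none of
  which are modeled. Passing tests demonstrate correctness of the
  pipeline's operations, not clinical performance on real tissue.
* Cohort-scale runs synthesize intensity series directly; full hologram
  stacks for every burst of every well (~10¹⁰ samples) are generated only
  on demand for single-stack validation of the reconstruction stage.
* The true identity of the 20 clinical biomarkers is not public; the
  package reproduces the named families and the selection procedure, not
  the original feature list.
* Grade 2 and 3 tissues are one pooled phenotype, as in the three-class
  clinical comparison.
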