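# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the validation-study designs, in the package's own terms.

## Scope and data model

The package analyses epoched multichannel EEG (`EpochSet`: trials × channels ×
samples in µV, with montage, sampling rate, 0-based stimulus-onset index and
per-trial condition labels CA/CU). The pre-stimulus window of length `w` is
always the half-open slice `[onset - w, onset)`. All topographic analyses use
the average reference, which makes maps reference-free; per-electrode spectral
analyses are deliberately reference-*dependent* and are repeated under five
reference schemes (average, linked mastoids, FPz, Cz, Oz) to demonstrate that
dependence.

## Synthetic generator

Each trial is a sum of four components:

1. **Microstates.** A piecewise-constant sequence of template topographies.
   Durations are uniform on 80–120 ms; the epoch opens partway through an
   ongoing state. Templates are forward-projected fields of randomly placed
   dipoles (unit norm, zero mean, pairwise |spatial correlation| ≤ 0.7), so
   they are physically plausible scalp fields. The strength envelope within a
   state is a rectified sinusoid phase-locked to the state run: an integer
   number of half-period arches (base frequency 10 Hz, i.e. ~50 ms arches)
   spans each run, so the field strength peaks mid-state and dips to a
   configurable floor (default 0.1 of the peak) exactly at transitions. This
   mirrors the microstate phenomenology — GFP troughs mark state boundaries —
   and it matters quantitatively: if transitions occurred at full field
   strength, the map discontinuity would be large and any subsequent high-pass
   filtering would ring across entire states. Template polarity is fixed;
   polarity invariance is exercised in the clustering instead.
   Per-condition occurrence weights (`state_weights_ca/cu`) can bias which
   templates occur in which condition; this is the planted counterpart of
   condition-dissociating maps. `state_amplitude` (default 3 µV) is the GFP of
   the state field at the envelope peak — typical of spontaneous EEG.
2. **Alpha.** A 10 Hz cosine whose phase at stimulus onset is drawn per trial
   from a von Mises distribution (κ default 2); the mean direction differs
   between conditions by `condition_phase_offset` (default π). It projects
   through a localized occipital spatial profile (Gaussian bump around Oz,
   unit GFP), amplitude default 1 µV. The von Mises mean-offset model matches
   the assumptions of the Watson–Williams test used downstream.
3. **Differential source.** The forward field of a fixed occipital dipole at
   (0, −0.75, 0) in normalized head coordinates (RAS, head radius 1), scaled
   per condition (field GFP defaults 0.4 µV CA vs 1.2 µV CU). This is the
   recoverable source-level condition effect.
4. **Sensor noise.** Independent Gaussian noise per channel and sample
   (default 0.9 µV = 0.3 × state amplitude).

The generator returns a `GroundTruth` with the per-sample state sequence, the
planted templates, per-trial onset phases, source amplitudes, and any planted
artifact trials. With a fixed seed the output is bit-reproducible.

What the generator does *not* emulate: 1/f background spectra (noise is
white), ocular/muscle artifacts beyond simple amplitude excursions,
inter-subject anatomical variability (all subjects share one montage and
head model), and volume-conduction differences between subjects. Passing
recovery tests therefore demonstrate that the *algorithms* recover planted
structure at realistic SNR, not that real recordings would behave this way.

## Preprocessing

- **References** are linear per-sample transforms (subtract channel mean, a
  named electrode, or the mastoid average); they are idempotent and commute
  with filtering.
- **Band-pass**: 2nd-order Butterworth (1–30 Hz), applied forward and
  backward (zero phase, squared magnitude response), with reflect padding of
  three filter lengths per pass. Filtering is applied to the full epochs
  before any window extraction.
- **Spherical-spline interpolation** (thin-plate spline on the sphere, order
  m = 4, 50 Legendre terms, ridge 1e−5 on the spline system) replaces bad
  channels from the good ones; flagging bad channels is left to the user.
- **Artifact rejection**: absolute-amplitude threshold, default 100 µV —
  deterministic and testable; no oculomotor modeling.

A practical caveat established during development: a 1 Hz high-pass applied
to a short epoch effectively subtracts the epoch-mean topography (a mixture
of the states present), and its step response rings over ~160 ms. For real
continuous recordings this is harmless, but for synthetic ground-truth
scoring it biases every map toward minus the mean of its neighbors. The
clustering validation study therefore scores the raw average-referenced
epochs; the filter has its own measured contract (gain 0.9967 at 10 Hz, DC
attenuation > 40 dB, zero phase shift), and the end-to-end pipeline still
filters by default.

## Microstate analysis

One map per trial: the GFP local maximum (strict, window-interior) closest
to onset within the last 50 ms; if none exists, the sample of maximal GFP
(boundary allowed). Maps from all subjects and both conditions are pooled
and clustered jointly.

The clustering is the modified (polarity-invariant) spatial k-means:
assignment maximizes squared spatial correlation, the template update is the
dominant eigenvector of the assigned maps' scatter (computed by warm-started
power iteration), convergence is declared when the explained variance gains
less than `tol` (relative). The best of `restarts` random data-point
initializations is kept; when scanning an ascending k range, the previous
solution plus the worst-explained map seeds one extra restart, which makes
explained variance non-decreasing in k. On tiny instances the optimum is
verified against exhaustive assignment enumeration.

Model order is the minimum of CV = σ²·((C−1)/(C−1−k))², with σ² the
polarity-invariant mean residual variance and C the channel count. Labeling
assigns each trial to the template with maximal |C| (ties to the lowest
index). GEV is normalized per subject × condition, so condition GEVs are
comparable across subjects with different trial counts; condition contrasts
are paired two-tailed t-tests across subjects (df = n−1).

## Source analysis

**Forward model.** Concentric 3-shell conductor (scalp/skull/brain radii
1.0/0.92/0.87, conductivities 1/0.0125/1). Rather than transcribing a
closed-form shell coefficient, each Legendre mode's radial boundary-value
problem (potential and radial-current continuity, insulating exterior) is
solved as a 5×5 linear system; 60 series terms by default. The angular part
uses the tangential-vector form τ = ê − cosγ·d̂, which is finite for central
dipoles and for electrodes on the dipole axis. Verified against the
homogeneous-sphere closed form (2n+1)/n and the infinite-medium dipole
potential.

**Source space.** A cubic grid (default spacing 0.13, ~900 points) restricted
to a shell between radius 0.35 and the brain boundary — an idealization of a
gray-matter source space: the deep core (white matter, ventricles) carries no
cortical or limbic generators, and excluding it also removes solution points
whose between-subject variance is so small that t-maps peak there spuriously.
"Occipital" is defined as y < −0.5.

**Inverse.** M = R Aᵀ(A R Aᵀ + λI)⁻¹ with prior R⁻¹ = WᵀW + 0.1·I. W
penalizes each point's deviation from the d⁻²-weighted average of neighbors
within 1.5 grid steps; points with truncated neighborhoods (shell
boundaries) have their self-coefficient scaled by N_max/N_i, which removes
the constant field from the prior's null space. The weak energy term keeps
the prior from being dominated by its near-singular smooth modes. λ =
lambda_rel (default 0.1) × mean eigenvalue of A R Aᵀ. Magnitudes are
Euclidean norms of the 3-D moments; for pure localization readouts a
standardized magnitude (moment normalized by the 3×3 model covariance of the
estimate, in the spirit of standardized low-resolution tomography) is
available and is what the point-spread study uses — with it, noiseless
single-dipole localization error is ≤ ~1.4 grid spacings.

**Contrast.** Paired two-tailed t-tests across subjects on per-subject mean
magnitudes at every solution point, Benjamini–Hochberg FDR at q = 0.05, and
the maximal-|t| point reported. The pipeline restricts trials to those
labeled with the dissociating templates (the condition-specific maps),
falling back to all trials when too few subjects retain both conditions; an
`all_trials` switch reproduces the control analysis.

## Spectral analysis

Blackman-windowed DFT of the raw (re-referenced, unfiltered) 200 ms
pre-stimulus window: at 1000 Hz this gives 5 Hz bins with 10 Hz exactly on
bin 2; no zero padding or interpolation, and off-bin frequency requests are
errors. Band-passing is deliberately not applied on this path — the 1–30 Hz
filter belongs to the microstate path, and filtering before phase estimation
would distort the window mainlobe. One caveat the tests encode explicitly: a
three-term Blackman window has mainlobe support through bin 2, so a DC
offset leaks ~10% of its amplitude into the 10 Hz bin; power invariance to
constant offsets holds only beyond the mainlobe.

Phase statistics are circular: per-subject circular-mean angles per condition
and electrode, then a Watson–Williams test across subjects per electrode
(F with the 1 + 3/(8κ̂) correction, κ̂ from the mean within-sample resultant
via Fisher's approximation; a warning is issued below mean resultant 0.45).
Lags are circular differences of the group mean directions in (−180°, 180°];
electrodes with p < 0.05 and |lag| > 170° are flagged as near-inversions.
The electrode-wise phase tests are reported uncorrected by default (an FDR
flag exists); the power contrast is FDR-corrected across channels. The
group Watson–Williams operates on per-subject mean angles, not pooled
trials.

## Validation studies and problem sizes

All studies live in `prestim.validation`, derive every random stream from a
single seed, and are run both by the test suite and the reproduction script.
Sizes were chosen for desk-scale runtimes:

- **Template recovery**: 20 cohorts × (204 channels, 5 templates, 150 trials
  per condition, noise 0.3 × state amplitude, alpha and differential source
  disabled to isolate the clustering); CV selected k = 5 in 20/20 cohorts
  with matched-template |C| ≥ 0.95 at the development seeds.
- **Brute-force oracle**: 50 instances of 8 maps × 4 channels, k = 2;
  exhaustive enumeration of sign-free assignments.
- **Watson–Williams calibration**: 20 000 null draws (von Mises κ = 2,
  20 + 20); the test's true type-I rate is ≈ 0.046, slightly conservative,
  as expected for the F-approximation at moderate concentration.
- **Source studies**: 64 channels, grid spacing 0.2 (~220 points). Point
  spread on 20 random noiseless dipoles (standardized readout); planted
  occipital contrast on 20 cohorts of 11 subjects × 30 trials per condition,
  each cohort with its own template draw; FDR control on 200 null
  replicates (equal condition parameters).
- **Reference dependence**: 20 cohorts of 11 subjects with the localized
  occipital alpha profile and opposite-phase conditions; the flagged
  near-inversion electrode sets under average vs Oz references differed in
  every cohort at the development seeds.

## Known limitations

- The spherical 3-shell head and the synthetic "occipital" flag stand in for
  realistic head geometry and anatomical labeling; localization claims are
  therefore tested only as planted-effect recovery in this idealized model.
- The LAURA-style prior's exact coefficients are a design choice (documented
  above); the operator construction is pluggable.
- The CV criterion's penalty is weak at high channel counts; with heavily
  contaminated maps (e.g. short filtered epochs of synthetic step-state
  data) it can select large k. Real spontaneous EEG, and the generator's
  raw-path maps, produce clean minima.
- Behavioral tabulation covers category percentages, ideal-ISI selection and
  RT contrasts only; block-level ANOVA is out of scope.
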