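# Methods

This note documents the models, parameter choices and numerical
decisions behind `nirsemo`, and what the synthetic study generator does
and does not emulate.

## Optics: the modified Beer-Lambert law

Continuous-wave fNIRS measures light intensity `I(λ, t)` per channel at
three wavelengths (785, 808, 850 nm). The optical-density change
`ΔOD = ln(I_ref/I)` is modelled as linear in the chromophore
concentration changes:

```
ΔOD(λᵢ) = (ε_HbO(λᵢ)·ΔC_HbO + ε_HbR(λᵢ)·ΔC_HbR) · r · DPF(λᵢ)
```

* **Inversion.** With 3 wavelengths and 2 unknowns the system is
  overdetermined; the only coherent reading of "inverting" the 3×2
  extinction matrix is the least-squares (Moore-Penrose) solution,
  computed from the pseudoinverse after dividing each wavelength's ΔOD
  by `r·DPF(λ)`. The inverse is exact on forward-generated data (the
  round-trip test requires relative error < 1e-10) and is linear, so
  filtering and averaging commute with it.
* **Extinction table.** The acquisition device's calibration constants
  are not public. The shipped defaults are tabulated hemoglobin
  extinction values at the three wavelengths in natural-log convention
  (mm⁻¹·µM⁻¹: ε_HbO = 1.695, 1.957, 2.437 ×10⁻⁴; ε_HbR = 2.538, 1.681,
  1.591 ×10⁻⁴) with adult-forehead DPFs of 6.1/6.0/5.8. Everything is
  overridable via a YAML table keyed by wavelength; the synthetic
  generator and the inverter read the same table, so recovered
  concentrations are exact up to noise. Because the true device
  constants are unknown, absolute concentration scales are arbitrary —
  which is immaterial for classification, as the SVM z-scores features
  per training fold.
* **Reference intensity.** `I_ref` defaults to the per-channel,
  per-wavelength mean over the whole recording ("mean" policy); a
  pre-stimulus policy is selectable. The choice only shifts ΔOD by a
  per-channel constant, which the later 10-s pre-clip baseline
  correction removes.

## Preprocessing

* **Filter.** Zero-phase (forward-backward) 4th-order Butterworth
  band-pass, 0.01–0.2 Hz. This removes cardiac (~1.2 Hz) and
  respiratory (~0.25 Hz) oscillations and slow drift; Mayer waves
  (~0.1 Hz) sit inside the band and deliberately survive. The filter's
  squared magnitude response is the oracle for the gain tests (pass
  0.1 Hz within [0.9, 1.1]; reject 1.2 Hz below 0.05).
* **Filtering raw intensity.** The pipeline filters before converting
  to optical density. A literal band-pass of raw intensity would remove
  the mean light level and make `ln(I_ref/I)` undefined, so the filter
  is applied to the fluctuation about each channel's mean intensity and
  the mean is restored. For the small fractional fluctuations typical
  of fNIRS this equals filtering ΔOD to first order.
* **Block design vs the high-pass edge.** Clips average 70 s and recur
  roughly every 115–130 s, so the sustained part of a block response
  lies near the 0.01 Hz high-pass edge and is attenuated (roughly
  halved for typical clip lengths in the generator's schedule). The
  end-to-end recovery test therefore compares pipeline output against
  the *same filter applied to the ground truth*, requiring agreement
  within 15%; spatial pattern shape, which is what the decoder uses, is
  preserved because the attenuation is common to all channels.
* **Baseline and epoching.** Per clip, the mean over the 10 s before
  onset is subtracted; the last 30 s of each clip is tiled into three
  half-open, non-overlapping 10-s windows (indexed 1..3, earliest to
  latest; 500 samples each at 50 Hz); each window's per-channel time
  mean is one 24-dimensional feature sample. Clips shorter than 30 s
  are an error — no partial windows. No artifact rejection is
  performed anywhere, mirroring the analysis the package implements.

## Rating analytics

* **Reliability.** ICC(2,k): two-way random effects, absolute
  agreement, average measures across the 13 raters, computed from the
  ANOVA mean squares; it agrees with pingouin's ICC(A,k) to machine
  precision (cross-checked in the tests). ICC(2,1) and ICC(3,k) are
  selectable. Note the average-measures null is skewed: for pure noise
  it behaves as 1 − 1/F with F ~ F(n−1, (n−1)(k−1)), mean ≈ −0.07 for
  30 clips × 13 raters, not 0.
* **Manipulation checks.** For each target emotion, participant-mean
  ratings over its clip group enter a one-way repeated-measures ANOVA
  over the 10 positive items (no sphericity correction by default;
  Greenhouse-Geisser selectable) plus paired t-tests of the target item
  against the other nine, Benjamini-Hochberg corrected over those nine
  p-values. Items are labelled target / lower / higher / not-different.
* **MDS.** Nonmetric (Kruskal) scaling of the 1 − r dissimilarities of
  the 10 positive emotions, SMACOF-optimised from a classical-scaling
  (Torgerson) start, which makes the solution deterministic. Stress-1
  `sqrt(Σ(d − d̂)²/Σd²)` is recomputed from the returned coordinates via
  isotonic regression, so the reported stress always matches the
  embedding. The cluster assignment itself is configuration — the
  default encouragement/playfulness/harmony partition — with an
  advisory hierarchical-clustering helper that never overrides it.
* **Cluster scores and selection.** A clip's cluster score is the plain
  mean of its member-item ratings. Top-6 selection breaks ties by
  ascending clip id. Two clusters' top-6 sets can overlap (one clip can
  score high on both); cluster-vs-cluster contrasts resolve this with a
  deterministic rule: the contested clip goes to the cluster scoring it
  higher, the other refills from its next-best clips.

## Decoding

36 balanced samples (18 per class, three windows from each of six
clips) per contrast and chromophore. Folds are clip-grouped: one clip
per class per fold, six test samples per fold, so a clip's windows
never straddle the split (a "sample-random" reading would leak highly
correlated windows between train and test). The classifier is a
linear-kernel SVM with C = 1 on features z-scored with training-fold
statistics; C was not specified by the analysis being reproduced, and
1 is the standard default. Accuracy pools the 36 held-out predictions
(equal to the mean of fold accuracies here). Permutation chance
shuffles the 36 labels uniformly before a full re-fit of the
cross-validation, 100 times; the mean and SD (ddof = 1) of the shuffle
accuracies are reported. The SD can be taken over shuffles (pooled,
~9-13%) or over participants; both are computable, the shuffle-pooled
form is reported.

## Synthetic study generator

The generator is the package's test bed: 13 participants, 37 clips
(10 positive emotions × 3 clips, 6 negative, 1 neutral, presented
neutral → negatives → positives with within-block shuffling), durations
drawn from a Beta(2, 2.95) stretched to [30, 129] s (mean ≈ 70 s),
rests of 45 s plus up to 15 s jitter, 24 channels at 50 Hz.

* **Signal model.** True ΔC per clip = cluster-specific spatial pattern
  × ramped boxcar (5-s linear ramps) × clip amplitude factor
  (uniform 0.6–1.4) × participant scale (uniform 0.7–1.3). Default peak
  amplitudes: 0.4 µM HbO, 0.2 µM HbR. The patterns are plausibility
  fixtures on a 4×6 channel grid — encouragement: medial HbO increase;
  playfulness: global HbR decrease; harmony: left-lateral; negative:
  right-lateral — configurable, not measured quantities.
* **Noise.** Per channel: cardiac (0.15 µM, 1.2 ± 0.05 Hz), respiratory
  (0.10 µM, 0.25 Hz), Mayer (0.12 µM, 0.10 Hz) sinusoids with random
  phase and amplitude jitter; a normalised random-walk drift (0.2 µM);
  white noise (0.05 µM); and 0.5% multiplicative measurement noise on
  intensity. HbR noise reuses the structure at 0.4×. The in-band
  (Mayer + drift) components dominate the feature-level noise, as in
  real recordings.
* **Ratings.** Latent Gaussian clip profiles with the published 14-item
  correlation matrix (projected to the nearest positive-definite
  matrix by eigenvalue clipping) as target; a clip elevates its target
  emotion by 2.0 latent SD and the target's cluster-mates by 1.5 —
  chosen so designated clips reliably top their own cluster's score,
  the premise of the balanced stimulus selection; participants add
  independent N(0, 0.5²) noise; equal-probability thresholds of the
  marginal latent distribution map to the 1–7 scale. The ±0.05
  correlation-fidelity check applies to the latent base draws (shifts
  disabled) at 3000 clips; the discretised, shifted output preserves
  the qualitative three-cluster geometry rather than the exact printed
  correlations.
* **What it does not emulate.** Motion artifacts, optode-coupling
  changes, habituation or order effects, heterogeneous per-channel DPF,
  anatomical channel positions, and genuinely unknown real-data effect
  sizes. Passing tests demonstrate the pipeline's correctness and
  statistical calibration under this model, not the reproducibility of
  the original study's real-data accuracies, which cannot be recomputed
  without the recordings.

## Problem sizes and determinism

Everything is a pure function of (design, seed); reruns are
bit-identical, and derived seeds come from `numpy` seed sequences (kept
below 2³¹). The test suite exercises reduced sampling rates (5–25 Hz)
and shortened clips for speed — the windowing arithmetic is
rate-independent — while the chance-level acceptance check runs the
full 13-participant, 50 Hz study conditions with 100 shuffles per
classifier (1300 cross-validated null fits). Degenerate inputs
(zero-variance channels or contrasts, rank-deficient extinction
matrices, clips too short to window, non-positive intensities) raise
descriptive errors or flagged NaNs rather than propagating silently.

## Known limitations

* The generator's spatial patterns and amplitudes are caricatures; only
  scale-free conclusions (chance levels, monotone power, pattern-shape
  recovery) transfer to real data.
* Correlation topographies use per-clip mean responses (30 paired
  observations per participant); the per-sample alternative is exposed
  but secondary.
* The SNIRF reader covers the minimal intensity + probe + stim layout
  it writes, not every optional field of the format.
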