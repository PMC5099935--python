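# Methods

This note documents the models, conventions and numerical choices behind
`nirsbci`, in the order the pipeline runs them, and states what the
synthetic test bed does and does not establish about real recordings.

## Montage and optics

The default montage places four sources and four detectors over the
forehead as two 30 mm squares (one per hemisphere) joined by two
midline-crossing pairs, giving ten channels of exactly 30 mm
source–detector separation, five per hemisphere, with channels 4 and 7 on
the Fp1/Fp2 positions of the 10-10 system. The geometry is synthetic: it
reproduces the channel count, separation and frontal landmarks of the
emulated instrument layout, not its exact optode coordinates, which are
irrelevant to every computation downstream (no cortical projection is
performed).

The modified Beer–Lambert law uses molar extinction coefficients from the
standard Gratzer/Cope compilation, converted to mm⁻¹ per mmol/L
(760 nm: ε_HbO = 0.0586, ε_HbR = 0.1549; 850 nm: ε_HbO = 0.1058,
ε_HbR = 0.0691), differential pathlength factors 7.25/6.38 (adult
forehead), and the 30 mm channel separation as the geometric pathlength.
These are instrument conventions rather than results; all are
configurable. Concentrations are expressed in mmol/L throughout, with the
unit recorded on the container to prevent silent µM/mM confusion. The I₀
reference for ΔOD defaults to the per-channel temporal mean of a run —
any constant reference only shifts ΔOD by a constant, which the band-pass
removes. The simulator's forward model is the exact algebraic inverse of
the inversion chain; with an explicit I₀ the round-trip reproduces
concentrations to ~1e-16 (tested at 1e-9).

## Band-pass filter

The hemodynamic band is isolated with a 6-pole Chebyshev type-II
band-pass applied forward–backward (`sosfiltfilt`, odd-reflection
padding), i.e. zero phase lag and a squared magnitude response. A type-II
design is parameterized by its *stopband* edges; placing them at the
printed 0.01–0.2 Hz corners would put 0.1 Hz (the Mayer band the filter
must examine) at −7.5 dB and 0.15 Hz at −23.7 dB, so the printed corners
are treated as the passband and the 40 dB stopband edges are placed at
(lo/2, hi·2.5) = (0.005, 0.5) Hz. Measured single-pass response: −0.26 dB
at 0.02 Hz, −0.03 dB at 0.1 Hz, −1.0 dB at 0.15 Hz, ≤−40 dB at DC and at
≥0.5 Hz (cardiac ~1.1 Hz ends up below 0.5% amplitude after the
forward–backward pass). Filtering runs on the continuous concentration
series before epoching so transients stay at run edges. The narrower
0.01–0.09 Hz variant is available as a preset.

## Epochs, baseline, features

Epochs span −8…25 s around task onsets (trials whose window does not fit
in the run are dropped with a warning), baseline-corrected by the mean
over −2…0 s. The −8 s left edge is what gives all 31 feature windows
(3 s wide, right ends on integer seconds −5…25) full support. "Average
slope" is the within-window OLS regression slope of value against time
(units per second); an endpoint-difference variant exists behind
`slope_kind="endpoint"`. The printed 33.3% window overlap of the source
description conflicts with width 3 s / step 1 s (66.7%); width and step
are treated as authoritative. Feature z-scoring is fitted on training
folds only inside cross-validation; a global fit is available for
sensitivity checks but is never the default.

## Separability statistic

The point-biserial r uses the population (N-denominator) SD of the pooled
trials, which makes perfectly separated equal-sized classes give exactly
|r| = 1 and makes r identical to the Pearson correlation between trial
values and a binary class indicator (the property the test suite pins to
1e-12). p-values come from the exact t transform on n₁+n₂−2 degrees of
freedom; Bonferroni multiplicity defaults to the number of points on the
displayed axis (time samples for per-channel colorbars, channels ×
periods for topographic maps) and is recorded in the output. Maps are
rendered as sign(r)·(−log₁₀ p_adj), positive where MA responds more than
BL.

## Classifiers and the CV protocol

Shrinkage LDA shrinks the pooled within-class covariance toward νI
(ν = trace Σ̂/d) with the analytic Ledoit–Wolf intensity computed from
class-centered data (verified against scikit-learn's estimator to 1e-12;
the γ=0 case is pinned to a classic-LDA solve at 1e-8). If the
within-class scatter is exactly zero the direction falls back to the
class-mean difference. The linear SVM wraps scikit-learn's `SVC`
(C = 1.0 by default, tolerance 1e-6); MA is the positive class for every
decision function.

The protocol is 10 repeats of stratified 5-fold CV. Splits are drawn once
per repeat from the scheme seed and reused across classifiers,
chromophore sets and window anchors, so "identical training and test
samples" is a structural guarantee rather than a convention; the trained
weights of every fold are digested into a hash, and randomizing test-fold
labels at scoring time provably leaves that hash unchanged (the leakage
audit). HbR+HbO fusion trains a 2-feature linear meta-classifier of the
same kind as its bases on out-of-fold base decision values from an inner
stratified 5-fold split of the training data; at test time the bases are
refit on the full training fold. The naive variant (meta trained on
in-sample base outputs) exists behind `inner_folds=None` but is biased
and not used.

Group evaluation: per-subject maxima are taken over anchors in 5–25 s
(hemodynamic delay); paired comparisons use the t-test on differences or
the Wilcoxon signed-rank (zeros dropped, exact null for ≤12 non-zero
differences, normal approximation with continuity correction above —
matching the small-cohort regime). Mutual information between two
classifiers' outputs is the plug-in estimate on hard predicted labels
pooled over all test folds in the 9–13 s peak window (soft-output MI is a
non-default option), regressed against accuracy by OLS.

## Synthetic data: what it emulates and what it does not

The generator reproduces the block design exactly: per paradigm three
runs of 20 trials (10 MA / 10 BL in seeded pseudo-random order), 3 s
instruction, 15 s task, uniform 20–25 s rests, 75 s lead-in, 60 s
lead-out, 15.6 Hz sampling. One seed drives schedule, per-trial amplitude
jitter, physiological noise and measurement noise through a splittable
`SeedSequence`, so each component is independently reproducible and
subject generation is bit-identical per seed.

Responses are double-gamma HRFs (peak delay 6 s, undershoot delay 16 s,
ratio 6; gamma shape delay/dispersion + 1 so the mode sits exactly at the
delay) convolved with the task boxcar and normalized so a unit amplitude
yields a unit-peak single-trial response. HbR is scaled independently of
HbO — not a negative mirror — because the emulated pattern has Δ[HbR]
*increasing* under MA at the anterior channels. The default effect places
the strongest HbR/HbO response on channels 4 and 7 (Fp1/Fp2), subtle
responses on 5 and 6, weak ones elsewhere, and small negative amplitudes
for BL; per-trial amplitudes carry a log-normal jitter (CV 0.2, unit
mean). The task duration defaults to the stated 15 s even though the
figure shading of the emulated study marks 0–10 s; the discrepancy is
surfaced here and the duration is configurable.

Noise per channel: 1/f drift (FFT-shaped, SD 3e-3 mmol/L), a 0.1 Hz
Mayer wave with a random-walk phase (SD 2.4e-3), 0.25 Hz respiration
(1.5e-3), 1.1 Hz cardiac pulsation (1.5e-3), each scaled by a per-channel
log-normal factor (σ = 0.3) so channels are not artificially identical,
with HbR noise at 0.3× the HbO level; white Gaussian noise (SD 6e-3) is
added in optical-density space after the forward model. These levels were
fixed once so that the default cohort's per-subject maximum accuracies
span the realistic ~65–95% range with means in the mid-70s to 80s —
the regime of the emulated study — and are not revisited per experiment.

Passing tests on this generator establish that the pipeline recovers
known ground truth under physiologically plausible noise. They do not
establish robustness to what the generator omits: motion artifacts,
systemic superficial contamination (no short channels), optode-coupling
drift, non-stationary vigilance effects, or inter-subject anatomical
variability. The generator is a correctness instrument, not a subject
model.

## Validation experiments and problem sizes

* **Null calibration** — three cohorts of 5 zero-effect subjects (30+30
  trials each) through the full pipeline; per-anchor cohort-mean LDA
  accuracy must lie in the 95% binomial interval around 50% at
  n = 5×60 trials for ≥90% of anchor points (measured coverage ~94–96%,
  grand mean ~50%).
* **Signal recovery** — a 5-subject cohort with a strong single-channel
  effect (HbR 8e-3 mmol/L on channel 4) at default noise: peak
  cross-validated accuracy must exceed 90% post-onset and the injected
  channel must attain the maximal |r| in the grand-average map.
  "Pre-onset at chance" is assessed against a *matched zero-effect
  cohort with identical noise realizations*, for two measured reasons:
  slow 1/f drift correlates a subject's trials, so per-anchor cohort
  means scatter well beyond independent-Bernoulli counting (the null
  itself can reach ~60%), and zero-phase filtering is acausal, smearing
  a bounded few points of class information into the pre-onset baseline
  — a property of offline zero-phase processing, not a protocol leak
  (unfiltered data classify pre-onset at chance). The pre-onset *excess*
  of the strong cohort over its matched null (measured 0–5 points,
  versus a ~45-point genuine post-onset effect) is bounded at 10 points.
* **Filter contract, protocol audit, oracle suite** — as described above;
  all deterministic and fast.

Cohort sizes (5 subjects, 10×5-fold CV, 31 anchors) are the package's
standard validation configuration; they keep the whole validation suite
in the low minutes on a single CPU while leaving the binomial and
null-matched bands narrow enough to be informative.

## Known limitations

* SNIRF support covers the raw-intensity blocks, probe geometry and
  stimulus tables this package writes; it is not a general SNIRF
  validator.
* The meta-classifier's inner split refits bases ten times per outer
  fold; for much larger feature sets a cached decomposition would be
  worthwhile.
* p-values from the r-map are pointwise; no cluster-level correction is
  offered (Bonferroni only, by design).
* The forward optical model is the homogeneous MBLL; no layered tissue
  or photon-transport modeling.
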