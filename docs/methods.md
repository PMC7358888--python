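# Methods

## The measurement model

The package analyses one signal-averaged beat per subject, recorded on 10
channels at 2 kHz.  The TU complex is treated as the sum of a ventricular
repolarization (T) wave and a following U wave; in the bifid case the
lowest point between the two peaks, **B**, marks the U-wave onset, and the
interval B → U end (**BUe**) is the U duration.  Wave ends are defined by
the **tangent method**: the tangent at the steepest down-slope of the wave,
extrapolated to the isoelectric line (the mean of the 40 ms preceding the
QRS onset).  All temporal parameters are heart-rate corrected by dividing
by √RR (Bazett); the correction is a configuration choice (`correction=
'none'` gives raw intervals) because the defining formula in the source
literature is ambiguous, and Bazett is both standard practice and
consistent with a corrected QTc of ≈ 0.400 s at a heart rate near 63 bpm.

For the multivariate layer the observed leads are modelled as a noiseless
linear mixture **x**(t) = A·**s**(t) of statistically independent,
non-Gaussian source waveforms.  Two consequences are exploited:

* the **PCA ratio** — 100·λ₂/λ₁ of the inter-lead covariance of the
  J-point→U-end segment — measures how far the leads depart from a single
  shared repolarization waveform (0 % for a rank-1 segment; 25 % for two
  orthogonal components with a 4:1 variance ratio);
* **ICA** recovers the sources up to permutation, sign and scale, and the
  **inverse projection** A[:, S]·s_S(t) shows what a subset S of components
  contributes to each original lead.

## Pipeline stages and the parameters that matter

**Beat detection.** Second-derivative energy summed over all leads (the
sharp QRS adds coherently on every channel; tall, steep T waves do not),
smoothed over 80 ms, background-subtracted, thresholded at 20 % of its 98th
percentile; candidate runs less than 120 ms apart are merged and a
periodicity filter removes residual T-wave candidates.  R peaks are the
maxima of the summed squared deflection, refined on a 3.5 ms-smoothed copy.

**Averaging.** Exactly the first 10 sinus beats (an error, never a silent
fallback, if fewer are available), aligned by cross-correlating a 120 ms
QRS window within ±10 ms.  The beat window spans R−300 ms to
R+max(700, 780·RR) ms: the fixed 700 ms tail would clip the U end at heart
rates below ≈ 55 bpm, because the raw QU interval is the corrected QUc
times √RR.

**Denoising.** Per-lead discrete wavelet transform (sym8, level 5), soft
universal threshold σ√(2 log N) with σ from the median absolute deviation
of the finest detail coefficients.  Channels are never mixed.

**Delineation.**  Q onset / J point: the nearest samples before/after R
where the signal returns to within 1 % of the R amplitude of the baseline
with a near-zero local slope (the amplitude tolerance relaxes stepwise at
fast heart rates, where the previous beat's U wave keeps the PQ stretch off
baseline).  T peak: the tallest prominent peak in the first 55 % of the TU
segment.  U peak: the largest-|amplitude| extremum after the T peak (either
polarity, accommodating biphasic U waves), localized on a 20 ms-smoothed
trace because its top is flat.  B: the minimum of the smoothed trace
between the peaks.  Tangent ends anchor on the steepest down-slope of the
limb (searched up to 45 ms short of B for the T wave, so a deep T-U
junction notch cannot masquerade as the T down-slope, and truncated where
the wave has decayed below 8 % of its peak for the U wave); the tangent's
slope and value are estimated by least squares over ±14 ms around the
anchor, which is nearly unbiased there because the anchor is the wave's
inflection point.  U waves smaller than 10 µV (configurable) are reported
as absent.

**ICA stage.** The number of extracted components equals the number of
leads (10).  Each of the `n_runs` (default 50) repetitions fits FastICA
(negentropy fixed point; an order-statistics spacings-entropy backend is
available as a cross-check) on a copy of the centred data perturbed with
white noise of `additive_noise_sd` × per-lead SD, and applies the resulting
unmixing to the unperturbed data, so mixing·sources reconstructs the input
exactly.  The default perturbation is 2 % of the signal SD: measured on
planted mixtures, a 5 % perturbation (0.25 % of variance) drowns the
weakest genuine component dimensions, which carry ~0.5–1 % of variance.
Runs are matched by Hungarian assignment on absolute source correlations;
a component's stability is the mean pairwise |corr| within its cluster,
and the run that agrees best with all others is kept.

**Component counting.** For each component the inverse projection's energy
(averaged over leads) is split between the T window [J, B] and the U window
[B, U end].  A component is **U-specific** if ≥ 90 % of its TU energy lies
in the U window (the operationalization of "exclusively forms the U wave"),
and a **T-IC** if it is majority-T.  Salience is judged **per window**: a
component must carry ≥ 5 % of its own window's energy (summed over
components) to be counted.  The per-window form replaces a single 5 %
threshold against the whole TU complex, which the U wave — with roughly a
tenth of the T wave's energy — could never satisfy for its second
component; under the single-pool rule a two-component U wave would be
uncountable in principle.

**Statistics.** Welch's unequal-variance t test is the default two-group
comparison (the published PCA-ratio p value of .00054 is the Welch value;
the pooled test gives ≈ .0003 and remains available).  Best-subset logistic
regression enumerates all 2^k − 1 non-empty predictor subsets of the 15
U-wave-related explanatory variables plus the intercept-only model and
returns the minimum-AIC fit, with ties broken toward smaller subsets.  The
logistic fit is IRLS with a separation guard: when the deviance collapses
below 10⁻⁶, or the coefficients diverge while every observation is already
correctly classified, the model is flagged `separated` and the limiting
values are reported — log-likelihood 0 and AIC = 2·(number of parameters).
Under complete separation the coefficients are non-identifiable solver
artifacts; the AIC limit and the flag are the reproducible quantities.
ROC analysis uses the rank-statistic AUC (ties counted ½) and the
Youden-index cutoff, ties broken toward higher specificity.

## The synthetic cohort generator

The generator replaces the undeposited patient recordings with cohorts that
have, by construction, the statistical structure the analysis assumes.

**Parameter sampling.** Per subject, HR, QTc, QTp, TpUp, BUp, BUe and the
T/U peak amplitudes are drawn independently from truncated normal
distributions (±3 SD) with the published group means/SDs; QUp, QUc, TeUe
and U/T follow arithmetically, so the vector is internally consistent.
Amplitudes are additionally floored (T ≥ 0.10 mV, U ≥ 15 µV) because
non-positive amplitudes have no waveform meaning, and the heart rate at
35 bpm.

**Waveforms.** Every wave is a sum of asymmetric Gaussian bumps.  The main
T source has a Gaussian fall whose terminal tail is tapered (real T
down-slopes hug the baseline soon after the tangent point; an untapered
Gaussian keeps ~13 % of its peak there, which would bury a small U wave).
Three secondary T sources are narrow bumps tiling the T upstroke —
deliberately staggered and temporally disjoint, because four near-identical
overlapping bumps would be statistically inseparable, whereas the study's
premise is a T wave composed of four identifiable components.  The U wave
is one wide asymmetric bump; ATS1-like subjects optionally add a second,
narrower hump on the U upstroke as a separate source.  Planted U sources
keep ≥ 99 % of their energy inside [B, U end].  Controls receive no
separate U source: the U deflection is a shared late-tail shape embedded in
the last two T sources, so their U wave is made of the same components as
their T wave.

**Calibration.** A staged, damped fixed-point iteration adjusts the main
T bump (shift, scale, fall width), the U bump (shift, scale, rise/fall
widths) and, when the T down-slope and U up-slope cannot place the minimum
themselves, a small notch at B, until the *measured* fiducials of the
analysis-lead composite — measured with the same estimators the delineator
uses — match the drawn parameters to ≤ 1 ms.  Ground truth is then
re-measured from the realized clean waveform, so it is exact for the
waveform by construction.  Draws whose geometry cannot form a bifid TU
complex (e.g. a tall T with a small early U, where the T down-slope at B
exceeds the entire U wave) are rejected and redrawn; roughly 20 % of
ATS1-like and 40 % of control draws are rejected.  At n = 300 per group the
realized means still track the configured ones (BUe 0.234/0.165 s, group
contrast 0.069 vs 0.067 s); the visible cost is an inflated control U
amplitude (≈ 0.073 vs 0.062 mV, hence U/T ≈ 0.12 rather than 0.09),
because the smallest-U draws are the infeasible ones.

**Mixing.** Columns are uniform(0.45, 1) entries normalized to unit norm —
generic, full column rank.  Three structured adjustments (within-column
permutations or damping, preserving the norm): the analysis lead (V2 or V3,
chosen per subject) carries the largest entry of the main T and main U
columns, so lead selection is unambiguous and the analysis-lead waveform is
textbook-smooth; the secondary T columns put their two smallest entries on
V2/V3, so the component structure lives on the other leads; and the second
U source's precordial entries are damped to 12 %, placing it mainly on the
auxiliary channels.  Amplitudes of calibrated bumps are expressed in
analysis-lead units (divided by the source's own mixing coefficient), which
makes the analysis-lead morphology independent of the mixing draw.

**Beat trains and noise.** Twelve beats per record, RR jittered by 2 %
(truncated normal), plus white sensor noise of 10 µV SD — a realistic
high-frequency-ECG noise floor that signal averaging reduces by √10.

**What passing tests do and do not show.** The generator produces smooth,
stationary, artefact-free beats: no baseline wander, respiration, muscle
noise, ectopy or T-U morphology changes over time, and its source count is
exactly the structure the classifier seeks.  Recovery results therefore
demonstrate the *internal consistency* of the pipeline — that the
estimators recover the quantities the model defines, at realistic noise
levels — not clinical performance on real recordings.

## Problem sizes used in the tests

Fiducial-recovery runs use 100 noise-free subjects (all fiducials within
±4 ms of truth) and 26 subjects at the default noise (bulk fiducials within
6 ms at the 90th percentile; the bottom of shallow control U waves and
their tangent U ends are noise-limited to ≈ 12 ms).  The component-count
check uses three seeded cohorts of 8 + 8 subjects (≥ 20 analyzable per
condition) with 15 ICA repetitions per subject.  The group-contrast check
simulates 500 subjects per group.  These sizes keep the full suite within a
few minutes while leaving the statistical margins comfortable.

## Known limitations

* The tangent U end and the bottom B of sub-50 µV control U waves are
  noise-limited even after averaging; their per-subject errors reach
  ~10–30 ms at the default sensor noise.
* The feasibility rejection truncates the joint parameter distribution
  (see above); group *contrasts* are preserved but the control U-amplitude
  mean is biased upward by ≈ 1 SD/3.
* The generator's identifiable-source structure is an assumption about the
  data, not a discovery; on real ECGs the number of separable repolarization
  components is an empirical question.
* The generator's inter-lead heterogeneity is milder than a real torso's:
  simulated PCA ratios run ~5 % (ATS1-like) vs ~2 % (control) rather than
  the published ~26 % vs ~10 %.  The group ordering is preserved, which is
  what the cohort-level checks assert; the published PCA-ratio statistics
  are reproduced from their summary statistics instead.
* Best-subset enumeration is exact but exponential; it is capped at 20
  predictors (the study's predictor set has 15).
* No P waves, ectopic beats, or drug-effect modelling; arrhythmic-beat
  rejection beyond requiring 10 clean beats is out of scope.
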