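# Methods

## Problem and pipeline

Pressurised metered-dose inhalers (pMDIs) only deliver their full dose when
the patient actuates the canister *during* a slow, deep inhalation.  Two
critical user-technique errors dominate in practice: poor actuation
coordination (the actuation falls outside the inhalation) and inhaling too
fast (peak inspiratory flow rate, PIFR, above 90 L/min).  With a Flo-Tone
training mouthpiece attached, the inhalation produces a harmonic reed tone
(fundamental roughly 520–570 Hz, fixed per device) whose loudness grows
with flow, which makes both errors measurable from a plain audio recording.

The pipeline has three stages:

1. **Sound-event classification** — every 40 ms frame of the recording is
   assigned to one of four classes (1 noise, 2 exhalation, 3 inhalation,
   4 actuation) by quadratic discriminant analysis (QDA); adjacent frames
   of one class are concatenated into timed events.
2. **Acoustic flow estimation** — the detected inhalation audio is mapped
   to a flow profile through a power-law model of the harmonic band power;
   PIFR and inhaled volume follow from the profile.
3. **Technique assessment** — the event sequence and the PIFR are turned
   into the two dichotomous critical-error findings, with Cohen's kappa
   available for agreement analyses between raters/methods.

## Stage 1: frame classification

**Pre-processing.**  Recordings (RIFF PCM WAV, nominally 48 kHz/16-bit)
are band-pass filtered 140–22 000 Hz and cut into 40 ms frames with a
20 ms step; each frame has its mean (DC) removed.  The filter is a
4th-order Butterworth applied forward and backward (zero phase); the upper
edge is clamped to 0.45·fs when the sample rate cannot represent it.
Trailing partial frames are discarded, so a signal of L samples yields
floor((L − l)/h) + 1 frames of length l at step h.

**Features (30 per frame).**  MFCC 1–12 (26 triangular mel filters over
0–fs/2, log floor 1e−10, orthonormal DCT-II, gain-carrying 0th coefficient
excluded), LPC a1–a10 (autocorrelation method, Levinson–Durbin, error
filter convention A(z) = 1 + Σ aᵢ z⁻ⁱ), RMS energy, zero-crossing rate
(fraction of sign changes, in [0,1]), high-frequency power above 15 kHz
from the continuous wavelet transform (analytic Morlet `cmor1.5-1.0`,
12 voices/octave), the harmonic feature (peak of the lag-normalised
autocorrelation over lags corresponding to 500–600 Hz — near 1 for the
reed tone, small for broadband sounds, exactly gain-invariant), spectral
entropy (Shannon entropy of the PSD as a pmf, bits), sample skewness,
Pearson (non-excess) kurtosis, and the spectral centroid.  The registry is
configurable; the centroid completes the set of 29 features named for the
method to the stated total of 30.

**Training.**  Per class: mean vector, full sample covariance, and a prior
equal to the class frame frequency.  Covariances are regularised with
λ·diag(s²), λ = 1e−6, where s is the vector of pooled per-feature standard
deviations of the training frames.  The per-dimension scaling matters:
the raw features span about six orders of magnitude (spectral centroid in
kHz, band powers near 1e−5), and an isotropic trace-scaled ridge is
dominated by the largest feature and erases the variance structure of the
small ones, effectively disabling the energy and harmonic features as
discriminators.  The diagonal ridge is the same rule computed in
standardised feature space.

**Testing (per recording).**
1. *Noise estimation*: the noise-class mean and covariance are re-fitted
   from the frames holding the lowest 40 % of RMS energy values of the
   recording under test (priors kept); requires at least 13 frames.
2. *Model adaptation*: an initial nearest-mean (Euclidean) classification
   marks inhalation-like frames, and the inhalation mean moves to the
   unweighted average of the trained mean and those frames' centroid —
   one pass, absorbing reed pitch/loudness variation across mouthpieces.
3. *QDA*: each frame goes to the class maximising the prior-weighted
   Gaussian density.  Computed in the log domain (Cholesky factorisation;
   −½ mahalanobis − ½ log|Σ| + log P(ω)), which is exactly the density
   argmax wherever direct evaluation does not underflow.  Ties in either
   rule go to the lowest class id.
4. *Event formation*: an order-5 median filter (edges replicated) smooths
   the label sequence; maximal same-class runs become events spanning
   first-frame start to last-frame end; inhalation and exhalation runs
   shorter than 5 frames (100 ms) are dropped as noise.  Actuation runs
   are kept at any length — real actuation bursts average about five
   frames and can be as short as two, and the duration rule exists to
   suppress false breath events, not to discard genuine actuations.

**Feature selection.**  A greedy forward wrapper adds, at each step, the
feature maximising the weighted performance measure on held-out validation
recordings:

    J(X) = 0.2 (S_A + P_A) + 0.2 (S_I + P_I) + 0.1 (S_E + P_E)

where S/P are *event-level* sensitivity and positive predictive value (in
%, matching how the headline event metrics are reported; whether the
original selection used frame- or event-level metrics is not documented).
Selection stops when the best improvement falls below 0.01 points; the
whole trajectory is recorded so the peak subset can be read off.

## Stage 2: flow estimation

**Pre-processing.**  Inhalation audio is decimated ×4 (anti-aliased FIR,
zero phase), band-pass filtered 200–5000 Hz, and framed 50 ms / 25 ms
step.  Frames are stored unwindowed; the Hanning window whose purpose is
leakage control is applied inside the spectral estimator.  This keeps the
band-power calibration exact: a tone of amplitude A integrates to A²/2
regardless of the framing, which the synthetic generator and the model
round trip rely on.

**Features.**  Per frame: RMS energy E; band power at the reed fundamental
P_f0; and P_f0f1, adding the band at the first harmonic.  The fundamental
is found once per segment by the autocorrelation method restricted to
520–570 Hz with parabolic peak interpolation (±2 Hz); a normalised peak
below 0.2 flags "no reed sound".  Band powers come from a Welch PSD
(Hanning, 512-sample segments, 50 % overlap) integrated over f₀ ± 30 Hz
and 2f₀ ± 30 Hz.  At the 12 kHz working rate, 512-sample segments give
23.4 Hz bins, so the ±30 Hz band always captures a stable 96–100 % of a
tone's mainlobe power; with 256-sample segments (46.9 Hz bins, wider than
the band) the captured fraction swings between ~67 % and ~96 % depending
on where the fundamental falls on the bin grid, which destroys the
calibration.  Harmonics above f₁ are excluded on purpose: the broadband
actuation sound leaks into high frequencies.

**Models.**  Linear (f = αΦ + β) and power-law (ln f = γ ln Φ + δ) fits by
ordinary least squares, the latter in log-log space.  The default model is
the power law on P_f0f1 with (γ, δ) = (0.3183, 7.5061) in **natural**
logarithms: with base-10 logs these coefficients would map plausible band
powers (1e−5…1e−3) to physically absurd flows far above 10⁵ L/min, while
natural logs give the expected 40–240 L/min range.

**PIFR, profile, volume.**  PIFR is the model output at the frame of
maximum P_f0 — that frame tracks the reed, not the broadband burst, so it
is robust to an actuation during the breath.  The profile applies the
model frame by frame, zeroing frames whose P_f0f1 is below 1 % of the
segment maximum (a noise floor that keeps the log model from inventing
flow out of silence).  Volume is the trapezoidal integral of flow/60 over
the frame times (L).  When flow is estimated from a classified recording,
each detected inhalation event span is analysed separately (max PIFR over
spans, summed volume): the classifier has already carved the actuation
frames out of the inhalation, and keeping them out of the analysed audio
keeps their in-band leakage — which can exceed the weak reed tone at low
flows — out of the harmonic bands.

**Accuracy and robustness.**  Estimation accuracy is
100·(1 − |f̂ − f|/f), floored at 0 (the raw difference formula would award
99 % to a zero estimate).  Robustness is probed by adding white Gaussian
noise at −10…25 dB SNR in 5 dB steps (SNR measured over the full signal
support) and tabulating mean ± SE accuracy per feature; Bland–Altman bias
and 95 % limits of agreement summarise paired estimate/reference data.

## Stage 3: technique assessment

*Poor actuation coordination*: no actuation onset lies within the closed
span of any detected inhalation event (missing actuation or inhalation
both count as poor and are flagged).  This operationalises the checklist
guidance that the reed sound should start before the canister is pressed;
the containment rule is the package's formalisation, since no computable
definition was published.  *Inhaling too fast*: PIFR strictly above
90 L/min ("over 90").  Event-level evaluation matches predicted to
labelled events one-to-one, greedily by largest time overlap.  Cohen's
kappa uses marginal-product expected agreement; two constant and identical
raters give κ = 1 by convention, constant-but-unequal raters are rejected
as undefined.  Cohort summaries report the percentage of subjects with at
least one flagged recording per phase (before/after tuition).

## Synthetic data

Patient recordings are not available, so the generator emulates the
acoustic structure the method exploits, with exact ground truth:

* **Inhalation**: trapezoidal (ramp–plateau–ramp) flow profile; a harmonic
  tone at f₀ and 2f₀ (power split 75/25, configurable) gated on where flow
  ≥ the reed onset threshold (default 45 L/min, midpoint of the 30–60
  range over which real devices start sounding).  The instantaneous
  combined band power inverts the default power-law model,
  P = exp((ln f − δ)/γ), so the analysis chain should reproduce the
  programmed flow exactly up to estimation error.  Weak broadband
  turbulence spans the whole breath.
* **Actuation**: white-noise burst (50–500 ms) with 10 ms raised-cosine
  edges — the drug-release sound has a flat-like broadband spectrum.
* **Exhalation**: <1 kHz low-pass filtered noise under a slow envelope.
* **Background**: white (optionally pink) noise mixed at a prescribed SNR
  measured against the event mixture over the full support.

Corpora draw the PIFR cyclically from the four clinical flow ranges
(<60, 60–120, 120–180, 180–240 L/min; the lowest stratum is drawn over
50–60 so the reed is audible), the reed pitch from 520–570 Hz, and jitter
event timings; everything derives from a single master seed through
`numpy.random.SeedSequence`, so corpora regenerate bit-identically.  Label
spans mark the *audible* (reed-active) part of the breath, and an
actuation overlapping a breath is carved out of that breath's label so
event labels never overlap.

What the generator does **not** emulate — and hence what green tests do
not demonstrate about patient data: room acoustics and non-stationary
clinical background noise, device-to-device spectral variation beyond
pitch and loudness, actuation plume temporal structure, breath sounds
without the Flo-Tone, distance and orientation effects of the microphone,
and physiological coupling between flow and inspiratory capacity (a long
high-flow synthetic breath can integrate to an unphysiologically large
volume).  Synthetic classes are also more separable than real ones: the
published event metrics include a moderate exhalation sensitivity
(~41 %) that the clean synthetic exhalations will not reproduce.

## Numerical and design choices

* Zero-phase (`sosfiltfilt`) filtering everywhere a band is defined, so
  event boundaries carry no group delay.
* Log-domain QDA with Cholesky factors; non-positive-definite covariances
  raise rather than silently degrade.
* Ties (nearest mean, density argmax) break to the lowest class id;
  candidate ties in forward selection break to registry order.
* Degenerate inputs are defined, not exceptional: zero frames yield zero
  LPC vectors (with a warning), entropy 0, moments 0; silent segments
  flag "no reed sound"; recordings under 13 frames skip noise estimation;
  a recording with no inhalation-like frames skips adaptation.
* Frame label = class covering the frame midpoint; boundary ties go to the
  later-starting event; uncovered frames are noise.
* Default problem sizes in the test suite (40-recording corpus at
  15–25 dB SNR for end-to-end evaluation, 16 inhalations for the SNR
  sweep, 6 s recordings) were chosen as the smallest corpora at which the
  event metrics and accuracy estimates are stable across seeds.

## Known limitations

* The published identity of the 30 extracted and 11 selected features is
  not public; the registry is a documented, configurable stand-in.
* Exhalation detection is intentionally out of the critical-error logic
  (only coordination and PIFR are assessed), mirroring its limited
  reliability in the original evaluation.
* The volume estimate only integrates audible (reed-active) flow and so
  systematically undershoots the full inspired volume; PIFR is unaffected.
* Breath-hold duration, spacer/VHC use, and checklist digitisation are out
  of scope.
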