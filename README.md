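# inhaleraudio

Audio-based assessment of pressurised metered-dose inhaler (pMDI) user
technique.

Many patients lose most of their inhaled dose to two critical technique
errors: **poor actuation coordination** (pressing the canister outside the
inhalation) and **inhaling too fast** (peak inspiratory flow rate, PIFR,
over 90 L/min).  With a Flo-Tone training mouthpiece on the inhaler, the
inhalation produces a harmonic reed tone (~520–570 Hz fundamental) whose
power grows with flow.  This package detects both errors from a plain
audio recording of inhaler use.  It is aimed at respiratory digital-health
researchers and signal-processing engineers working on objective inhaler
adherence monitoring.

## Method

**Sound-event classification.**  The recording is band-passed
(140–22 000 Hz) and cut into 40 ms frames (20 ms step); 30 features per
frame (MFCC 1–12, LPC a₁–a₁₀, RMS energy, zero-crossing rate, CWT power
above 15 kHz, a 500–600 Hz harmonic feature, spectral entropy, skewness,
kurtosis, spectral centroid) feed a quadratic discriminant:

ω\* = argmax_ω  N(x; μ_ω, Σ_ω) · P(ω),    ω ∈ {noise, exhalation, inhalation, actuation}

with per-recording noise-model re-estimation (lowest 40 % energy frames)
and inhalation-mean adaptation before classification, an order-5 median
filter after it, and a 5-frame (100 ms) minimum duration for breath
events.

**Acoustic flow estimation.**  From the detected inhalation audio
(decimated ×4, band-passed 200–5000 Hz, 50/25 ms frames) the band power
of the reed fundamental and first harmonic P_f0f1 maps to flow through a
power law:

ln f̂ = 0.3183 · ln(P_f0f1) + 7.5061    (natural log, f̂ in L/min)

PIFR is the model output at the frame of maximum fundamental power, and
inhaled volume is the trapezoidal integral of the per-frame flow profile.

**Assessment.**  Coordination is good when an actuation onset falls inside
a detected inhalation event; inhaling too fast means PIFR > 90 L/min.
Cohen's kappa, event sensitivity/PPV and Bland–Altman statistics support
evaluation and agreement analyses.

Patient recordings are not distributable, so `inhaleraudio.synth`
generates labelled, seed-reproducible recordings (reed tone with power
tied to a programmed flow profile, broadband actuation bursts,
low-frequency exhalations, background noise at controlled SNR) with exact
ground truth — every stage of the pipeline is testable end to end.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
python examples/estimate_flow.py
```

```
reed fundamental     : 540.1 Hz
estimated PIFR       : 90.3 L/min   (programmed 90.0)
estimated volume     : 2.47 L      (programmed 2.72)
PIFR accuracy        : 99.7 %
```

A synthetic 2.5 s inhalation programmed to peak at 90 L/min is mixed with
background noise at 20 dB SNR and re-analysed: the reed pitch is recovered
to 0.1 Hz, the power-law model inverts the band power back to 90.3 L/min
(on the boundary of the "too fast" rule), and the integrated volume
undershoots slightly because only the audible part of the breath carries
flow information.  The other examples cover event detection
(`classify_events.py`), the full two-error assessment
(`assess_technique.py`), and noise robustness (`snr_robustness.py`),
which prints the mean PIFR accuracy per SNR showing the harmonic-band
feature beating raw energy below 0 dB.

A thin CLI wraps the same library:

```sh
inhaleraudio synth --n 8 --outdir corpus --seed 1
inhaleraudio train corpus --out models.json
inhaleraudio assess models.json corpus/rec000.wav
```

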