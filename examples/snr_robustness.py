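"""Robustness of acoustic flow estimation to background noise.

Fits power-law flow models for the RMS energy (E) and the harmonic band
power (P_f0f1) features on clean synthetic inhalations, then sweeps white
Gaussian noise from -10 to 25 dB SNR and prints the mean PIFR estimation
accuracy per feature.  The harmonic feature stays accurate at low SNR
because the added broadband noise contributes little power to the narrow
bands around the reed fundamental and its first harmonic.
"""

import numpy as np

import inhaleraudio as ia

rng = np.random.default_rng(7)
design, validation = [], []
for k in range(16):
    profile = ia.InhalationProfile(0.0, float(rng.uniform(2.0, 2.8)),
                                   float(rng.uniform(50, 240)))
    audio, truth = ia.synth_inhalation(profile, float(rng.uniform(520, 570)),
                                       48000.0, seed=int(rng.integers(2 ** 31)))
    (design if k < 8 else validation).append((audio, truth))

models = {}
for feature in ("E", "P_f0f1"):
    phi, flows = [], []
    for audio, truth in design:
        feats = ia.extract_flow_features(audio)
        i = int(np.argmax(feats.P_f0))
        phi.append(feats.feature(feature)[i])
        flows.append(truth.pifr_lmin)
    models[feature] = ia.fit_flow_model(np.array(phi), np.array(flows),
                                        kind="power", feature=feature)

recordings = [(a, t.pifr_lmin, t.volume_l) for a, t in validation]
table = ia.snr_sweep(recordings, models, np.arange(-10, 26, 5), seed=8)
pifr = table[table.metric == "pifr"].pivot(index="snr_db", columns="feature",
                                           values="mean")
print("mean PIFR estimation accuracy (%) per SNR level:")
print(pifr.round(1).to_string())
print("\nAt and below 0 dB the harmonic band power clearly outperforms the "
      "raw energy feature, which absorbs the full broadband noise power.")
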