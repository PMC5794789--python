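"""Seed-reproducible synthetic pMDI + Flo-Tone recordings with known truth.

Patient inhaler recordings cannot be shared, so every pipeline stage is
exercised on generated audio that emulates the acoustics the method relies
on:

* inhalation -- a harmonic reed tone (fundamental 520-570 Hz, first
  harmonic included, power split 75/25) that switches on once the
  programmed inspiratory flow exceeds the reed onset threshold and whose
  band power follows the inverse of the power-law flow model, plus weak
  turbulent broadband noise over the whole breath;
* actuation -- a short white-noise burst (the drug-release sound has a
  flat-like broadband spectrum) with raised-cosine on/offsets;
* exhalation -- low-pass (<1 kHz) filtered noise with a slow envelope;
* background -- white (optionally pink) noise mixed at a controlled SNR.

The generator writes standard WAV + label CSV + truth JSON, so generated
corpora are interchangeable with real labelled recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .flow import DEFAULT_POWER_COEFFS, FlowProfile
from .signal_io import (ACTUATION, EXHALATION, INHALATION, AudioSignal,
                        LabelTrack, write_labels, write_wav)

DEFAULT_FS = 48000.0
DEFAULT_F0_RANGE = (520.0, 570.0)
DEFAULT_REED_THRESHOLD = 45.0        # L/min, midpoint of the 30-60 onset range
HARMONIC_SPLIT = 0.75                # fraction of P_f0f1 in the fundamental
PIFR_STRATA = ((50.0, 60.0), (60.0, 120.0), (120.0, 180.0), (180.0, 240.0))


@dataclass
class InhalationProfile:
    """Trapezoidal (ramp - plateau - ramp) inspiratory flow profile."""

    start_s: float
    duration_s: float
    pifr_lmin: float
    rise_frac: float = 0.25
    fall_frac: float = 0.3

    def flow_at(self, t: np.ndarray) -> np.ndarray:
        """Programmed flow (L/min) at absolute times t."""
        rel = (np.asarray(t, dtype=np.float64) - self.start_s) / self.duration_s
        rise, fall = self.rise_frac, self.fall_frac
        up = rel / rise
        down = (1.0 - rel) / fall
        env = np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, 1.0)
        return self.pifr_lmin * env

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SyntheticScenario:
    """One recording's ground-truth schedule and acoustic parameters."""

    fs: float = DEFAULT_FS
    f0: float = 540.0
    reed_threshold_lmin: float = DEFAULT_REED_THRESHOLD
    duration_s: float = 6.0
    exhalation: tuple[float, float] | None = (0.8, 1.0)      # (start, dur)
    inhalation: InhalationProfile | None = field(
        default_factory=lambda: InhalationProfile(2.4, 2.5, 90.0))
    actuation: tuple[float, float] | None = (3.2, 0.2)       # (onset, dur)
    actuation_amp: float = 0.1
    exhalation_amp: float = 0.02
    turbulence_amp: float = 3e-4
    snr_db: float = 20.0
    noise_color: str = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        if not DEFAULT_F0_RANGE[0] <= self.f0 <= DEFAULT_F0_RANGE[1]:
            raise ValueError("reed pitch must lie in 520-570 Hz")
        if not 30.0 <= self.reed_threshold_lmin <= 60.0:
            raise ValueError("reed onset threshold must lie in 30-60 L/min")
        if self.inhalation is not None and not (
                20.0 <= self.inhalation.pifr_lmin <= 240.0):
            raise ValueError("PIFR must lie in 20-240 L/min")


class ScenarioError(ValueError):
    pass


def _flow_to_band_power(flow_lmin: np.ndarray,
                        coeffs: tuple[float, float] = DEFAULT_POWER_COEFFS,
                        ) -> np.ndarray:
    """Invert the power-law flow model: P = exp((ln f - delta) / gamma)."""
    g, d = coeffs
    with np.errstate(divide="ignore"):
        return np.where(flow_lmin > 0,
                        np.exp((np.log(np.maximum(flow_lmin, 1e-12)) - d) / g),
                        0.0)


def synth_inhalation(profile: InhalationProfile, f0: float, fs: float,
                     seed: int | np.random.Generator,
                     reed_threshold_lmin: float = DEFAULT_REED_THRESHOLD,
                     turbulence_amp: float = 3e-4,
                     coeffs: tuple[float, float] = DEFAULT_POWER_COEFFS,
                     ) -> tuple[AudioSignal, FlowProfile]:
    """Harmonic reed tone tracking the programmed flow profile.

    The tone (f0 plus first harmonic, power split 75/25) is gated on where
    flow >= the reed onset threshold; its instantaneous combined band power
    equals the inverse power-law model of the instantaneous flow.  A weak
    broadband turbulence component spans the entire breath.  Returns the
    audio (length = profile duration) and the true flow profile sampled
    every millisecond.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(profile.duration_s * fs))
    t = np.arange(n) / fs + profile.start_s
    flow = profile.flow_at(t)
    power = np.where(flow >= reed_threshold_lmin,
                     _flow_to_band_power(flow, coeffs), 0.0)
    a0 = np.sqrt(2.0 * HARMONIC_SPLIT * power)
    a1 = np.sqrt(2.0 * (1.0 - HARMONIC_SPLIT) * power)
    phase = 2.0 * np.pi * f0 * (np.arange(n) / fs)
    phi0 = rng.uniform(0, 2 * np.pi)
    tone = a0 * np.sin(phase + phi0) + a1 * np.sin(2.0 * phase + 2.0 * phi0)
    breath_env = np.clip(flow / max(profile.pifr_lmin, 1e-9), 0.0, 1.0)
    turbulence = turbulence_amp * breath_env * rng.normal(0.0, 1.0, n)
    samples = tone + turbulence
    t_truth = np.arange(0.0, profile.duration_s, 1e-3) + profile.start_s
    flows_truth = profile.flow_at(t_truth)
    truth = FlowProfile(t_truth, flows_truth,
                        pifr_lmin=float(flows_truth.max()),
                        volume_l=float(np.trapezoid(flows_truth / 60.0,
                                                    t_truth)))
    return AudioSignal(samples, fs, "synth-inhalation"), truth


def synth_actuation(duration_s: float, fs: float,
                    seed: int | np.random.Generator,
                    amplitude: float = 0.1,
                    ramp_s: float = 0.01) -> AudioSignal:
    """White-noise burst with raised-cosine on/offsets (flat-like spectrum)."""
    if not 0.05 <= duration_s <= 0.5:
        raise ValueError("actuation duration must lie in 0.05-0.5 s")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = rng.normal(0.0, 1.0, n)
    n_ramp = min(int(ramp_s * fs), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    x *= amplitude / max(np.sqrt(np.mean(x ** 2)), 1e-12)
    return AudioSignal(x, fs, "synth-actuation")


def synth_exhalation(duration_s: float, fs: float,
                     seed: int | np.random.Generator,
                     amplitude: float = 0.02,
                     cutoff_hz: float = 1000.0) -> AudioSignal:
    """Low-frequency breath noise: <1 kHz filtered noise, slow envelope."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    sos = sps.butter(4, cutoff_hz / (fs / 2.0), btype="lowpass", output="sos")
    x = sps.sosfilt(sos, rng.normal(0.0, 1.0, n))
    t = np.linspace(0.0, 1.0, n)
    env = np.sin(np.pi * np.clip(t, 0.0, 1.0)) ** 0.5
    x *= env
    x *= amplitude / max(np.sqrt(np.mean(x ** 2)), 1e-12)
    return AudioSignal(x, fs, "synth-exhalation")


def _background(n: int, rng: np.random.Generator, color: str) -> np.ndarray:
    x = rng.normal(0.0, 1.0, n)
    if color == "white":
        return x
    if color == "pink":
        # -3 dB/octave shaping in the frequency domain
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n)
        f[0] = f[1]
        spec /= np.sqrt(f / f[1])
        return np.fft.irfft(spec, n)
    raise ValueError(f"unknown noise colour {color!r}")


def synth_recording(scenario: SyntheticScenario,
                    ) -> tuple[AudioSignal, LabelTrack, FlowProfile]:
    """Mix a full labelled recording from one scenario.

    The label track marks the exhalation span, the *audible* (reed-active)
    part of the inhalation, and the actuation burst; an actuation scheduled
    inside the inhalation is carved out of the inhalation label so the
    event labels stay non-overlapping.  Background noise is scaled to the
    requested SNR measured against the event mixture over the full support.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.duration_s * sc.fs))
    mix = np.zeros(n)
    entries: list[tuple[float, float, int]] = []
    truth = FlowProfile(np.array([0.0, sc.duration_s]), np.zeros(2), 0.0, 0.0)

    def _insert(x: np.ndarray, start_s: float) -> None:
        i0 = int(round(start_s * sc.fs))
        i1 = min(i0 + x.size, n)
        if i1 <= i0:
            raise ScenarioError("event scheduled outside the recording")
        mix[i0:i1] += x[:i1 - i0]

    exhalation_span: tuple[float, float] | None = None
    if sc.exhalation is not None:
        ex_start, ex_dur = sc.exhalation
        ex = synth_exhalation(ex_dur, sc.fs, rng, amplitude=sc.exhalation_amp)
        _insert(ex.samples, ex_start)
        exhalation_span = (ex_start, ex_start + ex_dur)

    audible: tuple[float, float] | None = None
    if sc.inhalation is not None:
        prof = sc.inhalation
        if prof.end_s > sc.duration_s:
            raise ScenarioError("inhalation extends past the recording")
        inh, truth = synth_inhalation(
            prof, sc.f0, sc.fs, rng,
            reed_threshold_lmin=sc.reed_threshold_lmin,
            turbulence_amp=sc.turbulence_amp)
        _insert(inh.samples, prof.start_s)
        active = truth.flows >= sc.reed_threshold_lmin
        if np.any(active):
            audible = (float(truth.times[active][0]),
                       float(truth.times[active][-1]))

    act_span: tuple[float, float] | None = None
    if sc.actuation is not None:
        a_start, a_dur = sc.actuation
        act = synth_actuation(a_dur, sc.fs, rng, amplitude=sc.actuation_amp)
        _insert(act.samples, a_start)
        act_span = (a_start, a_start + a_dur)

    # breath labels, carved around an actuation overlapping them so the
    # class 2-4 event labels stay non-overlapping
    def _carved(span: tuple[float, float]) -> list[tuple[float, float]]:
        if act_span is not None and act_span[0] < span[1] \
                and act_span[1] > span[0]:
            return [(span[0], act_span[0]), (act_span[1], span[1])]
        return [span]

    if exhalation_span is not None:
        for s, e in _carved(exhalation_span):
            if e - s > 1e-6:
                entries.append((s, e, EXHALATION))
    if audible is not None:
        for s, e in _carved(audible):
            if e - s > 1e-6:
                entries.append((s, e, INHALATION))
    if act_span is not None:
        entries.append((act_span[0], act_span[1], ACTUATION))

    p_sig = float(np.mean(mix ** 2))
    if p_sig > 0:
        sigma = np.sqrt(p_sig / 10.0 ** (sc.snr_db / 10.0))
        mix = mix + sigma * _background(n, rng, sc.noise_color)
    else:
        mix = mix + 1e-4 * _background(n, rng, sc.noise_color)

    sig = AudioSignal(mix, sc.fs, f"synth-{sc.seed}")
    return sig, LabelTrack(sorted(entries)), truth


def make_scenarios(n_recordings: int, master_seed: int = 0,
                   snr_range_db: tuple[float, float] = (15.0, 25.0),
                   poor_coordination_frac: float = 0.0,
                   fs: float = DEFAULT_FS) -> list[SyntheticScenario]:
    """Stratified scenario draws: PIFR cycles through the four clinical flow
    ranges; reed pitch, timings and SNR vary per recording."""
    if n_recordings < 1:
        raise ValueError("need at least one recording")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_recordings)]
    rng = np.random.default_rng(ss.generate_state(1)[0] % (2 ** 31))
    scenarios = []
    for k in range(n_recordings):
        lo, hi = PIFR_STRATA[k % len(PIFR_STRATA)]
        pifr = rng.uniform(lo, hi)
        f0 = rng.uniform(*DEFAULT_F0_RANGE)
        inh_start = rng.uniform(2.2, 2.6)
        inh_dur = rng.uniform(2.2, 2.8)
        poor = rng.uniform() < poor_coordination_frac
        if poor:
            act_onset = inh_start - rng.uniform(0.5, 1.0)
        else:
            act_onset = inh_start + inh_dur * rng.uniform(0.35, 0.55)
        scenarios.append(SyntheticScenario(
            fs=fs, f0=f0, duration_s=6.0,
            exhalation=(rng.uniform(0.6, 1.0), rng.uniform(0.8, 1.2)),
            inhalation=InhalationProfile(inh_start, inh_dur, pifr),
            actuation=(act_onset, rng.uniform(0.15, 0.25)),
            snr_db=rng.uniform(*snr_range_db),
            seed=seeds[k]))
    return scenarios


def make_corpus(n_recordings: int, outdir: str | Path,
                master_seed: int = 0, **scenario_kwargs) -> list[Path]:
    """Generate WAV + label CSV + truth JSON per recording; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    scenarios = make_scenarios(n_recordings, master_seed, **scenario_kwargs)
    manifest = []
    for k, sc in enumerate(scenarios):
        sig, track, truth = synth_recording(sc)
        stem = f"rec{k:03d}"
        wav_path = outdir / f"{stem}.wav"
        lab_path = outdir / f"{stem}_labels.csv"
        truth_path = outdir / f"{stem}_truth.json"
        write_wav(wav_path, sig)
        write_labels(lab_path, track)
        truth_path.write_text(json.dumps({
            "pifr_lmin": truth.pifr_lmin,
            "volume_l": truth.volume_l,
            "f0_hz": sc.f0,
            "snr_db": sc.snr_db,
            "seed": sc.seed,
            "flow_times_s": np.round(truth.times, 4).tolist()[::25],
            "flow_lmin": np.round(truth.flows, 3).tolist()[::25],
        }))
        manifest.append(stem)
        paths.extend([wav_path, lab_path, truth_path])
    (outdir / "manifest.csv").write_text(
        "recording\n" + "\n".join(manifest) + "\n")
    return paths
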