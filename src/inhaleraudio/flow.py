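"""Acoustic estimation of inspiratory flow from the Flo-Tone reed sound.

The Flo-Tone mouthpiece emits a harmonic tone (fundamental ~520-570 Hz)
whose power grows with inspiratory flow.  Three per-frame features are
extracted from the inhalation audio: RMS energy E, band power at the
fundamental P_f0, and the combined power of fundamental plus first harmonic
P_f0f1 (higher harmonics are excluded on purpose -- they overlap the
broadband actuation sound).  Flow is mapped from a feature ``phi`` by either

    linear:     f = alpha * phi + beta
    power law:  ln f = gamma * ln phi + delta

The default power-law model for P_f0f1 uses coefficients
(gamma, delta) = (0.3183, 7.5061) with natural logarithms; with base-10
logs the same coefficients would produce physically absurd flows (far above
10^5 L/min) for plausible band powers, while natural logs give the expected
40-240 L/min range.

PIFR is the model output at the frame of maximum P_f0 (that frame is robust
to actuation bursts), and inhaled volume is the trapezoidal integral of the
per-frame flow profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import AudioSignal, EmptyInputError, FrameMatrix, bandpass, frame_signal

FLOW_BAND_HZ = (200.0, 5000.0)
DECIMATION_FACTOR = 4
FLOW_FRAME_S = 0.05
FLOW_STEP_S = 0.025
F0_SEARCH_HZ = (520.0, 570.0)
F0_MIN_PEAK = 0.2
HARMONIC_HALF_BAND_HZ = 30.0
WELCH_NPERSEG = 512
NOISE_FLOOR_FRACTION = 0.01
DEFAULT_POWER_COEFFS = (0.3183, 7.5061)   # (gamma, delta), natural log


@dataclass
class FlowFeatureSet:
    """Per-frame audio features of one inhalation segment."""

    E: np.ndarray
    P_f0: np.ndarray
    P_f0f1: np.ndarray
    f0: float | None
    frame_times: np.ndarray

    def feature(self, name: str) -> np.ndarray:
        try:
            return {"E": self.E, "P_f0": self.P_f0, "P_f0f1": self.P_f0f1}[name]
        except KeyError:
            raise ValueError(f"unknown flow feature {name!r}") from None


@dataclass
class FlowModel:
    """Feature-to-flow mapping, linear or power-law."""

    kind: str                      # "linear" | "power"
    feature: str                   # "E" | "P_f0" | "P_f0f1"
    coef: tuple[float, float]      # (alpha, beta) or (gamma, delta)
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "power"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def predict(self, phi: np.ndarray | float) -> np.ndarray | float:
        phi = np.asarray(phi, dtype=np.float64)
        if self.kind == "linear":
            a, b = self.coef
            out = a * phi + b
        else:
            g, d = self.coef
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(phi > 0,
                               np.exp(g * np.log(np.maximum(phi, 1e-300)) + d),
                               0.0)
        out = np.maximum(out, 0.0)
        return float(out) if out.ndim == 0 else out


def default_power_model(feature: str = "P_f0f1") -> FlowModel:
    return FlowModel("power", feature, DEFAULT_POWER_COEFFS, r2=None)


@dataclass
class FlowProfile:
    """Per-frame estimated flow (L/min) with PIFR and integrated volume."""

    times: np.ndarray
    flows: np.ndarray
    pifr_lmin: float
    volume_l: float | None = None


# ---------------------------------------------------------------------------
# pre-processing and feature extraction
# ---------------------------------------------------------------------------

def preprocess_flow(sig: AudioSignal,
                    band: tuple[float, float] = FLOW_BAND_HZ,
                    frame_len_s: float = FLOW_FRAME_S,
                    step_s: float = FLOW_STEP_S,
                    ) -> tuple[AudioSignal, FrameMatrix]:
    """Anti-aliased 4x decimation, 200-5000 Hz band-pass, 50/25 ms frames.

    Returns both the decimated band-limited signal (used for fundamental
    frequency estimation) and its frame matrix.  Frames are stored
    unwindowed; the Hanning window that controls spectral leakage is applied
    inside the Welch PSD estimator, which keeps the band-power calibration
    (a tone of amplitude A integrates to A^2/2) independent of the framing.
    """
    if sig.duration < frame_len_s:
        raise EmptyInputError("signal shorter than one flow analysis frame")
    if sig.fs % DECIMATION_FACTOR == 0:
        dec = sps.decimate(sig.samples, DECIMATION_FACTOR, ftype="fir",
                           zero_phase=True)
        fs_out = sig.fs / DECIMATION_FACTOR
    else:
        fs_out = round(sig.fs / DECIMATION_FACTOR)
        dec = sps.resample_poly(sig.samples, int(fs_out), int(round(sig.fs)))
    low = AudioSignal(dec, fs_out, sig.source_id)
    filtered = bandpass(low, band[0], band[1])
    frames = frame_signal(filtered, frame_len_s, step_s,
                          remove_dc=False, window="none")
    return filtered, frames


def estimate_f0(sig: AudioSignal,
                search_hz: tuple[float, float] = F0_SEARCH_HZ,
                min_peak: float = F0_MIN_PEAK) -> float | None:
    """Fundamental of the reed tone by the autocorrelation method.

    The normalised autocorrelation peak is searched over lags corresponding
    to 520-570 Hz with parabolic interpolation for sub-bin precision.
    Returns None ("no reed sound") when no peak reaches ``min_peak``.
    """
    if sig.duration < 0.1:
        raise EmptyInputError("need at least 100 ms to estimate pitch")
    x = sig.samples - sig.samples.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(np.abs(spec) ** 2, nfft)[:n]
    if r[0] <= 0:
        return None
    r = r / r[0]
    lag_lo = int(np.ceil(sig.fs / search_hz[1]))
    lag_hi = int(np.floor(sig.fs / search_hz[0]))
    if lag_hi >= n - 1 or lag_lo < 1:
        return None
    seg = r[lag_lo:lag_hi + 1]
    k = int(np.argmax(seg))
    if seg[k] < min_peak:
        return None
    lag = lag_lo + k
    # parabolic interpolation over the three lags around the peak
    if 1 <= lag < n - 1:
        y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            lag = lag + 0.5 * (y0 - y2) / denom
    f0 = sig.fs / lag
    return float(np.clip(f0, search_hz[0], search_hz[1]))


def harmonic_powers(frames: np.ndarray, fs: float, f0: float,
                    half_band: float = HARMONIC_HALF_BAND_HZ,
                    nperseg: int = WELCH_NPERSEG,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Band power at the fundamental and fundamental+first harmonic.

    Welch PSD (Hanning segments, 50% overlap) integrated over f0 +/- 30 Hz
    and additionally 2 f0 +/- 30 Hz.  Returns per-frame (P_f0, P_f0f1).
    """
    frames = np.atleast_2d(frames)
    nper = min(nperseg, frames.shape[1])
    freqs, psd = sps.welch(frames, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, axis=-1)
    df = freqs[1] - freqs[0]
    band0 = np.abs(freqs - f0) <= half_band
    band1 = np.abs(freqs - 2 * f0) <= half_band
    p0 = psd[:, band0].sum(axis=1) * df
    p1 = psd[:, band1].sum(axis=1) * df
    return p0, p0 + p1


def extract_flow_features(sig: AudioSignal,
                          f0: float | None = None) -> FlowFeatureSet:
    """Pre-process an inhalation segment and extract (E, P_f0, P_f0f1).

    When ``f0`` is not given it is estimated from the segment itself; a
    segment with no detectable reed tone gets zero harmonic powers and
    ``f0=None`` (flows from harmonic features are then unmeasurable).
    """
    filtered, frames = preprocess_flow(sig)
    e = np.sqrt(np.mean(frames.frames ** 2, axis=1))
    if f0 is None:
        f0 = estimate_f0(filtered)
    if f0 is None:
        zeros = np.zeros(frames.n_frames)
        return FlowFeatureSet(e, zeros, zeros.copy(), None, frames.start_times)
    p0, p01 = harmonic_powers(frames.frames, frames.fs, f0)
    return FlowFeatureSet(e, p0, p01, float(f0), frames.start_times)


# ---------------------------------------------------------------------------
# model fitting and application
# ---------------------------------------------------------------------------

def fit_flow_model(phi: np.ndarray, flows: np.ndarray,
                   kind: str = "power", feature: str = "P_f0f1") -> FlowModel:
    """Least-squares fit of a linear or power-law (log-log, natural log)
    feature-to-flow model; R^2 is reported in the fitting space."""
    phi = np.asarray(phi, dtype=np.float64)
    flows = np.asarray(flows, dtype=np.float64)
    if phi.size != flows.size:
        raise ValueError("phi and flow arrays must have equal length")
    if phi.size < 3:
        raise ValueError("need at least 3 points to fit a flow model")
    if kind == "power":
        if np.any(phi <= 0) or np.any(flows <= 0):
            raise ValueError("power-law fit requires strictly positive data")
        x, y = np.log(phi), np.log(flows)
    elif kind == "linear":
        x, y = phi, flows
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return FlowModel(kind, feature, (float(slope), float(intercept)),
                     r2=float(r2))


def estimate_pifr(features: FlowFeatureSet,
                  model: FlowModel | None = None) -> float | None:
    """PIFR (L/min) = model output at the frame of maximum P_f0.

    Returns None when the segment contains no reed sound.
    """
    model = model or default_power_model()
    if features.f0 is None or features.P_f0.size == 0 \
            or not np.any(features.P_f0 > 0):
        return None
    idx = int(np.argmax(features.P_f0))
    phi = features.feature(model.feature)[idx]
    return float(model.predict(phi))


def estimate_flow_profile(features: FlowFeatureSet,
                          model: FlowModel | None = None) -> FlowProfile:
    """Apply the flow model frame by frame.

    Frames whose P_f0f1 falls below 1% of the segment maximum are set to
    0 L/min -- a noise floor that keeps the log-domain model from inventing
    flow out of silence.
    """
    model = model or default_power_model()
    phi = features.feature(model.feature)
    flows = np.asarray(model.predict(phi), dtype=np.float64)
    ref = features.P_f0f1
    if ref.size and ref.max() > 0:
        flows = np.where(ref < NOISE_FLOOR_FRACTION * ref.max(), 0.0, flows)
    else:
        flows = np.zeros_like(flows)
    pifr = estimate_pifr(features, model)
    if pifr is None:
        pifr = 0.0
    return FlowProfile(features.frame_times, flows, pifr)


def estimate_volume(profile: FlowProfile) -> float:
    """Inhaled volume (L): trapezoidal integral of flow/60 over time."""
    if profile.times.size < 2:
        raise ValueError("need at least two frames to integrate volume")
    return float(np.trapezoid(profile.flows / 60.0, profile.times))


def flow_accuracy(estimate: float, reference: float) -> float:
    """Percent accuracy: 100 * (1 - |est - ref| / ref), floored at 0."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return max(0.0, 100.0 * (1.0 - abs(estimate - reference) / reference))


# ---------------------------------------------------------------------------
# robustness analysis
# ---------------------------------------------------------------------------

def add_noise_snr(sig: AudioSignal, snr_db: float,
                  seed: int | np.random.Generator) -> AudioSignal:
    """Add white Gaussian noise at a prescribed SNR over the signal support."""
    p_sig = float(np.mean(sig.samples ** 2))
    if p_sig <= 0:
        raise ValueError("cannot set an SNR against a silent signal")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    noisy = sig.samples + rng.normal(0.0, sigma, sig.samples.size)
    return AudioSignal(noisy, sig.fs, sig.source_id)


def snr_sweep(recordings: list[tuple[AudioSignal, float, float]],
              models: dict[str, FlowModel],
              snr_grid_db: list[float] | np.ndarray,
              seed: int = 0):
    """PIFR/volume accuracy of each feature's model across SNR levels.

    ``recordings`` holds (clean inhalation audio, reference PIFR L/min,
    reference volume L).  Returns a DataFrame with columns
    snr_db, feature, metric, mean, se.
    """
    import pandas as pd

    rows = []
    snr_grid_db = list(snr_grid_db)
    rng = np.random.default_rng(seed)
    for snr in snr_grid_db:
        acc: dict[tuple[str, str], list[float]] = {
            (name, met): [] for name in models for met in ("pifr", "volume")}
        for sig, ref_pifr, ref_vol in recordings:
            noisy = add_noise_snr(sig, snr, rng)
            feats = extract_flow_features(noisy)
            for name, model in models.items():
                pifr = estimate_pifr(feats, model)
                profile = estimate_flow_profile(feats, model)
                vol = estimate_volume(profile) if profile.times.size >= 2 else 0.0
                acc[(name, "pifr")].append(
                    flow_accuracy(pifr if pifr is not None else 0.0, ref_pifr))
                acc[(name, "volume")].append(flow_accuracy(vol, ref_vol))
        for (name, met), vals in acc.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            rows.append({"snr_db": snr, "feature": name, "metric": met,
                         "mean": vals.mean() if vals.size else np.nan,
                         "se": se})
    return pd.DataFrame(rows, columns=["snr_db", "feature", "metric",
                                       "mean", "se"])


def bland_altman_stats(estimates, references):
    """Mean bias and 95% limits of agreement (bias +/- 1.96 SD of diffs)."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.size != ref.size:
        raise ValueError("paired samples must have equal length")
    if est.size < 2:
        raise ValueError("need at least two pairs")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)
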