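"""Per-frame audio features for inhaler sound-event classification.

The classifier consumes a 30-dimensional feature vector per 40 ms frame:
twelve mel-frequency cepstral coefficients, ten linear-predictive-coding
coefficients, RMS energy, zero-crossing rate, continuous-wavelet-transform
high-frequency power (above 15 kHz), a harmonic feature tuned to the
Flo-Tone reed pitch (autocorrelation peak searched in 500-600 Hz), spectral
entropy, sample skewness and kurtosis, and the spectral centroid.

The registry is configurable so a different feature list can be substituted
without touching the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as spfft

from .signal_io import FrameMatrix

LOG_FLOOR = 1e-10
HF_CUTOFF_HZ = 15000.0
HARMONIC_LO_HZ = 500.0
HARMONIC_HI_HZ = 600.0

_MFCC_NAMES = [f"mfcc{i:02d}" for i in range(1, 13)]
_LPC_NAMES = [f"lpc{i:02d}" for i in range(1, 11)]
DEFAULT_FEATURE_NAMES = _MFCC_NAMES + _LPC_NAMES + [
    "rms_energy", "zcr", "hf_power", "harmonic",
    "spectral_entropy", "skewness", "kurtosis", "spectral_centroid",
]


@dataclass
class FeatureRegistry:
    """Ordered list of feature names to extract."""

    names: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURE_NAMES))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        unknown = set(self.names) - set(DEFAULT_FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class FeatureMatrix:
    """n_frames x n_features matrix with named columns."""

    values: np.ndarray
    names: list[str]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.frame_times)

    def to_csv(self, path) -> None:
        """Persist as CSV: frame_time_s column plus one column per feature."""
        import pandas as pd
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "frame_time_s", self.frame_times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd
        df = pd.read_csv(path)
        times = df.pop("frame_time_s").to_numpy()
        return cls(df.to_numpy(dtype=float), list(df.columns), times)


# ---------------------------------------------------------------------------
# individual extractors (2-D frame arrays in, per-frame values out)
# ---------------------------------------------------------------------------

def _power_spectrum(frames: np.ndarray) -> np.ndarray:
    spec = spfft.rfft(frames, axis=-1)
    return np.abs(spec) ** 2


def _mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_bins: int, fs: float) -> np.ndarray:
    """Triangular mel filters spanning 0 to fs/2 over rfft bins."""
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_filters + 2))
    bins = np.linspace(0.0, fs / 2.0, n_bins)
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(frames: np.ndarray, fs: float, n_filters: int = 26,
         n_coeffs: int = 12) -> np.ndarray:
    """MFCC 1..12 (the gain-carrying 0th coefficient is excluded).

    26 triangular mel filters over 0..fs/2, log floor, orthonormal DCT-II.
    """
    frames = np.atleast_2d(frames)
    if frames.shape[1] < 64:
        raise ValueError("mfcc requires frames of at least 64 samples")
    ps = _power_spectrum(frames)
    fb = _mel_filterbank(n_filters, ps.shape[1], fs)
    energies = ps @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = spfft.dct(log_e, type=2, norm="ortho", axis=-1)
    return ceps[:, 1:n_coeffs + 1]


def _autocorr(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation r[0..max_lag] via FFT, per frame."""
    n = frames.shape[1]
    nfft = spfft.next_fast_len(2 * n)
    spec = spfft.rfft(frames, n=nfft, axis=-1)
    r = spfft.irfft(np.abs(spec) ** 2, n=nfft, axis=-1)[:, :max_lag + 1]
    return r / n


def lpc_coeffs(frames: np.ndarray, order: int = 10) -> np.ndarray:
    """Autocorrelation-method LPC a1..a10 via Levinson-Durbin.

    Convention: the prediction-error filter is A(z) = 1 + sum a_i z^-i, so a
    frame from the AR(1) process x[n] = 0.9 x[n-1] + e[n] yields a1 ~ -0.9.
    Degenerate (zero/constant) frames fall back to the all-zero vector.
    """
    frames = np.atleast_2d(frames)
    r = _autocorr(frames, order)
    n_frames = frames.shape[0]
    a = np.zeros((n_frames, order))
    degenerate = r[:, 0] <= 1e-300
    if np.any(degenerate):
        warnings.warn("zero/constant frame(s) in LPC: returning zero vector")
    ok = ~degenerate
    if not np.any(ok):
        return a
    rr = r[ok]
    err = rr[:, 0].copy()
    aa = np.zeros((rr.shape[0], order))
    for i in range(1, order + 1):
        acc = rr[:, i].copy()
        if i > 1:
            acc += np.einsum("fj,fj->f", aa[:, :i - 1], rr[:, i - 1:0:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(err > 1e-300, -acc / np.maximum(err, 1e-300), 0.0)
        prev = aa[:, :i - 1].copy()
        aa[:, :i - 1] = prev + k[:, None] * prev[:, ::-1]
        aa[:, i - 1] = k
        err *= np.maximum(1.0 - k ** 2, 1e-12)
    a[ok] = aa
    return a


def zcr(frames: np.ndarray) -> np.ndarray:
    """Zero-crossing rate normalised to [0, 1] (fraction of sign changes)."""
    frames = np.atleast_2d(frames)
    signs = np.signbit(frames)
    return np.mean(signs[:, 1:] != signs[:, :-1], axis=1).astype(np.float64)


def rms_energy(frames: np.ndarray) -> np.ndarray:
    frames = np.atleast_2d(frames)
    return np.sqrt(np.mean(frames ** 2, axis=1))


def hf_power_cwt(frames: np.ndarray, fs: float,
                 cutoff: float = HF_CUTOFF_HZ,
                 voices_per_octave: int = 12) -> np.ndarray:
    """Mean squared CWT magnitude over scales with centre frequency >= cutoff.

    Analytic Morlet ('cmor1.5-1.0'); 0 with a warning when the band is not
    representable (fs/2 < cutoff).
    """
    frames = np.atleast_2d(frames)
    if fs / 2.0 < cutoff:
        warnings.warn(
            f"high-frequency band >= {cutoff} Hz not representable at fs={fs}")
        return np.zeros(frames.shape[0])
    wavelet = "cmor1.5-1.0"
    n_oct = np.log2((fs / 2.0) / cutoff)
    n_scales = max(2, int(np.ceil(n_oct * voices_per_octave)) + 1)
    freqs = np.geomspace(cutoff, fs / 2.0, n_scales)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    out = np.empty(frames.shape[0])
    chunk = max(1, int(2e6 // frames.shape[1]))
    for i in range(0, frames.shape[0], chunk):
        coef, _ = pywt.cwt(frames[i:i + chunk], scales, wavelet,
                           axis=-1, method="fft")
        out[i:i + chunk] = np.mean(np.abs(coef) ** 2, axis=(0, 2))
    return out


def harmonic_feature(frames: np.ndarray, fs: float,
                     lo_hz: float = HARMONIC_LO_HZ,
                     hi_hz: float = HARMONIC_HI_HZ) -> np.ndarray:
    """Peak normalised autocorrelation searched over 500-600 Hz lags.

    Amplitude-invariant in [0, 1]; near 1 for the harmonic Flo-Tone reed
    sound, small for broadband noise.
    """
    frames = np.atleast_2d(frames)
    lag_lo = int(np.ceil(fs / hi_hz))
    lag_hi = int(np.floor(fs / lo_hz))
    if frames.shape[1] <= lag_hi:
        raise ValueError("frame too short for the harmonic lag range")
    r = _autocorr(frames, lag_hi)
    r0 = r[:, 0]
    peak = r[:, lag_lo:lag_hi + 1].max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(r0 > 0, peak / np.maximum(r0, 1e-300), 0.0)
    return np.clip(val, 0.0, 1.0)


def spectral_entropy(frames: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of the frame PSD normalised to a pmf."""
    ps = _power_spectrum(np.atleast_2d(frames))
    total = ps.sum(axis=1, keepdims=True)
    zero = total[:, 0] <= 0
    p = ps / np.where(total > 0, total, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0),
                    axis=1)
    h[zero] = 0.0
    return h


def skewness(frames: np.ndarray) -> np.ndarray:
    frames = np.atleast_2d(frames)
    m = frames.mean(axis=1, keepdims=True)
    d = frames - m
    s2 = np.mean(d ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s2 > 0, np.mean(d ** 3, axis=1) / np.maximum(s2, 1e-300) ** 1.5, 0.0)
    return out


def kurtosis(frames: np.ndarray) -> np.ndarray:
    """Non-excess (Pearson) kurtosis; 3 for a Gaussian, 0 for a zero frame."""
    frames = np.atleast_2d(frames)
    m = frames.mean(axis=1, keepdims=True)
    d = frames - m
    s2 = np.mean(d ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s2 > 0, np.mean(d ** 4, axis=1) / np.maximum(s2, 1e-300) ** 2, 0.0)
    return out


def spectral_centroid(frames: np.ndarray, fs: float) -> np.ndarray:
    ps = _power_spectrum(np.atleast_2d(frames))
    freqs = np.linspace(0.0, fs / 2.0, ps.shape[1])
    total = ps.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cen = np.where(total > 0, ps @ freqs / np.maximum(total, 1e-300), 0.0)
    return cen


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_features(frames: FrameMatrix,
                     registry: FeatureRegistry | None = None) -> FeatureMatrix:
    """Extract the registry's features from every frame (registry order)."""
    registry = registry or FeatureRegistry()
    x = frames.frames
    fs = frames.fs
    columns: dict[str, np.ndarray] = {}

    wanted = set(registry.names)
    if wanted & set(_MFCC_NAMES):
        cc = mfcc(x, fs)
        for i, name in enumerate(_MFCC_NAMES):
            columns[name] = cc[:, i]
    if wanted & set(_LPC_NAMES):
        aa = lpc_coeffs(x)
        for i, name in enumerate(_LPC_NAMES):
            columns[name] = aa[:, i]
    if "rms_energy" in wanted:
        columns["rms_energy"] = rms_energy(x)
    if "zcr" in wanted:
        columns["zcr"] = zcr(x)
    if "hf_power" in wanted:
        columns["hf_power"] = hf_power_cwt(x, fs)
    if "harmonic" in wanted:
        columns["harmonic"] = harmonic_feature(x, fs)
    if "spectral_entropy" in wanted:
        columns["spectral_entropy"] = spectral_entropy(x)
    if "skewness" in wanted:
        columns["skewness"] = skewness(x)
    if "kurtosis" in wanted:
        columns["kurtosis"] = kurtosis(x)
    if "spectral_centroid" in wanted:
        columns["spectral_centroid"] = spectral_centroid(x, fs)

    values = np.column_stack([columns[n] for n in registry.names])
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    # frame_times are frame *start* times so that event boundaries formed
    # downstream run from first-frame start to last-frame end
    return FeatureMatrix(values, list(registry.names), frames.start_times)
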