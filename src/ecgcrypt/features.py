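"""Multi-domain ECG feature extraction and fusion.

Time-domain moments, DFT-based frequency features, STFT time–frequency
features, HRV metrics from detected R-peaks, the zero-crossing rate, and a
per-mode summary of the VMD/EMD decomposition are concatenated into one
fused vector with a fixed, documented layout:

    time (5) | freq (5) | timefreq (2) | hrv (5) | zcr (1) | mode_summary (2K+2)

Every named feature is recoverable bit-exactly from its slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import InputError, TooShortError
from .signal import ECGSignal

NN50_THRESHOLD_S = 0.050  # standard NN50 successive-difference threshold


# ---------------------------------------------------------------------------
# R peaks and HRV
# ---------------------------------------------------------------------------


def detect_r_peaks(signal: ECGSignal, fs: float | None = None) -> np.ndarray:
    """QRS detection by derivative–square–integrate with adaptive threshold.

    The classic energy-based recipe: band-pass to the QRS band (5–15 Hz),
    differentiate, square, integrate over a 150 ms moving window, pick
    integrator peaks above an adaptive threshold with a 200 ms refractory
    period, then snap each detection to the local signal maximum.
    Returns strictly increasing sample indices.
    """
    fs = fs or signal.fs
    x = np.asarray(signal.samples, dtype=float)
    if x.size < 2 * fs:
        raise TooShortError("need at least 2 s of signal for QRS detection")
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)

    sos = scipy.signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = scipy.signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    threshold = 0.30 * float(np.mean(np.sort(mwi)[-max(8, mwi.size // 100) :]))
    candidates, _ = scipy.signal.find_peaks(mwi, height=threshold, distance=refractory)
    if candidates.size == 0:
        return np.asarray([], dtype=int)

    # snap to the R wave: local maximum of the band-passed signal near the
    # integrator peak (the MWI peak lags the QRS by roughly the window)
    half = int(round(0.10 * fs))
    peaks = []
    for c in candidates:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(bp[lo:hi])))
    peaks = np.unique(np.asarray(peaks, dtype=int))
    # enforce refractory after snapping
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if mwi[p] > mwi[kept[-1]]:
                kept[-1] = int(p)
            continue
        kept.append(int(p))
    return np.asarray(kept, dtype=int)


@dataclass
class RRSeries:
    """Successive R–R intervals in seconds plus the source peak indices."""

    intervals: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise InputError("RR intervals must be positive")

    @property
    def count(self) -> int:
        return self.intervals.size


def rr_intervals(peaks: np.ndarray, fs: float) -> RRSeries:
    """RR series from strictly increasing peak sample indices."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise InputError("need at least 2 peaks to form RR intervals")
    return RRSeries(np.diff(peaks) / fs, peaks)


def ibi_histogram(
    rr: RRSeries, bin_width_s: float = 0.025
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-beat-interval histogram with fixed bin width over [min, max]."""
    if bin_width_s <= 0:
        raise InputError("bin width must be positive")
    lo, hi = rr.intervals.min(), rr.intervals.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width_s)))
    edges = lo + bin_width_s * np.arange(nbins + 1)
    counts, _ = np.histogram(rr.intervals, bins=edges)
    return edges, counts


def hrv_metrics(rr: RRSeries) -> dict[str, float]:
    """SDNN, RMSSD, NN50, pNN50 and mean heart rate.

    sdnn  = sqrt(Σ(RR_i − meanRR)² / (N−1))
    rmssd = sqrt(Σ(RR_{i+1} − RR_i)² / (N−1))
    nn50  = #{ |RR_{i+1} − RR_i| > 50 ms };  pnn50 = 100·nn50/(N−1)
    """
    if rr.count < 2:
        raise InputError("need at least 2 RR intervals for HRV metrics")
    x = rr.intervals
    N = x.size
    mean_rr = float(x.mean())
    sdnn = float(np.sqrt(np.sum((x - mean_rr) ** 2) / (N - 1)))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.sum(d**2) / (N - 1)))
    nn50 = int(np.count_nonzero(np.abs(d) > NN50_THRESHOLD_S))
    return {
        "sdnn": sdnn,
        "rmssd": rmssd,
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / (N - 1),
        "mean_hr": 60.0 / mean_rr,
    }


# ---------------------------------------------------------------------------
# time-domain moments
# ---------------------------------------------------------------------------


def time_domain_features(sequence: np.ndarray, population: bool = False) -> dict:
    """Mean, sample std, RMS, Fisher–Pearson skewness and excess kurtosis.

    ``population=True`` switches std to the N-denominator variant. Constant
    input reports skewness/kurtosis of 0 with ``degenerate=True``.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 samples")
    mean = float(x.mean())
    std = float(x.std(ddof=0 if population else 1))
    rms = float(np.sqrt(np.mean(x**2)))
    m2 = float(np.mean((x - mean) ** 2))
    if m2 == 0:
        return {
            "mean": mean, "std": 0.0, "rms": rms,
            "skewness": 0.0, "kurtosis": 0.0, "degenerate": True,
        }
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    return {
        "mean": mean,
        "std": std,
        "rms": rms,
        "skewness": m3 / m2**1.5,
        "kurtosis": m4 / m2**2 - 3.0,  # excess convention
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """DFT coefficients X[k] on a frequency grid (one- or two-sided)."""

    coefficients: np.ndarray
    frequencies: np.ndarray
    N: int
    fs: float
    side: str = "one-sided"

    def __post_init__(self) -> None:
        if self.frequencies.size != self.coefficients.size:
            raise InputError("frequency grid must match coefficient count")


def dft(sequence: np.ndarray, fs: float = 1.0, side: str = "one-sided") -> Spectrum:
    """Plain DFT, X[k] = Σ x[n]·e^{−j2πkn/N} (no forward 1/N)."""
    x = np.asarray(sequence)
    if x.size < 1:
        raise InputError("need at least 1 sample")
    X = np.fft.fft(x)
    if side == "one-sided":
        n_keep = x.size // 2 + 1
        return Spectrum(X[:n_keep], np.fft.rfftfreq(x.size, d=1.0 / fs), x.size, fs, side)
    if side == "two-sided":
        freqs = np.fft.fftshift(np.fft.fftfreq(x.size, d=1.0 / fs))
        return Spectrum(np.fft.fftshift(X), freqs, x.size, fs, side)
    raise InputError(f"unknown side {side!r}")


def idft(spectrum: Spectrum) -> np.ndarray:
    """Inverse DFT, x[n] = (1/N) Σ X[k]·e^{j2πkn/N}; real part returned."""
    if spectrum.side == "two-sided":
        X = np.fft.ifftshift(spectrum.coefficients)
    else:
        X = np.zeros(spectrum.N, dtype=complex)
        X[: spectrum.coefficients.size] = spectrum.coefficients
        # hermitian completion of the discarded negative frequencies
        tail = np.conj(spectrum.coefficients[1 : spectrum.N - spectrum.coefficients.size + 1])
        X[spectrum.coefficients.size :] = tail[::-1]
    return np.real(np.fft.ifft(X))


def frequency_features(spectrum: Spectrum, energy_fraction: float = 0.85) -> dict:
    """Dominant frequency, spectral centroid/spread/entropy/rolloff.

    All statistics use the power distribution P = |X|² normalized over the
    spectrum's own grid; entropy is in bits. Rolloff is the smallest grid
    frequency whose cumulative power reaches ``energy_fraction`` of the
    total.
    """
    P = np.abs(spectrum.coefficients) ** 2
    total = P.sum()
    if total == 0:
        raise InputError("all-zero spectrum has no frequency features")
    f = spectrum.frequencies
    p = P / total
    centroid = float(f @ p)
    spread = float(np.sqrt(((f - centroid) ** 2) @ p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    rolloff = float(f[np.searchsorted(np.cumsum(P), energy_fraction * total)])
    return {
        "dominant_frequency": float(f[np.argmax(P)]),
        "spectral_centroid": centroid,
        "spectral_spread": spread,
        "spectral_entropy": entropy,
        "spectral_rolloff": rolloff,
    }


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------


@dataclass
class STFTGrid:
    """Short-time Fourier magnitudes over (frame time, frequency)."""

    magnitudes: np.ndarray  # (frames, bins)
    times: np.ndarray  # frame centers, s
    frequencies: np.ndarray  # Hz
    window: int
    hop: int
    fs: float


def stft(
    sequence: np.ndarray,
    window: int | None = None,
    hop: int | None = None,
    fs: float = 1.0,
) -> STFTGrid:
    """Hann-windowed frame-by-frame DFT magnitudes.

    Defaults: 1 s window with 50% hop. Frame count is exactly
    floor((N − window)/hop) + 1; frame times are window centers.
    """
    x = np.asarray(sequence, dtype=float)
    window = window or int(round(fs))
    hop = hop or window // 2
    if hop <= 0:
        raise InputError("hop must be positive")
    if window > x.size:
        raise InputError(f"window {window} exceeds signal length {x.size}")
    n_frames = (x.size - window) // hop + 1
    w = np.hanning(window)
    starts = hop * np.arange(n_frames)
    frames = np.stack([x[s : s + window] * w for s in starts])
    mags = np.abs(np.fft.rfft(frames, axis=1))
    return STFTGrid(
        magnitudes=mags,
        times=(starts + window / 2) / fs,
        frequencies=np.fft.rfftfreq(window, d=1.0 / fs),
        window=window,
        hop=hop,
        fs=fs,
    )


def timefreq_features(grid: STFTGrid) -> dict[str, float]:
    """Frame-averaged spectral centroid and entropy of the spectrogram."""
    if grid.magnitudes.shape[0] < 1:
        raise InputError("need at least one STFT frame")
    P = grid.magnitudes**2
    totals = P.sum(axis=1)
    if np.all(totals == 0):
        raise InputError("all-zero spectrogram")
    centroids, entropies = [], []
    for row, tot in zip(P, totals):
        if tot == 0:
            continue
        p = row / tot
        centroids.append(float(grid.frequencies @ p))
        nz = p[p > 0]
        entropies.append(float(-np.sum(nz * np.log2(nz))))
    return {
        "mean_frequency": float(np.mean(centroids)),
        "mean_spectral_entropy": float(np.mean(entropies)),
    }


# ---------------------------------------------------------------------------
# ZCR and comparison
# ---------------------------------------------------------------------------


def zcr(sequence: np.ndarray, fs: float | None = None) -> dict[str, float]:
    """Zero-crossing rate: transitions between opposite nonzero signs.

    Zero samples bridging opposite signs count as a single crossing. The
    per-sample rate divides by N−1; a per-second rate is included when the
    sampling rate is given.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 samples")
    s = np.sign(x)
    s = s[s != 0]
    count = int(np.count_nonzero(np.diff(s) != 0)) if s.size > 1 else 0
    rate = count / (x.size - 1)
    out = {"count": float(count), "rate_per_sample": rate}
    if fs is not None:
        out["rate_per_second"] = rate * fs
    return out


def compare_signals(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Mean-squared error and its square root between equal-length signals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise InputError(f"length mismatch: {a.size} vs {b.size}")
    mse = float(np.mean((a - b) ** 2))
    return {"mse": mse, "rmse": float(np.sqrt(mse))}


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

TIME_KEYS = ("mean", "std", "rms", "skewness", "kurtosis")
FREQ_KEYS = (
    "dominant_frequency",
    "spectral_centroid",
    "spectral_spread",
    "spectral_entropy",
    "spectral_rolloff",
)
TIMEFREQ_KEYS = ("mean_frequency", "mean_spectral_entropy")
HRV_KEYS = ("sdnn", "rmssd", "nn50", "pnn50", "mean_hr")
ZCR_KEYS = ("rate_per_sample",)


@dataclass
class FeatureBundle:
    """Named per-domain features plus the fused vector.

    ``mode_summary`` holds (energy, center frequency) per VMD mode followed
    by (energy, dominant frequency) of the first IMF — 2K+2 values.
    """

    time: dict[str, float]
    freq: dict[str, float]
    timefreq: dict[str, float]
    hrv: dict[str, float]
    zcr: dict[str, float]
    mode_summary: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mode_summary_names: list[str] = field(default_factory=list)

    @property
    def fused(self) -> np.ndarray:
        return fuse_features(
            time=self.time,
            freq=self.freq,
            timefreq=self.timefreq,
            hrv=self.hrv,
            zcr=self.zcr,
            mode_summary=self.mode_summary,
        )

    def layout(self) -> list[str]:
        """Slot names of the fused vector, in order."""
        names = [f"time.{k}" for k in TIME_KEYS]
        names += [f"freq.{k}" for k in FREQ_KEYS]
        names += [f"timefreq.{k}" for k in TIMEFREQ_KEYS]
        names += [f"hrv.{k}" for k in HRV_KEYS]
        names += [f"zcr.{k}" for k in ZCR_KEYS]
        names += self.mode_summary_names or [
            f"mode_summary.{i}" for i in range(self.mode_summary.size)
        ]
        return names

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "freq": self.freq,
            "timefreq": self.timefreq,
            "hrv": self.hrv,
            "zcr": self.zcr,
            "mode_summary": dict(zip(self.layout()[-self.mode_summary.size :] if self.mode_summary.size else [], self.mode_summary.tolist())),
            "fused": self.fused.tolist(),
        }


def fuse_features(
    time: dict | None = None,
    freq: dict | None = None,
    timefreq: dict | None = None,
    hrv: dict | None = None,
    zcr: dict | None = None,
    mode_summary: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate the per-domain features into the canonical fused vector.

    The ordering is fixed (time | freq | timefreq | hrv | zcr |
    mode_summary) regardless of argument order; values are copied, never
    transformed. A missing domain raises an error naming it.
    """
    parts = []
    for name, record, keys in (
        ("time", time, TIME_KEYS),
        ("freq", freq, FREQ_KEYS),
        ("timefreq", timefreq, TIMEFREQ_KEYS),
        ("hrv", hrv, HRV_KEYS),
        ("zcr", zcr, ZCR_KEYS),
    ):
        if record is None:
            raise InputError(f"missing feature domain: {name}")
        try:
            parts.append(np.asarray([record[k] for k in keys], dtype=float))
        except KeyError as exc:
            raise InputError(f"domain {name!r} missing key {exc}") from None
    if mode_summary is None:
        raise InputError("missing feature domain: mode_summary")
    parts.append(np.asarray(mode_summary, dtype=float))
    fused = np.concatenate(parts)
    if not np.all(np.isfinite(fused)):
        raise InputError("fused vector contains non-finite entries")
    return fused
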