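"""Per-call acoustic features: frame-averaged MFCCs, duration, spectral centroid.

The feature set is the one used throughout the analysis: each call is
summarised by its duration (s), its spectral centroid (Hz, the
magnitude-weighted mean frequency of the whole-call spectrum) and ten
mel-frequency cepstral coefficients.  MFCCs are computed the classical way
— overlapping Hamming-windowed frames, magnitude spectrum, mel-scaled
triangular filterbank, log energies, orthonormal DCT-II — and each
coefficient is averaged over all frames of the call, so that one call
yields one 10-vector regardless of its length.  Window length is 30 ms for
meows and 300 ms for purrs (the two call types differ by nearly two orders
of magnitude in duration and fundamental frequency).

The 0th cepstral coefficient (a loudness proxy) is excluded by default;
"10 MFCCs" means coefficients 1-10.  With the default relative log floor
the retained coefficients are invariant to any positive gain applied to
the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal as sps
from scipy.io import wavfile

from .synth import CallRecording

__all__ = [
    "MfccConfig",
    "CallFeatures",
    "SpectrogramParams",
    "meow_config",
    "purr_config",
    "load_wav",
    "write_wav",
    "to_mono",
    "mel_scale",
    "mel_to_hz",
    "mel_filterbank",
    "mfcc_per_call",
    "duration",
    "spectral_centroid",
    "spectrogram",
    "extract_features",
    "extract_feature_table",
    "write_feature_csv",
    "read_feature_csv",
    "FEATURE_COLUMNS",
    "MFCC_COLUMNS",
]

MFCC_COLUMNS = [f"mfcc{i}" for i in range(1, 11)]
FEATURE_COLUMNS = ["duration_s", "spectral_centroid_hz"] + MFCC_COLUMNS
_CSV_HEADER = ["call_id", "individual_id", "species_id", "call_type"] + FEATURE_COLUMNS


class AudioFormatError(ValueError):
    """Unreadable or unsupported audio input."""


@dataclass(frozen=True)
class MfccConfig:
    """Parameters of the MFCC chain.

    window_length: analysis frame length in seconds (0.030 meow / 0.300 purr).
    hop_fraction: hop as a fraction of the window (0.5 = 50% overlap).
    n_filters: triangular mel filters between fmin and fmax.
    n_coefficients: cepstral coefficients kept (1..n when include_c0=False).
    fmax: upper filterbank edge; None means Nyquist.
    log_floor: added to filterbank energies, relative to the call's maximum
        energy, before the log — keeps silent frames finite and preserves
        gain invariance.
    """

    window_length: float
    hop_fraction: float = 0.5
    n_filters: int = 26
    n_coefficients: int = 10
    fmin: float = 0.0
    fmax: float | None = None
    log_floor: float = 1e-12
    include_c0: bool = False

    def validate(self, sample_rate: float | None = None) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if not (0 < self.hop_fraction <= 1):
            raise ValueError("hop_fraction must be in (0, 1]")
        if self.n_coefficients > self.n_filters:
            raise ValueError("n_coefficients must be <= n_filters")
        fmax = self.fmax
        if sample_rate is not None:
            nyq = sample_rate / 2
            fmax = nyq if fmax is None else fmax
            if not (self.fmin < fmax <= nyq + 1e-9):
                raise ValueError("require fmin < fmax <= Nyquist")
        elif fmax is not None and self.fmin >= fmax:
            raise ValueError("require fmin < fmax")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be a small positive real")


def meow_config(**overrides) -> MfccConfig:
    """Default MFCC configuration for meows (30 ms window)."""
    return MfccConfig(window_length=0.030, **overrides)


def purr_config(**overrides) -> MfccConfig:
    """Default MFCC configuration for purrs (300 ms window)."""
    return MfccConfig(window_length=0.300, **overrides)


@dataclass
class CallFeatures:
    """One row of the per-call feature table."""

    call_id: str
    individual_id: str
    species_id: str
    call_type: str
    duration: float
    spectral_centroid: float
    mfcc: np.ndarray  # coefficients 1..10

    def validate(self, sample_rate: float | None = None) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.spectral_centroid <= 0:
            raise ValueError("spectral_centroid must be > 0")
        if sample_rate is not None and self.spectral_centroid >= sample_rate / 2:
            raise ValueError("spectral_centroid must lie below Nyquist")
        if len(self.mfcc) != 10 or not np.all(np.isfinite(self.mfcc)):
            raise ValueError("mfcc must hold exactly 10 finite values")


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT display parameters (defaults match a 96 kHz QC spectrogram:
    1024-point FFT, Hamming window, 87.5% overlap -> 93.75 Hz bins,
    1.33 ms hop)."""

    n_fft: int = 1024
    window: str = "hamming"
    overlap: float = 0.875
    bit_depth: int = 16

    def validate(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.n_fft < 2 or (self.n_fft & (self.n_fft - 1)) != 0:
            raise ValueError("n_fft must be a power of two")


# ----------------------------------------------------------------- audio I/O

def load_wav(
    path: str | Path,
    individual_id: str = "",
    species_id: str = "",
    call_type: str = "",
) -> CallRecording:
    """Read a PCM WAV file, scaling samples to [-1, 1].

    Integer PCM (8/16/32-bit) is divided by its full-scale value; float
    data is passed through.  Stereo files keep shape (n, 2); use
    :func:`to_mono` before analysis.
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on junk input
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path} contains no samples")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    return CallRecording(samples, float(rate), individual_id, species_id, call_type)


def write_wav(path: str | Path, recording: CallRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(recording.samples, -1.0, 1.0)
    data = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(recording.sample_rate), data)


def to_mono(recording: CallRecording) -> CallRecording:
    """Per-sample channel mean for stereo input; identity for mono."""
    s = recording.samples
    if s.ndim == 1:
        return recording
    if s.ndim == 2 and s.shape[1] in (1, 2):
        mono = s.mean(axis=1)
        return CallRecording(
            mono,
            recording.sample_rate,
            recording.individual_id,
            recording.species_id,
            recording.call_type,
        )
    raise AudioFormatError(f"expected 1 or 2 channels, got shape {s.shape}")


# ------------------------------------------------------------------ mel/MFCC

def mel_scale(f):
    """Hz -> mel: 2595 * log10(1 + f/700); linear below ~1 kHz, log above."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    """Inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=float)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(
    config: MfccConfig, n_fft: int, sample_rate: float
) -> np.ndarray:
    """Triangular filters with centres equally spaced on the mel axis.

    Returns an (n_filters, n_fft//2 + 1) weight matrix over rFFT bins.
    Raises if the FFT resolution cannot separate adjacent filter centres.
    """
    config.validate(sample_rate)
    fmax = sample_rate / 2 if config.fmax is None else config.fmax
    mel_pts = np.linspace(mel_scale(config.fmin), mel_scale(fmax), config.n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    center_bins = np.round(hz_pts / (sample_rate / n_fft)).astype(int)
    if np.any(np.diff(center_bins[1:-1]) < 1):
        raise ValueError(
            f"{config.n_filters} filters cannot be resolved by an {n_fft}-point "
            "FFT at this sample rate (duplicate centre bins); reduce n_filters "
            "or raise n_fft"
        )
    weights = np.zeros((config.n_filters, bin_freqs.size))
    for m in range(config.n_filters):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        weights[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return weights


def _frame(samples: np.ndarray, win: int, hop: int) -> np.ndarray:
    n_frames = (samples.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return samples[idx]


def n_frames(n_samples: int, sample_rate: float, config: MfccConfig) -> int:
    """Number of full analysis frames (last partial frame dropped)."""
    win = int(round(config.window_length * sample_rate))
    hop = max(1, int(round(win * config.hop_fraction)))
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def mfcc_per_call(recording: CallRecording, config: MfccConfig) -> np.ndarray:
    """Frame-averaged MFCC vector (coefficients 1..n, or 0..n-1 with c0).

    Chain per frame: Hamming window -> magnitude rFFT -> triangular mel
    filterbank -> log(energy + floor) -> orthonormal DCT-II.  Coefficients
    are then averaged over all full frames of the call.
    """
    config.validate(recording.sample_rate)
    samples = np.asarray(recording.samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("mfcc_per_call expects mono audio; apply to_mono first")
    sr = recording.sample_rate
    win = int(round(config.window_length * sr))
    if samples.size < win:
        raise ValueError(
            f"recording of {samples.size} samples is shorter than one "
            f"{config.window_length * 1e3:.0f} ms window ({win} samples); "
            "use the shorter-window (meow) configuration for short calls"
        )
    hop = max(1, int(round(win * config.hop_fraction)))
    n_fft = 1 << (win - 1).bit_length()

    frames = _frame(samples, win, hop) * np.hamming(win)
    mags = np.abs(sfft.rfft(frames, n=n_fft, axis=1))
    fb = mel_filterbank(config, n_fft, sr)
    energies = mags @ fb.T
    emax = energies.max()
    floor = config.log_floor * (emax if emax > 0 else 1.0)
    logE = np.log(energies + floor)
    cepstra = sfft.dct(logE, type=2, norm="ortho", axis=1)
    if config.include_c0:
        coeffs = cepstra[:, : config.n_coefficients]
    else:
        coeffs = cepstra[:, 1 : config.n_coefficients + 1]
    return coeffs.mean(axis=0)


def duration(recording: CallRecording) -> float:
    """Call duration in seconds: n_samples / sample_rate."""
    n = np.asarray(recording.samples).shape[0]
    if n < 1:
        raise ValueError("empty recording")
    return n / recording.sample_rate


def spectral_centroid(recording: CallRecording) -> float:
    """Magnitude-weighted mean frequency of the whole-call spectrum (Hz)."""
    samples = np.asarray(recording.samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("spectral_centroid expects mono audio")
    if samples.size == 0 or not np.any(samples):
        raise ValueError("spectral centroid undefined for an all-zero signal")
    mags = np.abs(sfft.rfft(samples))
    freqs = sfft.rfftfreq(samples.size, d=1.0 / recording.sample_rate)
    mags, freqs = mags[1:], freqs[1:]  # positive frequencies only
    return float(np.sum(freqs * mags) / np.sum(mags))


def spectrogram(
    recording: CallRecording, params: SpectrogramParams = SpectrogramParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """STFT magnitude matrix for QC plots.

    Returns (freqs, times, magnitude, info) where info reports the
    frequency resolution ``sample_rate / n_fft`` and the hop time
    ``n_fft * (1 - overlap) / sample_rate``.
    """
    params.validate()
    samples = np.asarray(recording.samples, dtype=float)
    noverlap = int(round(params.overlap * params.n_fft))
    freqs, times, sxx = sps.spectrogram(
        samples,
        fs=recording.sample_rate,
        window=params.window,
        nperseg=params.n_fft,
        noverlap=noverlap,
        mode="magnitude",
        detrend=False,
    )
    info = {
        "bin_width_hz": recording.sample_rate / params.n_fft,
        "hop_samples": params.n_fft - noverlap,
        "hop_time_s": (params.n_fft - noverlap) / recording.sample_rate,
    }
    return freqs, times, sxx, info


# ----------------------------------------------------------- feature tables

def extract_features(
    recording: CallRecording, config: MfccConfig, call_id: str = ""
) -> CallFeatures:
    """Duration + spectral centroid + 10 frame-averaged MFCCs for one call."""
    rec = to_mono(recording)
    feats = CallFeatures(
        call_id=call_id or rec.individual_id,
        individual_id=rec.individual_id,
        species_id=rec.species_id,
        call_type=rec.call_type,
        duration=duration(rec),
        spectral_centroid=spectral_centroid(rec),
        mfcc=mfcc_per_call(rec, config),
    )
    feats.validate(rec.sample_rate)
    return feats


def extract_feature_table(
    recordings: Iterable[CallRecording],
    meow_cfg: MfccConfig | None = None,
    purr_cfg: MfccConfig | None = None,
) -> pd.DataFrame:
    """Feature rows for a set of calls, windowed per call type."""
    meow_cfg = meow_cfg or meow_config()
    purr_cfg = purr_cfg or purr_config()
    rows = []
    for i, rec in enumerate(recordings):
        cfg = meow_cfg if rec.call_type == "meow" else purr_cfg
        f = extract_features(rec, cfg, call_id=f"call_{i:04d}")
        rows.append(
            [f.call_id, f.individual_id, f.species_id, f.call_type, f.duration, f.spectral_centroid]
            + list(f.mfcc)
        )
    return pd.DataFrame(rows, columns=_CSV_HEADER)


def write_feature_csv(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the per-call feature table in the supplementary-data layout."""
    table.to_csv(path, sep=sep, index=False)


_HEADER_ALIASES = {
    "call_id": ("call_id", "call", "id", "recording", "file"),
    "individual_id": ("individual_id", "individual", "cat_id", "cat", "caller", "subject"),
    "species_id": ("species_id", "species"),
    "call_type": ("call_type", "type", "vocalisation", "vocalization"),
    "duration_s": ("duration_s", "duration", "dur", "duration_sec"),
    "spectral_centroid_hz": (
        "spectral_centroid_hz",
        "spectral_centroid",
        "centroid",
        "centroid_hz",
    ),
}


def _normalise(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def read_feature_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a feature table, tolerating header-name variants.

    The delimiter is sniffed when not given.  Columns are mapped by fuzzy
    header match (case/punctuation-insensitive aliases; ``mfcc 1``/``MFCC1``
    both map to ``mfcc1``); unmapped required columns raise ``ValueError``.
    Missing label columns are filled with empty strings so pre-extracted
    tables without, e.g., species labels still load.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    rename = {}
    for col in df.columns:
        key = _normalise(str(col))
        for target, aliases in _HEADER_ALIASES.items():
            if key in tuple(_normalise(a) for a in aliases):
                rename[col] = target
                break
        else:
            if key.startswith("mfcc") and key[4:].isdigit():
                rename[col] = f"mfcc{int(key[4:])}"
    df = df.rename(columns=rename)
    for col in ("call_id", "individual_id", "species_id", "call_type"):
        if col not in df.columns:
            df[col] = ""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return df[_CSV_HEADER]
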