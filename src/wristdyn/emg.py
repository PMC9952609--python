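"""Surface-EMG preprocessing and spectral feature extraction.

Pipeline: band-pass (second-order Butterworth, 10-2000 Hz) and 50 Hz notch
filtering, segmentation into non-overlapping short-term windows (0.25 s) and
overlapping mid-term windows (2 s length, 1 s step), per-window power
spectral density, and the muscle-fatigue features

    MNF = sum(fj * Pj) / sum(Pj)      (mean frequency, Hz)
    MNP = sum(Pj) / M                 (mean power)
    MDF = first fj whose cumulative power reaches half the total (Hz)

Fatigue shifts the sEMG spectrum toward lower frequencies, so MNF/MDF drop
and the features separate fatigued from fresh muscle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InputError, ParameterError, UndefinedFeatureError

__all__ = [
    "EMGRecording",
    "WindowSpec",
    "PowerSpectrum",
    "SpectralFeatures",
    "filter_emg",
    "segment_windows",
    "power_spectrum",
    "spectral_features",
    "extract_feature_table",
]

BAND_LOW_HZ = 10.0
BAND_HIGH_HZ = 2000.0
NOTCH_HZ = 50.0
NOTCH_Q = 30.0


@dataclass(frozen=True)
class EMGRecording:
    """Multichannel surface-EMG recording.

    ``channels`` maps channel names (e.g. ``FCU``, ``BR``) to equal-length
    amplitude arrays in microvolts.  ``filtered`` is a provenance flag set by
    :func:`filter_emg`.
    """

    fs: float
    channels: dict
    filtered: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if not self.channels:
            raise InputError("recording needs at least one channel")
        chans = {}
        length = None
        for name, x in self.channels.items():
            arr = np.asarray(x, dtype=float).reshape(-1)
            if length is None:
                length = arr.size
            elif arr.size != length:
                raise InputError("all channels must have equal length")
            chans[name] = arr
        object.__setattr__(self, "channels", chans)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Short/mid-term analysis window lengths (seconds)."""

    short_len: float = 0.25
    mid_len: float = 2.0
    mid_step: float = 1.0

    def __post_init__(self):
        if min(self.short_len, self.mid_len, self.mid_step) <= 0:
            raise ParameterError("window lengths must be positive")
        if self.mid_step > self.mid_len:
            raise ParameterError("mid_step must not exceed mid_len")


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a frequency-bin grid."""

    fj: np.ndarray
    Pj: np.ndarray

    def __post_init__(self):
        fj = np.asarray(self.fj, dtype=float)
        Pj = np.asarray(self.Pj, dtype=float)
        if fj.shape != Pj.shape or fj.ndim != 1:
            raise InputError("fj and Pj must be equal-length 1-D arrays")
        if np.any(np.diff(fj) <= 0) or fj[0] < 0:
            raise InputError("fj must be strictly increasing and non-negative")
        if np.any(Pj < 0):
            raise InputError("Pj must be non-negative")
        object.__setattr__(self, "fj", fj)
        object.__setattr__(self, "Pj", Pj)

    @property
    def M(self) -> int:
        return self.fj.size


@dataclass(frozen=True)
class SpectralFeatures:
    mnf: float
    mnp: float
    mdf: float
    t_start: float | None = None
    t_end: float | None = None
    channel: str | None = None


def filter_emg(
    rec: EMGRecording,
    band: tuple[float, float] = (BAND_LOW_HZ, BAND_HIGH_HZ),
    notch_hz: float = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
    zero_phase: bool = True,
) -> EMGRecording:
    """Band-pass then notch-filter every channel.

    The band-pass is a second-order Butterworth IIR; mains interference is
    removed with a second-order IIR notch (quality factor ``notch_q``) at
    ``notch_hz``.  Filters are applied forward-backward by default
    (zero-phase); set ``zero_phase=False`` for the causal streaming-parity
    mode.  When the sampling rate cannot support the upper band edge it is
    clipped to ``0.45 * fs`` with a warning.
    """
    low, high = band
    if rec.fs <= 2 * low:
        raise ParameterError(
            f"fs = {rec.fs} Hz cannot support a {low} Hz band-pass lower edge"
        )
    if rec.fs <= 2 * high:
        high = 0.45 * rec.fs
        warnings.warn(
            f"band upper edge clipped to {high:.1f} Hz for fs = {rec.fs} Hz",
            stacklevel=2,
        )
    sos_band = signal.butter(2, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    b_notch, a_notch = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)

    def apply(x):
        if zero_phase:
            y = signal.sosfiltfilt(sos_band, x)
            return signal.filtfilt(b_notch, a_notch, y)
        y = signal.sosfilt(sos_band, x)
        return signal.lfilter(b_notch, a_notch, y)

    out = {name: apply(x) for name, x in rec.channels.items()}
    return replace(rec, channels=out, filtered=True)


def segment_windows(rec: EMGRecording, spec: WindowSpec = WindowSpec()):
    """Segment into short-term and mid-term windows.

    Returns ``(short, mid)``: lists of ``(t_start, t_end, slice)`` tuples
    with absolute start times.  Trailing partial windows are dropped; a
    recording shorter than a window yields an empty list for that kind.
    """
    n = rec.n_samples

    def cut(length_s: float, step_s: float):
        win = int(round(length_s * rec.fs))
        step = int(round(step_s * rec.fs))
        out = []
        start = 0
        while start + win <= n:
            out.append((start / rec.fs, (start + win) / rec.fs, slice(start, start + win)))
            start += step
        return out

    short = cut(spec.short_len, spec.short_len)  # non-overlapping
    mid = cut(spec.mid_len, spec.mid_step)
    if not short and not mid:
        warnings.warn("recording shorter than every analysis window", stacklevel=2)
    return short, mid


def power_spectrum(x: np.ndarray, fs: float, taper: str = "hann") -> PowerSpectrum:
    """Hann-tapered one-sided periodogram of one window.

    The mean is removed first; normalization is Parseval-consistent
    (``sum(Pj) * df`` approximates the detrended window's mean square).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InputError("power spectrum needs at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise InputError("window contains non-finite samples")
    fj, Pj = signal.periodogram(x, fs=fs, window=taper, detrend="constant")
    return PowerSpectrum(fj=fj, Pj=Pj)


def spectral_features(ps: PowerSpectrum) -> SpectralFeatures:
    """MNF, MNP and MDF of one power spectrum.

    MNP is defined for any spectrum (zero for all-zero input); MNF and MDF
    require positive total power.
    """
    total = float(np.sum(ps.Pj))
    mnp = total / ps.M
    if total <= 0:
        raise UndefinedFeatureError("MNF/MDF undefined for an all-zero spectrum")
    mnf = float(np.sum(ps.fj * ps.Pj) / total)
    cum = np.cumsum(ps.Pj)
    mdf = float(ps.fj[np.searchsorted(cum, total / 2.0)])
    return SpectralFeatures(mnf=mnf, mnp=mnp, mdf=mdf)


def extract_feature_table(
    rec: EMGRecording,
    spec: WindowSpec = WindowSpec(),
    allow_raw: bool = False,
) -> pd.DataFrame:
    """Per-channel spectral features over the mid-term windows.

    Fatigue evolves slowly, so the classifier consumes mid-term windows; the
    short-term segmentation is available through :func:`segment_windows`.
    Refuses unfiltered recordings unless ``allow_raw`` is set.

    Returns a DataFrame with columns
    ``t_start, t_end, channel, mnf_hz, mnp, mdf_hz``.
    """
    if not rec.filtered and not allow_raw:
        raise InputError(
            "recording has not passed filter_emg; pass allow_raw=True to override"
        )
    _, mid = segment_windows(rec, spec)
    rows = []
    for name, x in rec.channels.items():
        for t0, t1, sl in mid:
            feats = spectral_features(power_spectrum(x[sl], rec.fs))
            rows.append(
                {
                    "t_start": t0,
                    "t_end": t1,
                    "channel": name,
                    "mnf_hz": feats.mnf,
                    "mnp": feats.mnp,
                    "mdf_hz": feats.mdf,
                }
            )
    return pd.DataFrame(rows, columns=["t_start", "t_end", "channel", "mnf_hz", "mnp", "mdf_hz"])
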