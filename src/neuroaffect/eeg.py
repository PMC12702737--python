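"""Band-power feature extraction from pre/post EEG recordings.

The pipeline mirrors a standard affective-neuroscience recipe: zero-phase
4th-order Butterworth band-pass (1-50 Hz), segmentation into 2-s
non-overlapping epochs, per-epoch baseline correction (mean subtraction),
Welch PSD inside each epoch (1-s Hann segments, 50% overlap), trapezoidal
band integration over the canonical bands, and arithmetic-mean aggregation
over epochs and a named channel set.  Change scores are raw post-minus-pre
differences of the aggregated band powers and are never rescaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .exceptions import InputError

__all__ = [
    "BANDS",
    "THETA_CHANNELS",
    "GAMMA_CHANNELS",
    "EEGRecording",
    "PSDSpectrum",
    "BandPowerSummary",
    "ChangeScores",
    "bandpass_filter",
    "epoch",
    "baseline_correct",
    "compute_psd",
    "band_power",
    "time_domain_descriptors",
    "band_power_summary",
    "change_scores",
]

#: Canonical EEG bands (Hz).  Gamma is capped at the 50 Hz filter ceiling.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Default frontal-midline aggregate for theta.
THETA_CHANNELS = ("Fz", "FCz", "Cz")
#: Default frontal-parietal aggregate for gamma.
GAMMA_CHANNELS = ("F3", "F4", "Fz", "P3", "P4", "Pz")


@dataclass
class EEGRecording:
    """A multichannel recording: ``samples`` is channels x time, microvolts."""

    channel_labels: List[str]
    fs: float
    samples: np.ndarray
    condition: str = "pre"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InputError("fs must be > 0")
        if self.samples.ndim != 2:
            raise InputError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PSDSpectrum:
    """One-sided power spectral density per channel (microvolts^2 / Hz)."""

    frequencies: np.ndarray
    power: np.ndarray  # channels x frequencies

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise InputError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise InputError("PSD power must be non-negative")


@dataclass
class BandPowerSummary:
    """Absolute band power per band per channel, plus the two aggregates."""

    channel_labels: List[str]
    band_powers: Dict[str, np.ndarray]  # band -> per-channel power
    theta_aggregate: float
    gamma_aggregate: float


@dataclass
class ChangeScores:
    """Raw post-minus-pre differences of aggregated band power."""

    theta_change: float
    gamma_change: float


def bandpass_filter(recording: EEGRecording, low: float = 1.0,
                    high: float = 50.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass per channel.

    Forward-backward filtering avoids phase distortion of band power; the
    effective magnitude order doubles.
    """
    nyq = recording.fs / 2.0
    if not 0 < low < high:
        raise InputError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise InputError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, (low, high), btype="bandpass",
                     fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=-1)
    return EEGRecording(channel_labels=list(recording.channel_labels),
                        fs=recording.fs, samples=filtered,
                        condition=recording.condition)


def epoch(recording: EEGRecording, epoch_seconds: float = 2.0) -> List[np.ndarray]:
    """Split into floor(T / epoch_seconds) non-overlapping epochs.

    Half-open 0-based windows; the trailing remainder is dropped.
    """
    samples_per = int(round(epoch_seconds * recording.fs))
    n_epochs = recording.n_samples // samples_per
    if n_epochs < 1:
        raise InputError(
            f"recording of {recording.duration:.3f} s shorter than one "
            f"{epoch_seconds} s epoch")
    return [recording.samples[:, k * samples_per:(k + 1) * samples_per]
            for k in range(n_epochs)]


def baseline_correct(ep: np.ndarray) -> np.ndarray:
    """Subtract each channel's epoch mean (minimal baseline correction)."""
    ep = np.asarray(ep, dtype=float)
    return ep - ep.mean(axis=-1, keepdims=True)


def compute_psd(ep: np.ndarray, fs: float) -> PSDSpectrum:
    """Welch PSD per channel: 1-s Hann segments, 50% overlap.

    Density scaling, so the trapezoidal integral over frequency approximates
    the signal variance (Parseval).
    """
    ep = np.atleast_2d(np.asarray(ep, dtype=float))
    if ep.shape[-1] < 2:
        raise InputError("epoch must have at least 2 samples")
    nperseg = min(int(round(fs)), ep.shape[-1])
    freqs, power = sps.welch(ep, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2, detrend=False, axis=-1)
    return PSDSpectrum(frequencies=freqs, power=power)


def band_power(psd: PSDSpectrum, band: Tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the PSD over [low, high), per channel.

    Band edges falling between grid points are handled by linear
    interpolation, which makes band power exactly additive over adjacent
    bands.
    """
    low, high = band
    if not low < high:
        raise InputError(f"empty band ({low}, {high})")
    f = psd.frequencies
    if low < f[0] - 1e-12 or high > f[-1] + 1e-12:
        raise InputError(
            f"band ({low}, {high}) outside PSD range ({f[0]}, {f[-1]})")
    inner = f[(f > low) & (f < high)]
    grid = np.concatenate(([low], inner, [high]))
    vals = np.vstack([np.interp(grid, f, psd.power[c])
                      for c in range(psd.power.shape[0])])
    return np.trapezoid(vals, grid, axis=-1)


def time_domain_descriptors(ep: np.ndarray):
    """Per-channel mean, SD, skewness, kurtosis (excess) of an epoch.

    For constant channels the SD is 0 and skewness/kurtosis are NaN
    (undefined); descriptive output only.
    """
    ep = np.atleast_2d(np.asarray(ep, dtype=float))
    if ep.shape[-1] < 4:
        raise InputError("epoch must have at least 4 samples")
    mean = ep.mean(axis=-1)
    sd = ep.std(axis=-1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant channels are flagged as NaN below; silence scipy's
        # precision warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = spstats.skew(ep, axis=-1)
        kurt = spstats.kurtosis(ep, axis=-1)
    skew = np.where(sd == 0, np.nan, skew)
    kurt = np.where(sd == 0, np.nan, kurt)
    return mean, sd, skew, kurt


def _aggregate(powers: np.ndarray, labels: Sequence[str],
               channel_set: Sequence[str]) -> float:
    missing = [c for c in channel_set if c not in labels]
    if missing:
        raise InputError(f"channel set not found in recording: {missing}")
    idx = [list(labels).index(c) for c in channel_set]
    return float(np.mean(powers[idx]))


def band_power_summary(recording: EEGRecording,
                       theta_channels: Sequence[str] = THETA_CHANNELS,
                       gamma_channels: Sequence[str] = GAMMA_CHANNELS,
                       epoch_seconds: float = 2.0) -> BandPowerSummary:
    """Run filter -> epoch -> baseline -> PSD -> band power, mean over epochs."""
    filtered = bandpass_filter(recording)
    epochs = epoch(filtered, epoch_seconds)
    per_band = {name: [] for name in BANDS}
    for ep in epochs:
        psd = compute_psd(baseline_correct(ep), recording.fs)
        for name, band in BANDS.items():
            per_band[name].append(band_power(psd, band))
    band_powers = {name: np.mean(vals, axis=0) for name, vals in per_band.items()}
    return BandPowerSummary(
        channel_labels=list(recording.channel_labels),
        band_powers=band_powers,
        theta_aggregate=_aggregate(band_powers["theta"],
                                   recording.channel_labels, theta_channels),
        gamma_aggregate=_aggregate(band_powers["gamma"],
                                   recording.channel_labels, gamma_channels),
    )


def change_scores(pre: EEGRecording, post: EEGRecording,
                  theta_channels: Sequence[str] = THETA_CHANNELS,
                  gamma_channels: Sequence[str] = GAMMA_CHANNELS) -> ChangeScores:
    """Unstandardized post-minus-pre band-power change scores.

    Theta is aggregated over the frontal-midline set, gamma over the
    frontal-parietal set (both configurable).
    """
    if list(pre.channel_labels) != list(post.channel_labels):
        raise InputError("pre and post recordings have different channel labels")
    if pre.fs != post.fs:
        raise InputError("pre and post recordings have different sampling rates")
    s_pre = band_power_summary(pre, theta_channels, gamma_channels)
    s_post = band_power_summary(post, theta_channels, gamma_channels)
    return ChangeScores(
        theta_change=s_post.theta_aggregate - s_pre.theta_aggregate,
        gamma_change=s_post.gamma_aggregate - s_pre.gamma_aggregate,
    )
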