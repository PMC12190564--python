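"""Preprocessing chain for one recording.

Fixed order: resample to the analysis rate -> power-line notch ->
high-pass -> robust average reference -> edge trim -> non-overlapping
5-s epochs.  All filters run forward-backward (zero phase) so that
phase-based connectivity downstream is not biased by filter delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

TIMEPOINTS = ("pre2h", "baseline", "1h", "2h", "3h", "4h", "12h", "1d")

MONTAGE_1020 = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8",
    "Pz", "P3", "P4", "P7", "P8", "O1", "O2",
)


@dataclass
class RawRecording:
    """One subject x time-point multichannel scalp EEG signal (microvolts)."""

    subject: str
    timepoint: str
    montage: tuple
    rate_hz: float
    data: np.ndarray  # channels x samples, µV

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError("data must be channels x samples matching montage")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EpochArray:
    """Consecutive non-overlapping fixed-length epochs of one recording."""

    subject: str
    timepoint: str
    montage: tuple
    rate_hz: float
    epoch_s: float
    data: np.ndarray  # epochs x channels x samples
    bad_channels: tuple = ()

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


def resample(rec: RawRecording, target_hz: float) -> RawRecording:
    """Anti-alias low-pass (cutoff 0.45 * target rate) then rational-ratio
    polyphase resampling. Only downsampling (or identity) is supported."""
    if target_hz > rec.rate_hz:
        raise ValueError("upsampling not supported")
    if target_hz == rec.rate_hz:
        return replace(rec, data=rec.data.copy())
    sos = signal.butter(8, 0.45 * target_hz, btype="low", fs=rec.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return replace(rec, rate_hz=float(target_hz), data=out)


def notch_filter(rec: RawRecording, line_hz: float = 60.0, q: float = 30.0) -> RawRecording:
    """Zero-phase second-order IIR notch (Q = 30) at the power-line frequency."""
    if line_hz >= rec.rate_hz / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(line_hz, q, fs=rec.rate_hz)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=out)


def highpass_filter(rec: RawRecording, cutoff_hz: float = 1.0) -> RawRecording:
    """Zero-phase 4th-order Butterworth high-pass removing DC and slow drift."""
    if cutoff_hz >= rec.rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(4, cutoff_hz, btype="high", fs=rec.rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def _flag_bad(data: np.ndarray, z_thresh: float, corr_thresh: float) -> np.ndarray:
    """Flag channels with outlying amplitude or no correlation to any other.

    Criteria: robust z-score (median/MAD across channels) of the channel SD
    above `z_thresh`, or maximum absolute correlation with every other
    channel below `corr_thresh`.
    """
    sds = data.std(axis=1)
    med = np.median(sds)
    mad = np.median(np.abs(sds - med))
    # floor keeps the z-score finite when channel SDs are nearly identical
    scale = max(1.4826 * mad, 0.01 * med, 1e-30)
    z = (sds - med) / scale
    bad = np.abs(z) > z_thresh

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant channels give NaN rows
        corr = np.corrcoef(data)
    np.fill_diagonal(corr, np.nan)
    max_corr = np.nanmax(np.abs(corr), axis=1)
    bad |= ~(max_corr >= corr_thresh)  # NaN (constant channel) counts as bad
    return bad


def robust_average_reference(
    rec: RawRecording,
    z_thresh: float = 5.0,
    corr_thresh: float = 0.4,
    n_passes: int = 2,
) -> tuple:
    """Average reference estimated from good channels only.

    Bad channels are detected (amplitude z-score / correlation criteria),
    the reference is the mean of the remaining channels, and detection is
    refined once on the referenced data.  Bad channels stay in the output
    (they are only excluded from the reference estimate).

    Returns (referenced recording, tuple of bad channel labels).
    """
    if len(rec.montage) < 4:
        raise ValueError("robust reference needs at least 4 channels")
    bad = _flag_bad(rec.data, z_thresh, corr_thresh)
    for _ in range(n_passes):
        good = ~bad
        if not good.any():
            raise RuntimeError("all channels flagged bad; cannot re-reference")
        ref = rec.data[good].mean(axis=0)
        referenced = rec.data - ref
        bad = bad | _flag_bad(referenced, z_thresh, corr_thresh)
    good = ~bad
    if not good.any():
        raise RuntimeError("all channels flagged bad; cannot re-reference")
    ref = rec.data[good].mean(axis=0)
    out = replace(rec, data=rec.data - ref)
    bad_labels = tuple(np.asarray(rec.montage)[bad])
    return out, bad_labels


def epoch(rec: RawRecording, epoch_s: float = 5.0, bad_channels: tuple = ()) -> EpochArray:
    """Cut into consecutive non-overlapping epochs; trailing partial epoch
    is discarded."""
    spe = int(round(epoch_s * rec.rate_hz))
    n = rec.n_samples // spe
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n * spe].reshape(len(rec.montage), n, spe).transpose(1, 0, 2)
    return EpochArray(
        subject=rec.subject,
        timepoint=rec.timepoint,
        montage=rec.montage,
        rate_hz=rec.rate_hz,
        epoch_s=epoch_s,
        data=data.copy(),
        bad_channels=tuple(bad_channels),
    )


def amplitude_screen(ep: EpochArray, limit_uv: float = 500.0) -> EpochArray:
    """Drop epochs containing any sample beyond +-limit_uv (artifact guard
    for real recordings; synthetic data is clean by construction)."""
    keep = np.abs(ep.data).max(axis=(1, 2)) <= limit_uv
    return replace(ep, data=ep.data[keep])


def preprocess_recording(
    rec: RawRecording,
    target_hz: float = 200.0,
    line_hz: float = 60.0,
    highpass_hz: float = 1.0,
    epoch_s: float = 5.0,
    edge_trim_s: float = 1.0,
    screen_uv: float | None = None,
) -> EpochArray:
    """Full chain: resample -> notch -> high-pass -> robust reference ->
    edge trim -> epoch (-> optional amplitude screen)."""
    rec = resample(rec, target_hz)
    rec = notch_filter(rec, line_hz)
    rec = highpass_filter(rec, highpass_hz)
    rec, bad = robust_average_reference(rec)
    trim = int(round(edge_trim_s * rec.rate_hz))
    if trim > 0 and rec.n_samples > 2 * trim:
        rec = replace(rec, data=rec.data[:, trim:-trim])
    ep = epoch(rec, epoch_s, bad_channels=bad)
    if screen_uv is not None:
        ep = amplitude_screen(ep, screen_uv)
    return ep
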