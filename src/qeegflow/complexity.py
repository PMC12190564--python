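"""Signal-complexity measures: permutation entropy and spectral entropy.

Permutation entropy is the Shannon entropy of the distribution of ordinal
patterns of m-sample motifs (default m = 3, lag 1), normalized by
log2(m!) to [0, 1]; ties are broken by order of occurrence (the earlier
index ranks lower), which makes the measure deterministic.  Per-band
values are computed on zero-phase band-pass-filtered signals.

Spectral entropy is the Shannon entropy of the PSD normalized to a
probability distribution over the in-band frequency bins, scaled by
log2(n_bins) to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandScheme
from .preprocess import EpochArray
from .spectral import FEATURE_COLUMNS, SpectralEstimate, _with_global


@dataclass(frozen=True)
class ComplexityConfig:
    order: int = 3  # embedding dimension m
    delay: int = 1  # lag tau in samples
    normalize: bool = True

    def __post_init__(self):
        if self.order < 2 or self.delay < 1:
            raise ValueError("need order >= 2 and delay >= 1")


def _ordinal_codes(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Integer code of the ordinal pattern of every m-motif along the last
    axis. Stable argsort ranks tied samples by occurrence order."""
    span = (m - 1) * tau + 1
    if x.shape[-1] < span + 1:
        raise ValueError("signal too short for the requested embedding")
    win = np.lib.stride_tricks.sliding_window_view(x, span, axis=-1)[..., ::tau]
    pattern = np.argsort(win, axis=-1, kind="stable")
    weights = m ** np.arange(m)
    return pattern @ weights


def permutation_entropy(x: np.ndarray, cfg: ComplexityConfig = ComplexityConfig()) -> float:
    """Normalized permutation entropy of a 1-D signal, in [0, 1]."""
    codes = _ordinal_codes(np.asarray(x, dtype=float), cfg.order, cfg.delay)
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    h = -(p * np.log2(p)).sum()
    if cfg.normalize:
        h /= math.log2(math.factorial(cfg.order))
    return float(h)


def _pe_array(x: np.ndarray, cfg: ComplexityConfig) -> np.ndarray:
    """Permutation entropy along the last axis of an N-D array."""
    codes = _ordinal_codes(np.asarray(x, dtype=float), cfg.order, cfg.delay)
    flat = codes.reshape(-1, codes.shape[-1])
    n_codes = cfg.order ** cfg.order
    out = np.empty(flat.shape[0])
    for i, row in enumerate(flat):
        counts = np.bincount(row, minlength=n_codes)
        p = counts[counts > 0] / row.size
        out[i] = -(p * np.log2(p)).sum()
    if cfg.normalize:
        out /= math.log2(math.factorial(cfg.order))
    return out.reshape(codes.shape[:-1])


def band_limited_pe(
    epochs: EpochArray,
    band: str,
    cfg: ComplexityConfig = ComplexityConfig(),
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Permutation entropy of the band-filtered signal, per channel
    (epoch-averaged) plus a GLOBAL row."""
    scheme = scheme or BandScheme()
    lo, hi = scheme.limits(band)
    if hi >= epochs.rate_hz / 2:
        raise ValueError("band exceeds Nyquist")
    sos = signal.butter(4, [lo, hi], btype="band", fs=epochs.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    pe = _pe_array(filtered, cfg)  # epochs x channels
    per_channel = pe.mean(axis=0)
    rows = [
        (epochs.subject, ch, epochs.timepoint, "perm_entropy", band, v)
        for ch, v in zip(epochs.montage, per_channel)
    ]
    return _with_global(pd.DataFrame(rows, columns=FEATURE_COLUMNS))


def spectral_entropy(
    est: SpectralEstimate, band: str, scheme: BandScheme | None = None
) -> pd.DataFrame:
    """Normalized Shannon entropy of the in-band PSD distribution, per
    channel (epoch-averaged) plus a GLOBAL row."""
    scheme = scheme or BandScheme()
    mask = scheme.mask(est.freqs, band)
    if mask.sum() < 2:
        raise ValueError("band needs at least 2 frequency bins")
    psd = est.psd[:, :, mask]
    total = psd.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, psd / total, np.nan)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h = -plogp.sum(axis=-1) / np.log2(mask.sum())
    h = np.where(np.isfinite(total[..., 0]) & (total[..., 0] > 0), h, np.nan)
    per_channel = h.mean(axis=0)
    rows = [
        (est.subject, ch, est.timepoint, "spec_entropy", band, v)
        for ch, v in zip(est.montage, per_channel)
    ]
    return _with_global(pd.DataFrame(rows, columns=FEATURE_COLUMNS))
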