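"""Multitaper power spectra, relative band powers and band ratios.

The PSD estimator uses DPSS (Slepian) tapers with time-half-bandwidth
product ``NW = epoch_s * half_bandwidth`` (default 5 for 5-s epochs and a
1 Hz half bandwidth) and ``2*NW - 1`` tapers, averaging one-sided
density-scaled periodograms over tapers.  Feature rows follow the long
format (subject, channel-or-GLOBAL, timepoint, metric, band, value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from .bands import BandScheme
from .preprocess import EpochArray

FEATURE_COLUMNS = ["subject", "channel", "timepoint", "metric", "band", "value"]

#: metric names of the five spectral ratios, with numerator/denominator bands
RATIO_DEFS = {
    "ratio_theta_alpha": (("theta",), ("alpha",)),
    "ratio_theta_beta": (("theta",), ("beta",)),
    "ratio_delta_alpha": (("delta",), ("alpha",)),
    "ratio_slow_fast": (("delta", "theta"), ("alpha", "beta")),
    "ratio_delta_alphatheta": (("delta",), ("alpha", "theta")),
}


@dataclass
class SpectralEstimate:
    """Per-epoch, per-channel one-sided multitaper PSD (µV²/Hz)."""

    subject: str
    timepoint: str
    montage: tuple
    freqs: np.ndarray
    psd: np.ndarray  # epochs x channels x freqs
    half_bandwidth_hz: float
    n_tapers: int


def dpss_tapers(n_samples: int, rate_hz: float, half_bandwidth_hz: float) -> np.ndarray:
    """Unit-energy DPSS tapers for the requested half bandwidth."""
    nw = n_samples / rate_hz * half_bandwidth_hz
    k = int(2 * nw - 1)
    if k < 1:
        raise ValueError("epoch too short for the requested half bandwidth")
    return windows.dpss(n_samples, nw, Kmax=k)


def _onesided_scale(n_samples: int, rate_hz: float, n_freqs: int) -> np.ndarray:
    """Density scaling per rfft bin: 2/fs except the DC (and Nyquist, when
    present) bin, which are not mirrored."""
    scale = np.full(n_freqs, 2.0 / rate_hz)
    scale[0] = 1.0 / rate_hz
    if n_samples % 2 == 0:
        scale[-1] = 1.0 / rate_hz
    return scale


def multitaper_psd(epochs: EpochArray, half_bandwidth_hz: float = 1.0) -> SpectralEstimate:
    """Mean over tapers of |tapered DFT|^2, one-sided, density-scaled."""
    x = epochs.data  # E x C x N
    n = x.shape[-1]
    tapers = dpss_tapers(n, epochs.rate_hz, half_bandwidth_hz)
    # E x C x K x F
    tx = np.fft.rfft(x[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.rate_hz)
    scale = _onesided_scale(n, epochs.rate_hz, freqs.size)
    psd = (np.abs(tx) ** 2).mean(axis=2) * scale
    return SpectralEstimate(
        subject=epochs.subject, timepoint=epochs.timepoint, montage=epochs.montage,
        freqs=freqs, psd=psd, half_bandwidth_hz=half_bandwidth_hz,
        n_tapers=tapers.shape[0],
    )


def band_power(est: SpectralEstimate, scheme: BandScheme, band: str) -> np.ndarray:
    """Band-integrated power per epoch x channel (sum of in-band bins)."""
    return est.psd[:, :, scheme.mask(est.freqs, band)].sum(axis=-1)


def _with_global(df: pd.DataFrame) -> pd.DataFrame:
    """Append GLOBAL rows: mean over channels per (subject,timepoint,metric,band)."""
    g = (
        df.groupby(["subject", "timepoint", "metric", "band"], as_index=False)["value"]
        .mean()
    )
    g["channel"] = "GLOBAL"
    return pd.concat([df, g[FEATURE_COLUMNS]], ignore_index=True)


def relative_band_power(est: SpectralEstimate, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Relative power of the four bands w.r.t. broadband (1-30 Hz).

    Computed per epoch, averaged over epochs per channel; GLOBAL row is the
    mean over channels.  The four relative powers sum to 1 per channel.
    """
    scheme = scheme or BandScheme()
    broad = band_power(est, scheme, scheme.broadband[0])
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in scheme.names:
            rel = np.where(broad > 0, band_power(est, scheme, name) / broad, np.nan)
            per_channel = rel.mean(axis=0)  # NaN epochs flag the channel missing
            for ch, v in zip(est.montage, per_channel):
                rows.append((est.subject, ch, est.timepoint, "rel_power", name, v))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return _with_global(df)


def band_ratios(rel: pd.DataFrame) -> pd.DataFrame:
    """The five spectral ratios from channel-level relative band powers.

    The broadband normalizer cancels, so ratios of relative powers equal
    ratios of absolute band powers.  Zero denominators yield NaN
    (flagged-missing) rows.  Ratios carry band label 'none'.
    """
    chan = rel[(rel.metric == "rel_power") & (rel.channel != "GLOBAL")]
    wide = chan.pivot_table(
        index=["subject", "channel", "timepoint"], columns="band", values="value"
    )
    rows = []
    for (subject, channel, tp), r in wide.iterrows():
        for metric, (num, den) in RATIO_DEFS.items():
            d = sum(r[b] for b in den)
            v = sum(r[b] for b in num) / d if d > 0 else np.nan
            rows.append((subject, channel, tp, metric, "none", v))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return _with_global(df)
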