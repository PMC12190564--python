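"""Coherence and weighted phase lag index from multitaper cross-spectra.

Observations pool epochs AND tapers, maximizing the count at fixed
recording length.  Per frequency bin, with k indexing observations,

    Coh_xy(f)  = |mean_k S_xy,k(f)| / sqrt(mean_k S_xx,k(f) * mean_k S_yy,k(f))
    wPLI_xy(f) = |mean_k Im S_xy,k(f)| / mean_k |Im S_xy,k(f)|

and the band value is the mean of the estimator over in-band bins.  wPLI
ignores amplitude-only (zero-lag) coupling because a real cross-spectrum
contributes nothing to the imaginary part; coherence does not — the
defining contrast between the two measures.

The cross-spectral tensor of a 5-min 19-channel recording is large, so
``CrossSpectra`` stores the tapered FFT coefficients and materializes
S_xy per channel pair on demand (``pair`` / ``tensor``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandScheme
from .preprocess import EpochArray
from .spectral import _onesided_scale, dpss_tapers

CONNECTIVITY_COLUMNS = ["subject", "timepoint", "method", "band", "pair", "value"]


@dataclass
class CrossSpectra:
    """Tapered spectra X (epochs x tapers x channels x freqs); the
    cross-spectrum S_xy,k(f) = X_x,k(f) * conj(X_y,k(f)) is Hermitian in
    (x, y) and its diagonal equals the multitaper PSD after averaging
    over tapers."""

    subject: str
    timepoint: str
    montage: tuple
    freqs: np.ndarray
    coeffs: np.ndarray  # epochs x tapers x channels x freqs, density-scaled

    @property
    def n_observations(self) -> int:
        return self.coeffs.shape[0] * self.coeffs.shape[1]

    def pair(self, i: int, j: int) -> np.ndarray:
        """S_xy for one channel pair, flattened to (observations, freqs)."""
        s = self.coeffs[:, :, i, :] * np.conj(self.coeffs[:, :, j, :])
        return s.reshape(-1, self.freqs.size)

    def tensor(self) -> np.ndarray:
        """Full epochs x tapers x channels x channels x freqs tensor (use
        on small fixtures only)."""
        return np.einsum("etcf,etdf->etcdf", self.coeffs, np.conj(self.coeffs))


def cross_spectra(epochs: EpochArray, half_bandwidth_hz: float = 1.0) -> CrossSpectra:
    """DPSS-tapered FFT coefficients scaled so that mean_k |X|^2 equals the
    one-sided multitaper PSD."""
    x = epochs.data
    n = x.shape[-1]
    tapers = dpss_tapers(n, epochs.rate_hz, half_bandwidth_hz)
    tx = np.fft.rfft(x[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    tx = tx.transpose(0, 2, 1, 3)  # epochs x tapers x channels x freqs
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.rate_hz)
    tx = tx * np.sqrt(_onesided_scale(n, epochs.rate_hz, freqs.size))
    return CrossSpectra(
        subject=epochs.subject, timepoint=epochs.timepoint,
        montage=epochs.montage, freqs=freqs, coeffs=tx,
    )


def coherence_bins(sxy: np.ndarray, sxx: np.ndarray, syy: np.ndarray) -> np.ndarray:
    """Coherence per frequency bin from (observations x freqs) spectra.
    Bins with a zero auto-spectrum are returned as NaN (skipped)."""
    num = np.abs(sxy.mean(axis=0))
    den = np.sqrt(sxx.real.mean(axis=0) * syy.real.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def wpli_bins(sxy: np.ndarray) -> np.ndarray:
    """wPLI per frequency bin; 0/0 (all imaginary parts zero) gives 0."""
    im = sxy.imag
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _pair_rows(cs: CrossSpectra, method: str, bands, scheme: BandScheme) -> pd.DataFrame:
    if cs.n_observations < 1:
        raise ValueError("no epoch x taper observations")
    # a single observation yields the degenerate coherence/wPLI of 1
    masks = {b: scheme.mask(cs.freqs, b) for b in bands}
    auto = (np.abs(cs.coeffs) ** 2).reshape(
        -1, len(cs.montage), cs.freqs.size
    )  # obs x channels x freqs
    rows = []
    for i, j in itertools.combinations(range(len(cs.montage)), 2):
        sxy = cs.pair(i, j)
        if method == "coherence":
            bins = coherence_bins(sxy, auto[:, i, :], auto[:, j, :])
        else:
            bins = wpli_bins(sxy)
        for b, m in masks.items():
            v = np.nanmean(bins[m])
            rows.append((cs.subject, cs.timepoint, method, b,
                         f"{cs.montage[i]}-{cs.montage[j]}", v))
    return pd.DataFrame(rows, columns=CONNECTIVITY_COLUMNS)


def coherence(cs: CrossSpectra, bands=None, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-pair coherence rows for the requested bands (default: the four
    narrow bands plus broadband)."""
    scheme = scheme or BandScheme()
    return _pair_rows(cs, "coherence", bands or scheme.all_names, scheme)


def wpli(cs: CrossSpectra, bands=None, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Per-pair weighted phase lag index rows."""
    scheme = scheme or BandScheme()
    return _pair_rows(cs, "wpli", bands or scheme.all_names, scheme)


def global_connectivity(pair_rows: pd.DataFrame, n_channels: int = 19) -> pd.DataFrame:
    """Unweighted mean over all C(n,2) unordered channel pairs per
    (subject, timepoint, method, band); errors if pairs are missing."""
    expected = n_channels * (n_channels - 1) // 2
    out = []
    for key, grp in pair_rows.groupby(["subject", "timepoint", "method", "band"]):
        if len(grp) != expected:
            have = set(grp["pair"])
            raise ValueError(
                f"{key}: expected {expected} pairs, got {len(grp)} "
                f"(missing {expected - len(grp)})"
            )
        out.append((*key, "GLOBAL", grp["value"].mean()))
    return pd.DataFrame(out, columns=CONNECTIVITY_COLUMNS)
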