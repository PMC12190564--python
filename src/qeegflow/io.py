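"""EDF I/O and cohort manifests.

Reading goes through MNE's EDF reader with channel-label
canonicalization (case-insensitive, legacy temporal labels T3/T4/T5/T6
mapped to T7/T8/P7/P8).  Writing uses a minimal EDF encoder (16-bit,
1-second data records, physical dimension µV) sufficient for round-trips
of synthetic cohorts.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MONTAGE_1020, RawRecording

LEGACY_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def canonical_label(label: str, montage=MONTAGE_1020) -> str | None:
    """Map an EDF channel label onto the montage (case-insensitive,
    'EEG Fp1-Ref'-style prefixes and legacy aliases honored)."""
    s = label.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    s = s.split("-")[0].strip()
    s = LEGACY_ALIASES.get(s.upper(), s)
    lut = {m.upper(): m for m in montage}
    return lut.get(s.upper())


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path) -> None:
    """Write one recording as EDF (int16, 1-s records, µV).

    The duration is truncated to whole seconds and the sampling rate must
    be an integer number of samples per second.
    """
    fs = rec.rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.montage)
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : n_records * fs]
    pmax = np.maximum(np.abs(data).max(axis=1), 1.0) * 1.0001
    dig = np.round(data / pmax[:, None] * 32767).astype("<i2")

    header_bytes = 256 * (n_ch + 1)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(f"Startdate X {rec.subject} {rec.timepoint}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for ch in rec.montage:
            fh.write(_pad(f"EEG {ch}", 16))
        for _ in rec.montage:
            fh.write(_pad("", 80))
        for _ in rec.montage:
            fh.write(_pad("uV", 8))
        for p in pmax:
            fh.write(_pad(f"{-p:.3f}"[:8], 8))
        for p in pmax:
            fh.write(_pad(f"{p:.3f}"[:8], 8))
        for _ in rec.montage:
            fh.write(_pad("-32768", 8))
        for _ in rec.montage:
            fh.write(_pad("32767", 8))
        for _ in rec.montage:
            fh.write(_pad("", 80))
        for _ in rec.montage:
            fh.write(_pad(str(fs), 8))
        for _ in rec.montage:
            fh.write(_pad("", 32))
        for r in range(n_records):
            block = dig[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path, montage=MONTAGE_1020, subject: str = "", timepoint: str = "") -> RawRecording:
    """Load an EDF/EDF+ file as a µV-scaled RawRecording in montage order."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    mapping = {}
    for name in raw.ch_names:
        canon = canonical_label(name, montage)
        if canon is not None and canon not in mapping:
            mapping[canon] = name
    missing = [m for m in montage if m not in mapping]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    picks = [mapping[m] for m in montage]
    data = raw.get_data(picks=picks) * 1e6  # volts -> µV
    return RawRecording(subject=subject, timepoint=timepoint,
                        montage=tuple(montage), rate_hz=float(raw.info["sfreq"]),
                        data=data)


def write_cohort(cohort, outdir) -> pd.DataFrame:
    """Write every recording as EDF plus a manifest CSV
    (subject, timepoint, path, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, tp), rec in cohort.recordings.items():
        fname = f"{subject}_{tp}.edf"
        write_edf(rec, outdir / fname)
        rows.append(dict(subject=subject, timepoint=tp, path=fname,
                         seed=cohort.spec.seed))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


def read_manifest(path, montage=MONTAGE_1020):
    """Iterate (subject, timepoint, RawRecording) from a manifest CSV."""
    path = Path(path)
    manifest = pd.read_csv(path)
    for row in manifest.itertuples():
        rec = read_edf(path.parent / row.path, montage=montage,
                       subject=str(row.subject), timepoint=str(row.timepoint))
        yield rec
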