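"""Canonical clinical-EEG frequency bands.

The four narrow bands partition the broadband range 1-30 Hz under a
half-open convention [lo, hi), with beta closed at 30 Hz so that the
relative band powers of any spectrum sum exactly to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BROADBAND = ("broadband", 1.0, 30.0)

DEFAULT_BANDS = [
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
]


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous band definitions plus the broadband envelope."""

    bands: tuple = tuple(DEFAULT_BANDS)
    broadband: tuple = BROADBAND

    def __post_init__(self):
        lo0 = self.bands[0][1]
        hi_prev = lo0
        for name, lo, hi in self.bands:
            if lo != hi_prev or hi <= lo:
                raise ValueError("bands must be contiguous and non-overlapping")
            hi_prev = hi
        if (lo0, hi_prev) != self.broadband[1:]:
            raise ValueError("union of bands must equal broadband")

    @property
    def names(self) -> list:
        return [b[0] for b in self.bands]

    @property
    def all_names(self) -> list:
        """Band names including broadband (the five analysis bands)."""
        return self.names + [self.broadband[0]]

    def limits(self, name: str) -> tuple:
        for b in list(self.bands) + [self.broadband]:
            if b[0] == name:
                return (b[1], b[2])
        raise KeyError(f"unknown band {name!r}")

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        """Boolean bin mask for a band: lo <= f < hi, upper edge closed at
        the broadband ceiling so the four bands partition 1-30 Hz."""
        lo, hi = self.limits(name)
        closed_hi = hi >= self.broadband[2]
        m = (freqs >= lo) & ((freqs <= hi) if closed_hi else (freqs < hi))
        return m
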