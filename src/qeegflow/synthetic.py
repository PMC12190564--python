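"""Synthetic multichannel EEG cohorts with planted dynamics.

Generates, for each subject and each of eight peri-treatment time points,
a multichannel scalp recording composed of:

* pink (1/f^chi) background noise, partly shared (zero-lag) within scalp
  neighborhoods so channels are spatially correlated like real EEG,
* band-limited oscillations (band-passed white noise, not pure tones, so
  spectra are realistically broad), shared within a neighborhood, whose
  amplitude follows a per-time-point multiplier schedule,
* optional phase-lagged coupling: a shared band-limited source added to a
  channel pair, the second copy delayed by ``phase_lag / (2*pi*f_center)``
  seconds, giving analytic control of the sign of the imaginary
  cross-spectrum (hence of wPLI),
* optional periodic-discharge-like triphasic transients,
* additive white sensor noise.

Everything is deterministic given the scenario seed; per-(subject,
time-point) generators are spawned from ``numpy.random.SeedSequence`` so
recordings are independent but reproducible.  Units are microvolts; the
background RMS defaults to 20 µV, a conventional scalp-EEG magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .bands import BandScheme
from .preprocess import MONTAGE_1020, TIMEPOINTS, RawRecording

#: base RMS (µV) of each band oscillation at multiplier 1.0
DEFAULT_OSC_RMS_UV = {"delta": 8.0, "theta": 7.0, "alpha": 6.0, "beta": 4.0}
#: RMS (µV) injected per unit coupling gain
COUPLING_RMS_UV = 10.0

#: scalp neighborhoods sharing background activity (zero-lag), so synthetic
#: channels are spatially correlated like real EEG; shared components are
#: purely real in the cross-spectrum and therefore invisible to wPLI
REGIONS_1020 = (
    ("Fp1", "F3", "F7"),
    ("Fp2", "F4", "F8"),
    ("Fz", "Cz", "Pz"),
    ("C3", "T7"),
    ("C4", "T8"),
    ("P3", "P7", "O1"),
    ("P4", "P8", "O2"),
)


def _region_index(montage: tuple) -> np.ndarray:
    """Region id per channel: the standard 10-20 neighborhoods when the
    montage is the 19-channel layout, otherwise consecutive triples."""
    if set(montage) == set(MONTAGE_1020):
        idx = np.empty(len(montage), dtype=int)
        for r, chans in enumerate(REGIONS_1020):
            for ch in chans:
                idx[montage.index(ch)] = r
        return idx
    return np.arange(len(montage)) // 3


@dataclass(frozen=True)
class Coupling:
    """Shared-source coupling between two channels in one band."""

    channel_a: str
    channel_b: str
    band: str
    phase_lag_rad: float
    gains: tuple  # per-time-point coupling gain (8 entries)

    def __post_init__(self):
        if not (-np.pi < self.phase_lag_rad <= np.pi):
            raise ValueError("phase lag must lie in (-pi, pi]")
        if len(self.gains) != 8:
            raise ValueError("one coupling gain per time point (8)")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic cohort scenario."""

    n_subjects: int = 6
    montage: tuple = MONTAGE_1020
    rate_hz: float = 500.0
    segment_s: float = 300.0
    timepoints: tuple = TIMEPOINTS
    band_amp: dict = field(default_factory=dict)  # band -> 8 multipliers
    coupling: tuple = ()
    pink_exponent: float = 1.0
    pd_rate_hz: float = 0.0
    pd_amp_uv: float = 50.0
    noise_sd: float = 2.0
    background_rms_uv: float = 20.0
    shared_frac: float = 0.6  # fraction of background variance shared within a region
    osc_rms_uv: dict = field(default_factory=lambda: dict(DEFAULT_OSC_RMS_UV))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.segment_s <= 0 or self.rate_hz <= 0:
            raise ValueError("invalid cohort geometry")
        if len(self.timepoints) != 8:
            raise ValueError("exactly 8 time points required")
        if self.timepoints[1] != "baseline":
            raise ValueError("'baseline' must be the second time point")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        for band, amps in self.band_amp.items():
            if len(amps) != 8:
                raise ValueError(f"band_amp[{band!r}] needs 8 entries")
            if any(a < 0 for a in amps):
                raise ValueError("amplitude multipliers must be >= 0")
        for c in self.coupling:
            if c.channel_a not in self.montage or c.channel_b not in self.montage:
                raise ValueError("coupling channels must be in the montage")

    def amps(self, band: str) -> np.ndarray:
        return np.asarray(self.band_amp.get(band, [1.0] * 8), dtype=float)

    @property
    def subjects(self) -> list:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class SyntheticCohort:
    spec: ScenarioSpec
    recordings: dict  # (subject, timepoint) -> RawRecording
    ground_truth: pd.DataFrame  # realized per-time-point amp / coupling targets


def _rng(spec: ScenarioSpec, *entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *entropy]))


def _band_noise(rng, n, fs, lo, hi, order=4) -> np.ndarray:
    """Unit-RMS band-passed white noise."""
    x = rng.standard_normal(n)
    sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = y.std()
    return y / rms if rms > 0 else y


def _pink_noise(rng, n, chi) -> np.ndarray:
    """Unit-RMS 1/f^chi noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    shaped = np.fft.irfft(spec_w * f ** (-chi / 2.0), n)
    return shaped / shaped.std()


def _fractional_delay(x: np.ndarray, delay_s: float, fs: float) -> np.ndarray:
    """Delay a signal by an arbitrary (fractional-sample) amount via FFT
    phase rotation; circular wrap-around is negligible for delays far
    shorter than the segment."""
    spec_x = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return np.fft.irfft(spec_x * np.exp(-2j * np.pi * f * delay_s), len(x))


def _pd_train(rng, n, fs, rate_hz, amp_uv) -> np.ndarray:
    """Triphasic periodic-discharge train: 20-60-20 ms half-sine lobes with
    alternating sign, repeated at rate_hz with 5% timing jitter."""
    lobe_ms = (20.0, 60.0, 20.0)
    lobe_sign = (-0.5, 1.0, -0.5)
    pieces = []
    for ms, s in zip(lobe_ms, lobe_sign):
        ln = max(int(round(ms / 1000.0 * fs)), 1)
        pieces.append(s * np.sin(np.pi * np.arange(ln) / ln))
    template = amp_uv * np.concatenate(pieces)
    out = np.zeros(n)
    period = fs / rate_hz
    t = 0.0
    while t < n - len(template):
        i = int(round(t))
        out[i : i + len(template)] += template
        t += period * (1.0 + 0.05 * rng.standard_normal())
    return out


def simulate_recording(spec: ScenarioSpec, subject: str, timepoint: str) -> RawRecording:
    """Generate one subject x time-point recording at the native rate."""
    if timepoint not in spec.timepoints:
        raise ValueError(f"unknown time point {timepoint!r}")
    si = spec.subjects.index(subject)
    ti = spec.timepoints.index(timepoint)
    rng = _rng(spec, si, ti)
    scheme = BandScheme()
    n = int(round(spec.segment_s * spec.rate_hz))
    n_ch = len(spec.montage)
    regions = _region_index(tuple(spec.montage))
    # per-subject spatial gain pattern, fixed across time points like head
    # geometry; drawn independently of the per-time-point signal streams
    gain_rng = _rng(spec, si, 777)
    ch_gain = np.clip(1.0 + 0.2 * gain_rng.standard_normal(n_ch), 0.5, 1.5)
    # regionally shared activity (zero-lag): pink background + band oscillations
    shared_rms = spec.background_rms_uv * np.sqrt(spec.shared_frac)
    own_rms = spec.background_rms_uv * np.sqrt(1.0 - spec.shared_frac)
    region_sig = {}
    for r in np.unique(regions):
        sig = shared_rms * _pink_noise(rng, n, spec.pink_exponent)
        for name, lo, hi in scheme.bands:
            amp = spec.amps(name)[ti] * spec.osc_rms_uv.get(name, 0.0)
            # the oscillator is always drawn so that the random stream (and
            # hence every other component) is identical across amplitude
            # schedules — paired same-seed comparisons stay paired
            sig = sig + amp * _band_noise(rng, n, spec.rate_hz, lo, hi)
        region_sig[r] = sig
    data = np.empty((n_ch, n))
    for c in range(n_ch):
        x = ch_gain[c] * region_sig[regions[c]]
        x = x + own_rms * _pink_noise(rng, n, spec.pink_exponent)
        if spec.noise_sd > 0:
            x += spec.noise_sd * rng.standard_normal(n)
        if spec.pd_rate_hz > 0:
            x += _pd_train(rng, n, spec.rate_hz, spec.pd_rate_hz, spec.pd_amp_uv)
        data[c] = x
    # shared phase-lagged sources on coupled pairs
    for k, coup in enumerate(spec.coupling):
        gain = coup.gains[ti]
        if gain == 0:
            continue
        lo, hi = scheme.limits(coup.band)
        f_center = 0.5 * (lo + hi)
        src_rng = _rng(spec, si, ti, 1000 + k)
        src = COUPLING_RMS_UV * gain * _band_noise(src_rng, n, spec.rate_hz, lo, hi)
        delay_s = coup.phase_lag_rad / (2.0 * np.pi * f_center)
        ia = spec.montage.index(coup.channel_a)
        ib = spec.montage.index(coup.channel_b)
        data[ia] += src
        data[ib] += _fractional_delay(src, delay_s, spec.rate_hz)
    return RawRecording(
        subject=subject, timepoint=timepoint, montage=tuple(spec.montage),
        rate_hz=spec.rate_hz, data=data,
    )


def ground_truth_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Planted per-time-point band-amplitude and coupling-gain targets."""
    rows = []
    for ti, tp in enumerate(spec.timepoints):
        for name in BandScheme().names:
            rows.append(dict(kind="band_amp", timepoint=tp, band=name,
                             pair="", value=spec.amps(name)[ti]))
        for coup in spec.coupling:
            rows.append(dict(kind="coupling_gain", timepoint=tp, band=coup.band,
                             pair=f"{coup.channel_a}-{coup.channel_b}",
                             value=coup.gains[ti]))
    return pd.DataFrame(rows)


def simulate_cohort(spec: ScenarioSpec) -> SyntheticCohort:
    """All subjects x all 8 time points."""
    recs = {
        (subj, tp): simulate_recording(spec, subj, tp)
        for subj in spec.subjects
        for tp in spec.timepoints
    }
    return SyntheticCohort(spec=spec, recordings=recs,
                           ground_truth=ground_truth_table(spec))


# ---------------------------------------------------------------- ratings

RATING_CODES = {"W": 0, "S": 1, "I": 2}


def _categorize(score: float, t_low: float, t_high: float) -> int:
    if score < t_low:
        return 0  # worsened
    if score > t_high:
        return 2  # improved
    return 1  # no change


def simulate_ratings(
    latent_improvement: dict,
    rater_sd: float,
    thresholds: tuple = (-0.5, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Two noisy ordinal raters of a latent improvement score.

    Each rater observes latent + N(0, rater_sd) and assigns
    worsened/no-change/improved by thresholding.  Consensus is the raters'
    agreed category, adjudicated by the noise-free latent score on
    disagreement.
    """
    if not latent_improvement:
        raise ValueError("empty latent map")
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")
    if rater_sd < 0:
        raise ValueError("rater_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for (subject, tp), latent in latent_improvement.items():
        r1 = _categorize(latent + rater_sd * rng.standard_normal(), t_low, t_high)
        r2 = _categorize(latent + rater_sd * rng.standard_normal(), t_low, t_high)
        cons = r1 if r1 == r2 else _categorize(latent, t_low, t_high)
        rows.append(dict(subject=subject, timepoint=tp,
                         rater1=r1, rater2=r2, consensus=cons))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- presets

def _linear_gains(start: float, end: float) -> tuple:
    """pre-2h and baseline at `start`, then linear decline/rise to `end`
    over the six post-treatment time points."""
    post = np.linspace(start, end, 7)[1:]  # 1h..1d
    return (start, start, *post)


def load_preset(name: str) -> ScenarioSpec:
    """Load a shipped scenario preset (responder, non_responder,
    heterogeneous) or a YAML scenario file path."""
    try:
        text = (resources.files("qeegflow") / "presets" / f"{name}.yaml").read_text()
    except FileNotFoundError:
        with open(name) as fh:
            text = fh.read()
    return scenario_from_dict(yaml.safe_load(text))


def scenario_from_dict(cfg: dict) -> ScenarioSpec:
    cfg = dict(cfg)
    couplings = tuple(
        Coupling(c["channel_a"], c["channel_b"], c["band"],
                 float(c["phase_lag_rad"]), tuple(c["gains"]))
        for c in cfg.pop("coupling", [])
    )
    if "montage" in cfg:
        cfg["montage"] = tuple(cfg["montage"])
    if "timepoints" in cfg:
        cfg["timepoints"] = tuple(cfg["timepoints"])
    return ScenarioSpec(coupling=couplings, **cfg)
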