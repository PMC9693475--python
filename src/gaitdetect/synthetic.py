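"""Seeded synthetic shank angular-velocity generator with exact ground truth.

No public dataset accompanies the detection rules this package implements,
so validation is closed-loop: this module synthesises sagittal shank
gyroscope waveforms whose MSW/FS/FO landmark samples are known exactly by
construction, for level-ground walking (LGW), ramp ascent (RA) and ramp
descent (RD), in able-bodied-like (AB) and lower-limb-prosthesis-user-like
(LLPU) variants.

Each stride is a sum of compactly supported raised-cosine bumps laid out
swing-first:

    deep negative swing trough (MSW)  →  ascending zero crossing  →
    FS maximum  →  early-stance dip below zero (the spurious crossings the
    post-FS delay must skip)  →  low positive stance baseline with ripple
    maxima (stress for the FO maxima buffer)  →  FO maximum  →
    terminating descending zero crossing at the stride boundary.

Shape constants are engineering choices that reproduce the qualitative
morphology of shank angular velocity in walking; they are not claimed to
be physiological.  Ground-truth landmarks are located numerically on the
noiseless template with the same zero-crossing/extremum definitions the
detector uses, so truth is exact regardless of sample-grid alignment.
Stride-to-stride timing jitter warps each stride's whole timeline
uniformly (landmark fractions fixed); white Gaussian noise and linear
drift are added after concatenation.  All randomness flows through one
integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import EventLog, GaitEvent, GyroSeries
from .detection import local_extremum, zero_crossing

__all__ = [
    "SyntheticGaitSpec",
    "SyntheticRecording",
    "stride_template",
    "generate_walk",
    "preset",
    "PRESET_NAMES",
]

# stride layout, as fractions of the swing / stance portions -----------------
# bump supports are contiguous: flat-zero shelves between bumps would
# register spurious plateau maxima (tie-broken as events) and, under
# noise, grow tiny "last maxima" that steal the FO timestamp
# swing portion [0, 1-stance_fraction) of the stride:
_TROUGH_CENTER = 0.375  # of swing; support starts at the stride boundary
_TROUGH_HALFWIDTH = 0.375
_FS_CENTER = 0.90
_FS_HALFWIDTH = 0.15  # support touches the trough's
# stance portion [1-stance_fraction, 1):
_DIP_CENTER = 0.12  # of stance; early-stance negative dip
_DIP_HALFWIDTH = 0.07
_DIP_AMPL_FRAC = 0.15  # × fo_peak, negative
_BASELINE_CENTER = 0.45
_BASELINE_HALFWIDTH = 0.45
_BASELINE_AMPL_FRAC = 0.4  # × fo_peak; keeps mid-stance clearly above zero
_RIPPLE_CENTERS = (0.40, 0.55)
_RIPPLE_HALFWIDTH = 0.07
_FO_CENTER = 0.875  # support ends exactly at the stride boundary, so the
_FO_HALFWIDTH = 0.125  # push-off peak dives straight into the next swing

_LEAD_IN_S = 0.20  # event-free positive bump arming the initial ZC search
_LEAD_BUMP_S = 0.15
_LEAD_AMPL = 1.0  # rad/s

_MIN_STRIDE_S = 0.45  # > 2 × default 200 ms refractory
_DETECTION_THRESHOLD = 2.0  # rad/s; troughs must exceed this to be detectable


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Generative parameters for one synthetic walking trial.

    Amplitudes are rad/s; ``msw_amplitude`` is the trough magnitude (the
    waveform reaches ≈ −msw_amplitude) and must exceed the 2 rad/s
    detection threshold so a noiseless trial is fully detectable.
    ``side_overrides`` maps a side label to field replacements, which is
    how the LLPU presets encode prosthetic-side asymmetry.
    """

    sampling_rate: float = 100.0
    n_strides: int = 30
    cycle_duration_s: float = 1.04
    cycle_jitter_cv: float = 0.0
    stance_fraction: float = 0.60
    msw_amplitude: float = 5.0
    fs_peak: float = 2.5
    fo_peak: float = 2.0
    stance_ripple: float = 0.3
    noise_sd: float = 0.0
    drift: float = 0.0  # rad/s per s
    seed: int = 0
    sides: tuple[str, ...] = ("left", "right")
    side_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be at least 1")
        if not 0.3 <= self.stance_fraction <= 0.8:
            raise ValueError("stance_fraction outside plausible range [0.3, 0.8]")
        if self.msw_amplitude <= _DETECTION_THRESHOLD:
            raise ValueError(
                f"msw_amplitude {self.msw_amplitude} rad/s does not exceed the "
                f"{_DETECTION_THRESHOLD} rad/s detection threshold; the trough "
                "of a detectable stride must be deeper than the threshold"
            )
        if self.cycle_duration_s < _MIN_STRIDE_S:
            raise ValueError(f"cycle_duration_s must be ≥ {_MIN_STRIDE_S} s")

    def for_side(self, side: str) -> "SyntheticGaitSpec":
        over = self.side_overrides.get(side, {})
        return dataclasses.replace(self, **over) if over else self


@dataclass
class SyntheticRecording:
    """Per-side signals plus their exact ground-truth event logs."""

    series: dict[str, GyroSeries]
    truth: dict[str, EventLog]
    spec: SyntheticGaitSpec


def _bump(t: np.ndarray, center: float, halfwidth: float, ampl: float) -> np.ndarray:
    """Raised-cosine bump with compact support [center−hw, center+hw]."""
    u = (t - center) / halfwidth
    out = np.zeros_like(t)
    inside = np.abs(u) < 1.0
    out[inside] = 0.5 * ampl * (1.0 + np.cos(np.pi * u[inside]))
    return out


def _template_landmarks(wave: np.ndarray) -> dict[str, int]:
    """Locate MSW/FS/FO on a noiseless stride with the detector's own
    zero-crossing and extremum definitions."""
    n = len(wave)
    msw = int(np.argmin(wave))
    asc = next(
        i for i in range(msw + 1, n) if zero_crossing(wave[i - 1], wave[i]) == "ascending"
    )
    fs = next(
        i
        for i in range(max(asc, 1), n - 1)
        if local_extremum(wave[i - 1], wave[i], wave[i + 1]) == "maximum"
    )
    # the push-off bump runs to the template's end, so the descending ZC
    # terminating FO search is the stride boundary itself (the next stride
    # opens ≤ 0); intermediate crossings (the early-stance dip) are the
    # ones the post-FS delay exists to skip — FO is the stride's last max
    fo = max(
        i
        for i in range(fs + 1, n - 1)
        if local_extremum(wave[i - 1], wave[i], wave[i + 1]) == "maximum"
    )
    return {"MSW": msw, "FS": fs, "FO": fo}


def stride_template(
    spec: SyntheticGaitSpec, stride_duration_s: float
) -> tuple[np.ndarray, dict[str, int]]:
    """Build one noiseless stride and its exact event sample offsets.

    Returns the waveform (``round(duration × rate)`` samples) and a dict
    mapping event kind to its 0-based sample offset within the stride.
    """
    if stride_duration_s <= 0:
        raise ValueError("stride_duration_s must be positive")
    n = int(round(stride_duration_s * spec.sampling_rate))
    frac = np.arange(n) / n  # stride-relative time in [0, 1)
    swing = 1.0 - spec.stance_fraction
    sf = spec.stance_fraction

    wave = np.zeros(n)
    # swing
    wave += _bump(frac, _TROUGH_CENTER * swing, _TROUGH_HALFWIDTH * swing,
                  -spec.msw_amplitude)
    wave += _bump(frac, _FS_CENTER * swing, _FS_HALFWIDTH * swing, spec.fs_peak)
    # stance (u = position within the stance portion)
    u0 = swing
    wave += _bump(frac, u0 + _DIP_CENTER * sf, _DIP_HALFWIDTH * sf,
                  -_DIP_AMPL_FRAC * spec.fo_peak)
    wave += _bump(frac, u0 + _BASELINE_CENTER * sf, _BASELINE_HALFWIDTH * sf,
                  _BASELINE_AMPL_FRAC * spec.fo_peak)
    for c in _RIPPLE_CENTERS:
        wave += _bump(frac, u0 + c * sf, _RIPPLE_HALFWIDTH * sf, spec.stance_ripple)
    wave += _bump(frac, u0 + _FO_CENTER * sf, _FO_HALFWIDTH * sf, spec.fo_peak)

    landmarks = _template_landmarks(wave)
    return wave, landmarks


def _stride_durations(spec: SyntheticGaitSpec, rng: np.random.Generator) -> np.ndarray:
    mean = spec.cycle_duration_s
    sd = spec.cycle_jitter_cv * mean
    d = rng.normal(mean, sd, size=spec.n_strides) if sd > 0 else np.full(spec.n_strides, mean)
    d = np.clip(d, mean - 2.5 * sd, mean + 2.5 * sd) if sd > 0 else d
    return np.maximum(d, _MIN_STRIDE_S)


def _generate_side(
    spec: SyntheticGaitSpec, side: str, rng: np.random.Generator
) -> tuple[GyroSeries, EventLog]:
    fs_hz = spec.sampling_rate
    durations = _stride_durations(spec, rng)

    # event-free lead-in bump so the detector's initial descending-ZC
    # search is armed before the first stride's trough
    n_lead = int(round(_LEAD_IN_S * fs_hz))
    lead = np.zeros(n_lead)
    t_lead = np.arange(n_lead) / fs_hz
    lead += _bump(t_lead, _LEAD_BUMP_S / 2, _LEAD_BUMP_S / 2, _LEAD_AMPL)

    chunks = [lead]
    log = EventLog(side=side, sampling_rate=fs_hz)
    start = n_lead
    for dur in durations:
        wave, marks = stride_template(spec, float(dur))
        chunks.append(wave)
        for kind in ("MSW", "FS", "FO"):
            idx = start + marks[kind]
            log.append(GaitEvent(kind=kind, sample_index=idx, time_s=idx / fs_hz, side=side))
        start += len(wave)
    # short quiet tail so the final stride's push-off peak still meets a
    # terminating descending zero crossing
    chunks.append(np.zeros(int(round(0.1 * fs_hz))))

    signal = np.concatenate(chunks)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=len(signal))
    if spec.drift != 0.0:
        signal = signal + spec.drift * np.arange(len(signal)) / fs_hz
    log.sort()
    series = GyroSeries(
        samples=signal, sampling_rate=fs_hz, side=side,
        source={"generator": "synthetic", "seed": spec.seed, "side": side},
    )
    return series, log


def generate_walk(spec: SyntheticGaitSpec) -> SyntheticRecording:
    """Generate all sides of one trial; deterministic under ``spec.seed``.

    Each side draws from an independent child stream of the seed, so
    sides are uncorrelated but jointly reproducible.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.sides))
    series: dict[str, GyroSeries] = {}
    truth: dict[str, EventLog] = {}
    for side, child in zip(spec.sides, children):
        side_spec = spec.for_side(side)
        series[side], truth[side] = _generate_side(side_spec, side, np.random.default_rng(child))
    return SyntheticRecording(series=series, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# presets: three walking states × two gait styles
#
# Cycle durations and their stride-to-stride variability follow the group
# means (SD/mean as CV): AB 1.04 (LGW), 1.07 (RA), 1.00 (RD) s; LLPU 1.20,
# 1.28, 1.15 s.  Ramp variants scale peak amplitudes (ascent damps the
# swing dynamics, descent sharpens them); LLPU presets label the sides
# intact/prosthetic and reduce the prosthetic-side FO peak while adding
# stance ripple — a documented stress test, not a validated gait model.

_AB_BASE = dict(msw_amplitude=5.0, fs_peak=2.5, fo_peak=2.0, stance_ripple=0.3,
                noise_sd=0.05, n_strides=30)
_LLPU_SIDES = dict(
    sides=("intact", "prosthetic"),
    side_overrides={"prosthetic": {"fo_peak": 1.2, "stance_ripple": 0.45}},
)

_PRESETS: dict[str, dict] = {
    "AB_LGW": dict(_AB_BASE, cycle_duration_s=1.04, cycle_jitter_cv=0.058),
    "AB_RA": dict(_AB_BASE, cycle_duration_s=1.07, cycle_jitter_cv=0.121,
                  msw_amplitude=4.5, fs_peak=2.25, fo_peak=1.8),
    "AB_RD": dict(_AB_BASE, cycle_duration_s=1.00, cycle_jitter_cv=0.070,
                  msw_amplitude=5.5, fs_peak=2.75, fo_peak=2.2),
    "LLPU_LGW": {**_AB_BASE, **_LLPU_SIDES, "cycle_duration_s": 1.20,
                 "cycle_jitter_cv": 0.125},
    "LLPU_RA": {**_AB_BASE, **_LLPU_SIDES, "cycle_duration_s": 1.28,
                "cycle_jitter_cv": 0.133, "msw_amplitude": 4.5, "fs_peak": 2.25,
                "fo_peak": 1.8},
    "LLPU_RD": {**_AB_BASE, **_LLPU_SIDES, "cycle_duration_s": 1.15,
                "cycle_jitter_cv": 0.130, "msw_amplitude": 5.5, "fs_peak": 2.75,
                "fo_peak": 2.2},
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> SyntheticGaitSpec:
    """Return the documented parameter set for a named walking condition.

    ``overrides`` replace any spec field (commonly ``seed``, ``n_strides``
    or ``noise_sd``).
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose one of {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SyntheticGaitSpec(**params)
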