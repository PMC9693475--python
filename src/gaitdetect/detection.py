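"""Streaming rules-based gait event detection from shank angular velocity.

The detector is a small state machine driven, sample by sample, by the
sagittal-plane shank gyroscope signal (rad/s, swing trough negative).  Per
gait cycle it emits three events in fixed order:

1. **MSW** — after a descending zero crossing, the first local minimum
   deeper than −2 rad/s.  The fixed threshold is justified by mid-swing
   angular velocity always exceeding ~2 rad/s (~115 deg/s) in walking,
   which makes it portable across participants, unlike amplitude
   thresholds on FS/FO themselves.
2. **FS** — the first local maximum after the ascending zero crossing that
   follows MSW.
3. **FO** — after a fixed 200 ms post-FS delay (which skips the spurious
   zero crossings of early stance), every local maximum is buffered; when
   the next descending zero crossing arrives, the *last* buffered maximum
   is emitted as FO.  No amplitude threshold is involved, so FO detection
   is robust to the signal-magnitude changes seen on ramps and across
   prosthetic componentry.

Local extrema are decided on a 3-sample window (i−1, i, i+1), i.e. 30 ms
at 100 Hz, so MSW and FS are emitted at most one sample after they occur
(two with the median filter's lookahead) — well under a 50 ms real-time
latency budget.  FO is intrinsically retrospective: it is emitted at its
terminating descending zero crossing with the timestamp of the buffered
maximum.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .core import EventLog, GaitEvent, GyroSeries
from .filtering import Median3Filter, SignalQualityError

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "Phase",
    "GaitEventDetector",
    "ContractViolationError",
    "zero_crossing",
    "local_extremum",
    "detect",
    "suggest_invert_sign",
]


class ContractViolationError(RuntimeError):
    """Samples arrived out of order or the pipeline was misused."""


@dataclass(frozen=True)
class DetectorConfig:
    """All tunable constants of the detector.

    Parameters
    ----------
    sampling_rate:
        Signal sampling rate in Hz.  The extremum window is fixed at 3
        samples, so its time span scales inversely with this rate.
    msw_threshold:
        Magnitude (rad/s) the swing trough must exceed to count as MSW.
    refractory_ms:
        Post-FS delay during which FO search is suppressed; converted to
        samples by rounding so non-100 Hz rates work.
    invert_sign:
        Multiply the input by −1 (opposite sensor mounting).
    apply_median_filter:
        Pre-filter with the streaming window-3 median (default on).
    strict_fo:
        Literal reading of the FO rule, requiring more than one buffered
        maximum before the terminating descending zero crossing; default
        accepts a single maximum.
    """

    sampling_rate: float = 100.0
    msw_threshold: float = 2.0
    refractory_ms: float = 200.0
    window_samples: int = 3
    invert_sign: bool = False
    apply_median_filter: bool = True
    strict_fo: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.msw_threshold <= 0:
            raise ValueError("msw_threshold must be positive")
        if self.window_samples != 3:
            raise ValueError("the extremum window is fixed at 3 samples")
        if self.refractory_samples < 1:
            raise ValueError("refractory must round to at least 1 sample")

    @property
    def refractory_samples(self) -> int:
        return int(round(self.refractory_ms * self.sampling_rate / 1000.0))


class Phase(enum.Enum):
    SEEK_DESC_ZC = enum.auto()
    SEEK_MSW = enum.auto()
    SEEK_ASC_ZC = enum.auto()
    SEEK_FS = enum.auto()
    REFRACTORY = enum.auto()
    COLLECT_MAXIMA = enum.auto()


def zero_crossing(prev: float, curr: float) -> str:
    """Classify the transition between two consecutive samples.

    Descending = positive to non-positive, ascending = negative to
    non-negative (a sample exactly at zero completes a crossing).
    """
    if prev > 0 and curr <= 0:
        return "descending"
    if prev < 0 and curr >= 0:
        return "ascending"
    return "none"


def local_extremum(w0: float, w1: float, w2: float) -> str:
    """Classify the centre of a 3-sample window.

    Tie-break is strict against the past and non-strict against the
    future, so a plateau reports its first sample and a flat signal
    reports nothing.
    """
    if w1 < w0 and w1 <= w2:
        return "minimum"
    if w1 > w0 and w1 >= w2:
        return "maximum"
    return "none"


@dataclass
class DetectorState:
    phase: Phase = Phase.SEEK_DESC_ZC
    window: list[float] = field(default_factory=list)  # last ≤3 stream samples
    stream_index: int = -1  # index of newest stream sample seen
    maxima_buffer: list[tuple[int, float]] = field(default_factory=list)
    refractory_remaining: int = 0
    msw_seen: bool = False
    fs_seen: bool = False


class GaitEventDetector:
    """Streaming detector: push raw samples, collect events as they fire.

    The optional median filter runs inside the pipeline, so ``process``
    takes *raw* samples and events carry ``emitted_at_index`` in raw-input
    coordinates for latency auditing.
    """

    def __init__(self, config: DetectorConfig | None = None, side: str = "") -> None:
        self.config = config or DetectorConfig()
        self.side = side
        self.reset()

    def reset(self) -> None:
        """Return to a fresh state (phase SEEK_DESC_ZC, buffers cleared)."""
        self.state = DetectorState()
        self._filter = Median3Filter() if self.config.apply_median_filter else None
        self._raw_index = -1

    # -- streaming API ----------------------------------------------------

    def process(self, x: float, index: int | None = None) -> list[GaitEvent]:
        """Feed one raw sample; return the events decided at this sample."""
        if not math.isfinite(x):
            raise SignalQualityError(f"non-finite sample: {x!r}")
        expected = self._raw_index + 1
        if index is not None and index != expected:
            raise ContractViolationError(
                f"sample index {index} out of order (expected {expected})"
            )
        self._raw_index = expected
        if self.config.invert_sign:
            x = -x
        if self._filter is None:
            return self._step(float(x))
        y = self._filter.push(float(x))
        return [] if y is None else self._step(y)

    def finish(self) -> list[GaitEvent]:
        """Flush the filter lookahead at end of stream."""
        if self._filter is None:
            return []
        y = self._filter.flush()
        return [] if y is None else self._step(y)

    # -- state machine ----------------------------------------------------

    def _emit(self, kind: str, sample_index: int) -> GaitEvent:
        return GaitEvent(
            kind=kind,
            sample_index=sample_index,
            time_s=sample_index / self.config.sampling_rate,
            side=self.side,
            emitted_at_index=max(self._raw_index, sample_index),
        )

    def _step(self, v: float) -> list[GaitEvent]:
        """Advance the state machine by one (filtered) stream sample."""
        st = self.state
        st.stream_index += 1
        j = st.stream_index
        st.window.append(v)
        if len(st.window) > 3:
            st.window.pop(0)

        zc = "none"
        ext = "none"
        if len(st.window) >= 2:
            zc = zero_crossing(st.window[-2], st.window[-1])
        if len(st.window) == 3:
            ext = local_extremum(*st.window)
        prev_val = st.window[-2] if len(st.window) >= 2 else float("nan")
        events: list[GaitEvent] = []

        if st.phase is Phase.REFRACTORY:
            # all zero crossings and extrema during the delay are ignored:
            # the delay exists to skip early-stance signal oscillations
            st.refractory_remaining -= 1
            if st.refractory_remaining > 0:
                return events
            st.phase = Phase.COLLECT_MAXIMA

        if st.phase is Phase.SEEK_DESC_ZC:
            if zc == "descending":
                st.phase = Phase.SEEK_MSW
                st.msw_seen = st.fs_seen = False
            return events

        if st.phase is Phase.SEEK_MSW:
            if ext == "minimum" and prev_val < -self.config.msw_threshold:
                events.append(self._emit("MSW", j - 1))
                st.msw_seen = True
                st.phase = Phase.SEEK_ASC_ZC
                if zc == "ascending":  # trough and crossing in the same step
                    st.phase = Phase.SEEK_FS
            elif zc == "ascending":
                st.phase = Phase.SEEK_DESC_ZC  # swing ended without a deep trough
            return events

        if st.phase is Phase.SEEK_ASC_ZC:
            if zc == "ascending":
                st.phase = Phase.SEEK_FS
            return events

        if st.phase is Phase.SEEK_FS:
            if ext == "maximum":
                events.append(self._emit("FS", j - 1))
                st.fs_seen = True
                st.refractory_remaining = self.config.refractory_samples
                st.maxima_buffer.clear()
                st.phase = Phase.REFRACTORY
            elif zc == "descending":
                # signal fell back below zero before any maximum: abandon
                # the cycle; this crossing doubles as the pre-MSW one
                st.phase = Phase.SEEK_MSW
                st.msw_seen = st.fs_seen = False
            return events

        # Phase.COLLECT_MAXIMA
        if ext == "maximum":
            st.maxima_buffer.append((j - 1, prev_val))
        if zc == "descending":
            needed = 2 if self.config.strict_fo else 1
            if len(st.maxima_buffer) >= needed:
                events.append(self._emit("FO", st.maxima_buffer[-1][0]))
            st.maxima_buffer.clear()
            # this crossing doubles as the descending ZC that precedes MSW
            st.phase = Phase.SEEK_MSW
            st.msw_seen = st.fs_seen = False
        return events


def detect(series: GyroSeries, config: DetectorConfig | None = None) -> EventLog:
    """Run the detector over a whole recording.

    Equivalent, sample for sample, to streaming the series through
    :class:`GaitEventDetector` and flushing — batch mode exists purely for
    convenience and is bit-identical to streaming by construction.
    """
    config = config or DetectorConfig(sampling_rate=series.sampling_rate)
    if config.sampling_rate != series.sampling_rate:
        raise ValueError(
            "config sampling_rate does not match the series "
            f"({config.sampling_rate} != {series.sampling_rate})"
        )
    det = GaitEventDetector(config, side=series.side)
    log = EventLog(side=series.side, sampling_rate=series.sampling_rate)
    if len(series) == 0:
        import warnings

        warnings.warn("empty series: returning empty event log", stacklevel=2)
        return log
    for x in series.samples:
        log.extend(det.process(x))
    log.extend(det.finish())
    return log


def suggest_invert_sign(calibration: np.ndarray) -> bool:
    """Auto-polarity helper: flip if the global extremum of a calibration
    window is positive (the swing trough should dominate and be negative).
    Opt-in; never applied automatically."""
    calibration = np.asarray(calibration, dtype=float)
    if calibration.size == 0:
        return False
    return bool(abs(calibration.max()) > abs(calibration.min()))
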