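"""Core containers shared across the package.

A recording is a single-channel shank sagittal angular-velocity series
(:class:`GyroSeries`) per leg.  Detection and reference annotations are
lists of :class:`GaitEvent` wrapped in an :class:`EventLog`.  Event kinds:

``MSW``
    mid-swing — the deep negative trough of shank angular velocity during
    leg swing; the gatekeeper for the other two events.
``FS``
    foot strike (initial contact) — first local maximum after the
    post-swing ascending zero crossing.
``FO``
    foot off (toe off) — last local maximum before the descending zero
    crossing that precedes swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["EVENT_KINDS", "GyroSeries", "GaitEvent", "EventLog"]

EVENT_KINDS = ("MSW", "FS", "FO")


@dataclass
class GyroSeries:
    """Uniformly sampled single-channel angular velocity signal in rad/s."""

    samples: np.ndarray
    sampling_rate: float
    side: str = ""
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("GyroSeries expects a 1-D signal")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class GaitEvent:
    """One detected or reference gait event.

    ``sample_index`` is where the event *occurred* (0-based);
    ``emitted_at_index`` is the sample at which the streaming detector
    *decided* — the gap between the two is the detection latency and is
    audited in tests.  Reference events carry ``emitted_at_index ==
    sample_index``.
    """

    kind: str
    sample_index: int
    time_s: float
    side: str = ""
    emitted_at_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.emitted_at_index is None:
            object.__setattr__(self, "emitted_at_index", self.sample_index)
        if self.emitted_at_index < self.sample_index:
            raise ValueError("event cannot be emitted before it occurs")


@dataclass
class EventLog:
    """Ordered list of gait events for one side of one recording."""

    side: str
    sampling_rate: float
    events: list[GaitEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GaitEvent]:
        return iter(self.events)

    def append(self, event: GaitEvent) -> None:
        self.events.append(event)

    def of_kind(self, kind: str) -> list[GaitEvent]:
        return [e for e in self.events if e.kind == kind]

    def times_of(self, kind: str) -> np.ndarray:
        return np.array([e.time_s for e in self.of_kind(kind)], dtype=float)

    def extend(self, events: Iterable[GaitEvent]) -> None:
        self.events.extend(events)

    def sort(self) -> None:
        self.events.sort(key=lambda e: (e.sample_index, EVENT_KINDS.index(e.kind)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "side": [e.side or self.side for e in self.events],
                "event": [e.kind for e in self.events],
                "sample_index": [e.sample_index for e in self.events],
                "time_s": [round(e.time_s, 6) for e in self.events],
                "emitted_at_index": [e.emitted_at_index for e in self.events],
            }
        )

    def validate_cycles(self) -> None:
        """Check per-kind strictly increasing indices and cyclic MSW<FS<FO order."""
        for kind in EVENT_KINDS:
            idx = [e.sample_index for e in self.of_kind(kind)]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"{kind} sample indices not strictly increasing")
        order = [e.kind for e in sorted(self.events, key=lambda e: e.sample_index)]
        expect = {"MSW": "FS", "FS": "FO", "FO": "MSW"}
        for a, b in zip(order, order[1:]):
            if expect[a] != b:
                raise ValueError(f"cycle order violated: {a} followed by {b}")
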