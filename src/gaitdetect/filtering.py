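"""Streaming third-order (window-of-3) median filter.

The detector pre-filters the raw shank angular-velocity stream with a
nonlinear median filter: each output sample is the median of the 3-sample
window centred on it.  A median filter removes single-sample impulse noise
without the phase shift a causal Butterworth filter would introduce, which
is why it is the only filtering stage before event detection.

Streaming semantics: the window centred on sample ``i`` needs sample
``i + 1``, so the filter carries exactly one sample of lookahead latency.
Edges are handled by replicating the first/last sample, so the output
sequence has the same length as the input once :meth:`Median3Filter.flush`
has been called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter as _nd_median_filter

__all__ = ["Median3Filter", "FilterState", "SignalQualityError", "median3_offline"]


class SignalQualityError(ValueError):
    """Raised when a non-finite sample (NaN/inf) enters the pipeline."""


@dataclass
class FilterState:
    """Internal state of the streaming filter: at most the last 3 raw samples."""

    buffer: list[float] = field(default_factory=list)
    emitted_count: int = 0


def _median3(a: float, b: float, c: float) -> float:
    # median of three without sorting allocations
    return max(min(a, b), min(max(a, b), c))


class Median3Filter:
    """Streaming window-3 median filter with replicated edges.

    >>> f = Median3Filter()
    >>> [y for x in [1.0, 9.0, 1.0] if (y := f.push(x)) is not None] + [f.flush()]
    [1.0, 1.0, 1.0]
    """

    def __init__(self) -> None:
        self._state = FilterState()

    @property
    def state(self) -> FilterState:
        return self._state

    def push(self, x: float) -> float | None:
        """Feed one raw sample; return the next filtered sample, or ``None``.

        The first push returns ``None`` (one sample of lookahead); every
        subsequent push returns the filtered value for the previous input.
        """
        if not math.isfinite(x):
            raise SignalQualityError(f"non-finite sample: {x!r}")
        buf = self._state.buffer
        buf.append(float(x))
        if len(buf) == 1:
            return None
        if len(buf) == 2:
            # output for sample 0: window (x0, x0, x1) by edge replication
            out = _median3(buf[0], buf[0], buf[1])
        else:
            out = _median3(buf[0], buf[1], buf[2])
            buf.pop(0)
        self._state.emitted_count += 1
        return out

    def flush(self) -> float | None:
        """Emit the final pending output (last-sample replication), if any."""
        buf = self._state.buffer
        if not buf:
            return None
        if len(buf) == 1:
            out = buf[0]
        else:
            out = _median3(buf[-2], buf[-1], buf[-1])
        self._state = FilterState(emitted_count=self._state.emitted_count + 1)
        return out

    def reset(self) -> None:
        self._state = FilterState()


def median3_offline(x: np.ndarray) -> np.ndarray:
    """Whole-array window-3 median with replicated edges.

    Bit-identical to running :class:`Median3Filter` over the array and
    flushing; used for batch detection.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    if not np.all(np.isfinite(x)):
        raise SignalQualityError("signal contains non-finite samples")
    return _nd_median_filter(x, size=3, mode="nearest")
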