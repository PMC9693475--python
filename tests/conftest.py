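import numpy as np
import pytest

import gaitdetect as gd


@pytest.fixture(scope="session")
def clean_lgw_recording():
    """One-sided noiseless level-ground walk, 30 strides."""
    spec = gd.preset("AB_LGW", seed=0, noise_sd=0.0, sides=("left",))
    return gd.generate_walk(spec)


@pytest.fixture(scope="session")
def clean_lgw_detection(clean_lgw_recording):
    series = clean_lgw_recording.series["left"]
    return gd.detect(series)


def run_stream(filt, values):
    """Drive a streaming median filter over a sequence, including flush."""
    out = []
    for v in values:
        y = filt.push(v)
        if y is not None:
            out.append(y)
    y = filt.flush()
    if y is not None:
        out.append(y)
    return out


def brute_median3(values):
    """Independent sliding-window-3 median with replicated edges."""
    values = list(values)
    padded = [values[0]] + values + [values[-1]]
    return [sorted(padded[i : i + 3])[1] for i in range(len(values))]


def stream_detect(series, config):
    """Sample-by-sample detection, the long way around."""
    det = gd.GaitEventDetector(config, side=series.side)
    events = []
    for x in series.samples:
        events.extend(det.process(x))
    events.extend(det.finish())
    log = gd.EventLog(side=series.side, sampling_rate=series.sampling_rate)
    log.extend(events)
    return log


def oracle_match(ref_times, det_times, tol):
    """Exhaustive matching oracle: maximise pairs, then minimise total |Δt|.

    Returns (n_pairs, total_cost).  Exponential — only for tiny inputs.
    """
    best = (-1, 0.0)

    def rec(i, used, pairs, cost):
        nonlocal best
        if i == len(ref_times):
            if (pairs, -cost) > (best[0], -best[1]):
                best = (pairs, cost)
            return
        rec(i + 1, used, pairs, cost)
        for j, t in enumerate(det_times):
            if j not in used and abs(ref_times[i] - t) <= tol:
                rec(i + 1, used | {j}, pairs + 1, cost + abs(ref_times[i] - t))

    rec(0, frozenset(), 0, 0.0)
    return best


def make_log(times_by_kind, sampling_rate=1000.0, side="x"):
    """Build an EventLog from {kind: [times in seconds]}."""
    log = gd.EventLog(side=side, sampling_rate=sampling_rate)
    for kind, times in times_by_kind.items():
        for t in times:
            idx = int(round(t * sampling_rate))
            log.append(gd.GaitEvent(kind=kind, sample_index=idx, time_s=t, side=side))
    log.sort()
    return log
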