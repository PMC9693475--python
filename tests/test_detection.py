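import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitdetect as gd
from gaitdetect import DetectorConfig, GaitEventDetector, GyroSeries, detect
from gaitdetect.detection import ContractViolationError, local_extremum, zero_crossing
from gaitdetect.filtering import SignalQualityError

from conftest import stream_detect


@pytest.mark.parametrize(
    "prev, curr, expected",
    [
        (0.5, -0.2, "descending"),
        (-0.3, 0.4, "ascending"),
        (0.2, 0.1, "none"),
        (0.2, 0.0, "descending"),  # exact zero completes a crossing
        (-0.2, 0.0, "ascending"),
        (0.0, -0.1, "none"),  # flat start is not a crossing
    ],
)
def test_zero_crossing(prev, curr, expected):
    assert zero_crossing(prev, curr) == expected


@pytest.mark.parametrize(
    "window, expected",
    [
        ((1, -3, 1), "minimum"),
        ((0, 2, 1), "maximum"),
        ((1, 1, 1), "none"),
        ((1, 2, 2), "maximum"),  # plateau reports its first sample
        ((2, 1, 1), "minimum"),
        ((2, 2, 1), "none"),  # strict against the past
    ],
)
def test_local_extremum(window, expected):
    assert local_extremum(*window) == expected


def test_config_validation():
    assert DetectorConfig(sampling_rate=100).refractory_samples == 20
    assert DetectorConfig(sampling_rate=60).refractory_samples == 12
    with pytest.raises(ValueError):
        DetectorConfig(msw_threshold=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(window_samples=5)
    with pytest.raises(ValueError):
        DetectorConfig(sampling_rate=-1)


def test_single_clean_stride_yields_one_event_of_each_kind():
    spec = gd.preset("AB_LGW", seed=0, noise_sd=0.0, n_strides=1, sides=("left",))
    rec = gd.generate_walk(spec)
    log = detect(rec.series["left"])
    truth = rec.truth["left"]
    for kind in ("MSW", "FS", "FO"):
        assert len(log.of_kind(kind)) == 1
        assert abs(log.of_kind(kind)[0].sample_index - truth.of_kind(kind)[0].sample_index) <= 1


def test_thirty_clean_strides_in_strict_cyclic_order(clean_lgw_detection):
    log = clean_lgw_detection
    for kind in ("MSW", "FS", "FO"):
        assert len(log.of_kind(kind)) == 30
    log.validate_cycles()  # raises on any MSW<FS<FO ordering violation


def test_shallow_trough_produces_no_events():
    # deepest trough −1.5 rad/s never crosses the −2 rad/s MSW gate
    spec = gd.preset("AB_LGW", seed=1, noise_sd=0.0, n_strides=5, sides=("left",))
    rec = gd.generate_walk(spec)
    series = rec.series["left"]
    scaled = GyroSeries(series.samples * (1.5 / 5.0), series.sampling_rate, "left")
    assert len(detect(scaled)) == 0


def test_streaming_and_batch_are_identical(clean_lgw_recording):
    series = clean_lgw_recording.series["left"]
    cfg = DetectorConfig(sampling_rate=series.sampling_rate)
    assert stream_detect(series, cfg).to_dataframe().equals(detect(series, cfg).to_dataframe())


def test_invert_sign_recovers_events_from_flipped_signal(clean_lgw_recording):
    series = clean_lgw_recording.series["left"]
    flipped = GyroSeries(-series.samples, series.sampling_rate, "left")
    a = detect(series, DetectorConfig())
    b = detect(flipped, DetectorConfig(invert_sign=True))
    assert a.to_dataframe().equals(b.to_dataframe())


def test_two_sided_recording_detected_with_independent_state():
    rec = gd.generate_walk(gd.preset("LLPU_LGW", seed=3, noise_sd=0.0))
    assert set(rec.series) == {"intact", "prosthetic"}
    for side, series in rec.series.items():
        log = detect(series)
        truth = rec.truth[side]
        for kind in ("MSW", "FS", "FO"):
            assert len(log.of_kind(kind)) == len(truth.of_kind(kind))


def test_reset_restores_fresh_behaviour(clean_lgw_recording):
    series = clean_lgw_recording.series["left"]
    cfg = DetectorConfig()
    det = GaitEventDetector(cfg, side="left")
    first = [e for x in series.samples for e in det.process(x)] + det.finish()
    det.reset()
    assert det.state.refractory_remaining == 0
    assert det.state.phase.name == "SEEK_DESC_ZC"
    second = [e for x in series.samples for e in det.process(x)] + det.finish()
    assert first == second


def test_out_of_order_sample_index_rejected():
    det = GaitEventDetector(DetectorConfig())
    det.process(0.1, index=0)
    with pytest.raises(ContractViolationError):
        det.process(0.2, index=2)


def test_non_finite_sample_rejected():
    det = GaitEventDetector(DetectorConfig())
    with pytest.raises(SignalQualityError):
        det.process(float("nan"))


def test_empty_series_warns_and_returns_empty_log():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        log = detect(GyroSeries(np.array([]), 100.0, "left"))
    assert len(log) == 0
    assert any("empty" in str(x.message) for x in w)


def test_latency_bound_for_msw_and_fs(clean_lgw_detection):
    # ≤ 1 sample from the extremum window, +1 from the median filter
    for e in clean_lgw_detection.events:
        if e.kind in ("MSW", "FS"):
            assert e.emitted_at_index - e.sample_index <= 2


def test_fs_never_emitted_without_msw_and_fo_never_without_fs(clean_lgw_detection):
    seen = {"MSW": -1, "FS": -1}
    for e in sorted(clean_lgw_detection.events, key=lambda e: e.sample_index):
        if e.kind == "FS":
            assert seen["MSW"] > -1
        if e.kind == "FO":
            assert seen["FS"] > -1
        if e.kind in seen:
            seen[e.kind] = e.sample_index


def test_raising_threshold_never_adds_msw_events():
    rec = gd.generate_walk(gd.preset("AB_LGW", seed=5, n_strides=20, sides=("left",)))
    counts = [
        len(detect(rec.series["left"], DetectorConfig(msw_threshold=t)).of_kind("MSW"))
        for t in (1.0, 2.0, 3.0, 4.0, 4.9, 5.5)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[-1] == 0  # threshold above the trough amplitude


def test_strict_fo_requires_more_than_one_maximum():
    # a stance with a single maximum: strict mode must withhold FO
    fs_hz = 100.0
    t = np.arange(0, 3.0, 1 / fs_hz)
    sig = np.zeros_like(t)
    # arm → trough → FS peak → one stance max → descending end
    def bump(c, w, a):
        u = (t - c) / w
        m = np.abs(u) < 1
        out = np.zeros_like(t)
        out[m] = 0.5 * a * (1 + np.cos(np.pi * u[m]))
        return out

    sig += bump(0.1, 0.08, 1.0)  # arming descending ZC
    sig += bump(0.5, 0.25, -4.0)  # trough, support touching the FS bump's
    sig += bump(0.9, 0.15, 2.0)  # FS
    sig += bump(1.8, 0.4, 1.5)  # single stance maximum, then descends to 0
    series = GyroSeries(sig, fs_hz, "x")
    relaxed = detect(series, DetectorConfig())
    strict = detect(series, DetectorConfig(strict_fo=True))
    assert len(relaxed.of_kind("FO")) == 1
    assert len(strict.of_kind("FO")) == 0


def test_auto_polarity_helper():
    rec = gd.generate_walk(gd.preset("AB_LGW", seed=2, n_strides=3, sides=("left",)))
    x = rec.series["left"].samples
    assert gd.suggest_invert_sign(-x) is True
    assert gd.suggest_invert_sign(x) is False


@given(st.integers(0, 10_000))
@settings(derandomize=True, max_examples=25)
def test_detection_is_deterministic_across_runs(seed):
    spec = gd.preset("AB_LGW", seed=seed, n_strides=3, sides=("left",))
    s1 = gd.generate_walk(spec).series["left"]
    s2 = gd.generate_walk(spec).series["left"]
    assert np.array_equal(s1.samples, s2.samples)
    assert detect(s1).to_dataframe().equals(detect(s2).to_dataframe())
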