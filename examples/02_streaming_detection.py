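"""Stream samples one at a time, as a wearable device would.

The detector is a state machine fed sample-by-sample; events come out as
soon as they are decided.  MSW and FS are decided at most 2 samples
(20 ms at 100 Hz) after they occur — one sample from the 3-sample
extremum window and one from the median filter's lookahead — while FO is
intrinsically retrospective (its timestamp is the last stance maximum,
confirmed at the descending zero crossing that starts the next swing).
"""

import gaitdetect as gd

recording = gd.generate_walk(gd.preset("AB_LGW", seed=1, n_strides=5, sides=("left",)))
series = recording.series["left"]

detector = gd.GaitEventDetector(gd.DetectorConfig(sampling_rate=100.0), side="left")
for i, x in enumerate(series.samples):
    for event in detector.process(x):
        lag_ms = (event.emitted_at_index - event.sample_index) * 10.0
        print(f"sample {i:4d}: {event.kind:3s} at t={event.time_s:5.2f} s "
              f"(decision lag {lag_ms:.0f} ms)")
for event in detector.finish():
    print(f"flush: {event.kind} at t={event.time_s:.2f} s")
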