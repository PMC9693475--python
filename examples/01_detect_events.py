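"""Detect gait events in a synthetic level-ground walk.

Builds a 10-stride able-bodied walking signal (shank sagittal angular
velocity, 100 Hz), runs the rules-based detector and prints the event
counts and the first detected cycle.  One gait cycle should yield exactly
one mid-swing (MSW), one foot strike (FS) and one foot off (FO), in that
order.
"""

import gaitdetect as gd

spec = gd.preset("AB_LGW", seed=0, n_strides=10, sides=("left",))
recording = gd.generate_walk(spec)
series = recording.series["left"]

events = gd.detect(series, gd.DetectorConfig(sampling_rate=series.sampling_rate))

print(f"signal: {len(series)} samples at {series.sampling_rate:.0f} Hz "
      f"({series.duration_s:.1f} s)")
for kind in ("MSW", "FS", "FO"):
    print(f"  {kind}: {len(events.of_kind(kind))} events")

print("\nfirst detected cycle (times in seconds):")
for e in sorted(events.events, key=lambda e: e.sample_index)[:3]:
    print(f"  {e.kind:3s} at t={e.time_s:6.2f}  (decided at sample "
          f"{e.emitted_at_index}, i.e. {e.emitted_at_index - e.sample_index} "
          "samples after the event)")
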