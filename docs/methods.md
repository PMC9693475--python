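# Methods

## Detection model

The detector consumes a single uniformly sampled channel: the sagittal
(medio-lateral axis) angular velocity of the shank, in rad/s, with the
sign convention that the swing-phase trough is negative (`invert_sign`
flips opposite-mounted sensors; `suggest_invert_sign` can propose the
flip from a calibration window but is never applied automatically).

Two primitives drive everything, evaluated per incoming sample:

- **zero crossing** between consecutive samples: descending iff
  `prev > 0 and curr ≤ 0`, ascending iff `prev < 0 and curr ≥ 0`. A
  sample exactly at zero completes a crossing, so flat touches still
  trigger.
- **local extremum** on the 3-sample window (i−1, i, i+1): minimum iff
  `w[i] < w[i−1] and w[i] ≤ w[i+1]`, maximum mirrored. The tie-break is
  strict against the past and non-strict against the future, so a plateau
  reports its first sample and a constant signal reports nothing.

The state machine cycles through six phases:

```
SEEK_DESC_ZC → SEEK_MSW → SEEK_ASC_ZC → SEEK_FS → REFRACTORY → COLLECT_MAXIMA
      ↑____________↑__________________________________________________|
```

- `SEEK_MSW`: a local minimum below −`msw_threshold` (default 2.0 rad/s)
  emits **MSW**; an ascending crossing without one abandons the cycle.
- `SEEK_FS`: the first local maximum after the ascending crossing emits
  **FS** and starts the refractory delay; a descending crossing first
  abandons the cycle (and doubles as the next cycle's arming crossing).
- `REFRACTORY` (default 200 ms, converted to samples by rounding so
  non-100 Hz rates work): *all* crossings and extrema are ignored. The
  delay exists precisely because early stance oscillates around zero
  after FS; stance time in walking (~60% of a 1.0–1.3 s cycle) leaves a
  wide margin before the true FO.
- `COLLECT_MAXIMA`: every local maximum is buffered; the next descending
  crossing emits **FO** with the timestamp of the *last* buffered maximum
  (one suffices by default; `strict_fo=True` demands more than one and
  otherwise withholds FO), clears the buffer and re-enters `SEEK_MSW`
  directly — that crossing is also the arming crossing of the next cycle.
  A descending crossing with an empty buffer yields no FO for that cycle.

Latency contract: MSW/FS events carry `emitted_at_index`, the input
sample at which the decision fired; the gap to `sample_index` is ≤ 1
sample from the extremum lookahead plus ≤ 1 from the filter, i.e. ≤ 20 ms
at 100 Hz — comfortably under the ~50 ms budget real-time prosthetic
control and biofeedback need. FO is retrospective by definition; it is
emitted at its terminating descending crossing.

## Median pre-filter

A streaming window-3 median (edge samples replicated, so output length
equals input length and event indices are preserved) runs before the
state machine by default (`apply_median_filter=False` disables it for
validating raw signals). It removes single-sample impulses without the
phase shift a causal low-pass would add; its only cost is one sample of
lookahead. The offline path uses `scipy.ndimage.median_filter(size=3,
mode="nearest")`, which is bit-identical to the streaming filter.

## Synthetic gait generator

Ground-truth-bearing input is synthesised rather than recorded: each
stride is a sum of compactly supported raised-cosine bumps laid out
swing-first — trough (MSW), FS peak, early-stance dip below zero (the
spurious crossings the refractory must skip), a low positive stance
baseline with two ripple maxima (stress for the FO buffer), and a
push-off (FO) peak whose support ends exactly at the stride boundary so
the signal dives straight into the next swing. Bump supports are
contiguous: flat-zero shelves between bumps would create plateau
"maxima" under the tie-break rule and, under noise, spurious late maxima
that steal the FO timestamp — neither occurs in real signals. A short
event-free positive lead-in bump arms the detector's initial descending
crossing, and a 0.1 s quiet tail terminates the final stride's FO search.

Ground-truth landmarks are located *numerically* on the noiseless stride
template with the same crossing/extremum definitions the detector uses,
so truth is exact on any sample grid. Timing jitter warps whole strides
uniformly (landmark fractions fixed): durations are drawn from a normal
with the preset's CV, truncated at ±2.5 SD and floored at 0.45 s (twice
the default refractory). White Gaussian noise and linear drift are added
after concatenation; each side of a recording draws from an independent
child stream of the single integer seed.

Preset conditions (cycle duration mean and stride-to-stride CV follow
group-level values for able-bodied ≈ 1.04 s and prosthesis users ≈ 1.20 s
on level ground, with ramp variants 1.07/1.00 s and 1.28/1.15 s; stance
fraction 0.60):

| preset | cycle (s) | CV | amplitude scaling |
|---|---|---|---|
| AB_LGW / LLPU_LGW | 1.04 / 1.20 | 0.058 / 0.125 | trough −5.0, FS 2.5, FO 2.0 rad/s |
| AB_RA / LLPU_RA | 1.07 / 1.28 | 0.121 / 0.133 | ×0.9 (ascent damps dynamics) |
| AB_RD / LLPU_RD | 1.00 / 1.15 | 0.070 / 0.130 | ×1.1 |

LLPU presets label sides `intact`/`prosthetic` and give the prosthetic
side a reduced push-off peak (1.2 rad/s) with extra stance ripple (0.45
rad/s) — a documented stress test, not a validated gait model. Default
additive noise is 0.05 rad/s: MEMS gyroscope noise plus soft-tissue
artifact is well below 0.1 rad/s after median filtering. Shape constants
(bump centres/widths, stance baseline 0.4 × FO peak, dip 0.15 × FO peak)
are engineering choices reproducing the qualitative morphology of shank
angular velocity; they are not claimed to be physiological.

What passing closed-loop tests show — and what they do not: with exact,
noise-free waveforms every preset is recovered perfectly (sensitivity
100%, |error| ≤ 1–2 samples), which validates the *rule logic and its
implementation*, not performance on real gait. Real signals add soft-
tissue artifact, sensor misalignment, pathological waveform shapes and
reference-system error, none of which the generator emulates beyond
additive noise, amplitude asymmetry and timing jitter.

## Evaluation

Matching is a globally optimal one-to-one assignment (maximum pairs,
then minimum total |Δt|) among candidate pairs within a tolerance,
solved by `scipy.optimize.linear_sum_assignment` with dummy padding. The
default tolerance is half the median reference gait cycle — in periodic
gait this makes assignment unambiguous; tighter tolerances are advisable
when false positives abound. Unmatched reference events are false
negatives; unmatched detections are counted as false positives but
precision is deliberately not a headline metric. The temporal-error sign
is detected − reference (negative = detector leads). Quantiles use
linear interpolation between order statistics (numpy's default), so
reported IQRs are reproducible. Gait cycle durations are successive
differences of reference FS times; %-of-cycle errors are normalised by
the trial's mean reference cycle.

## Numerical and design choices

- 0-based sample indices everywhere; `time_s = index / sampling_rate`;
  files carry 6-decimal times; deg/s inputs are converted by π/180 at load.
- Degenerate inputs: empty series → empty log with a warning; non-finite
  samples → `SignalQualityError`; out-of-order streaming indices →
  `ContractViolationError`; fewer than 2 FS events → no cycles, warning;
  zero reference events → sensitivity is an error, not 0%.
- The refractory is specified in ms and rounded to samples (≥ 1), so the
  detector runs at other sampling rates; note the 3-sample window then
  spans a different time, which changes the effective latency.
- `run_demo` wires the six presets through detection and evaluation with
  per-condition seeds derived from one master seed; its outputs
  (summary table, overlay plots) are deterministic under that seed.
- Problem sizes in the shipped validation suite (30 strides per side for
  closed-loop runs, 100 recordings for the streaming/batch equivalence
  sweep, 1000 sequences for the filter oracle, 20 seeds per noise level)
  are chosen to make the whole suite run in seconds while keeping the
  Monte-Carlo comparisons stable.

## Known limitations

- The MSW threshold, while portable across the populations studied in
  the literature, may not transfer to gaits whose swing trough stays
  above 2 rad/s (severe shuffling gait, very slow walking); it is
  configurable per trial.
- A fixed 200 ms refractory assumes stance ≳ 400 ms; very fast walking
  or running would need an adaptive delay.
- If walking stops mid-swing the machine waits in `SEEK_ASC_ZC`/`SEEK_FS`
  until the signal resolves; no timeout is applied beyond the crossing
  rules.
- Walking-state classification (level vs ramp), stairs, running,
  turning and multi-IMU fusion are out of scope.
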