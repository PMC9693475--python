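"""Validation metrics: event matching, sensitivity, temporal error.

Detected events are paired one-to-one with reference events of the same
kind by a globally optimal assignment (minimum total |Δt| among pairings
within a time tolerance).  From the pairing:

* sensitivity (%) = 100 · TP / (TP + FN) — the fraction of reference
  events the detector recovered;
* temporal error (ms) = t_detected − t_reference, so a negative error
  means the detector *leads* the reference and a positive one that it
  lags;
* error as % of gait cycle = error / cycle duration × 100, with cycle
  durations taken as successive differences of reference FS times.

Because temporal errors in this setting are typically non-normal,
summaries report median and interquartile range (linear-interpolation
quantile convention).  False positives are counted and reported, but
precision is deliberately not a headline metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import EventLog, GaitEvent

__all__ = [
    "MatchResult",
    "match_events",
    "sensitivity",
    "temporal_error_ms",
    "gait_cycle_durations",
    "error_pct_of_cycle",
    "summarize",
    "evaluate_log",
    "default_tolerance_ms",
    "EmptyReferenceError",
]


class EmptyReferenceError(ValueError):
    """The reference log has no events of the requested kind."""


@dataclass
class MatchResult:
    """One-to-one pairing of detected vs reference events of one kind."""

    kind: str
    pairs: list[tuple[GaitEvent, GaitEvent]]  # (reference, detected)
    false_negatives: list[GaitEvent]
    false_positives: list[GaitEvent]
    tolerance_ms: float
    labels: dict = field(default_factory=dict)  # e.g. side / walking state

    @property
    def n_true_positives(self) -> int:
        return len(self.pairs)

    def errors_ms(self) -> np.ndarray:
        return np.array([temporal_error_ms(p) for p in self.pairs], dtype=float)

    def check_conservation(self, n_reference: int, n_detected: int) -> None:
        assert len(self.pairs) + len(self.false_negatives) == n_reference
        assert len(self.pairs) + len(self.false_positives) == n_detected


def default_tolerance_ms(reference: EventLog) -> float:
    """Half the median reference gait cycle — unambiguous in periodic gait."""
    cycles = gait_cycle_durations(reference)
    if len(cycles) == 0:
        return 500.0
    return float(np.median(cycles) * 1000.0 / 2.0)


def match_events(
    detected: EventLog,
    reference: EventLog,
    kind: str,
    tolerance_ms: float | None = None,
) -> MatchResult:
    """Optimal one-to-one pairing of events of ``kind`` within tolerance.

    Maximises the number of within-tolerance pairs, and among such
    pairings minimises the total |Δt|; solved as a rectangular assignment
    with dummy padding.
    """
    ref = reference.of_kind(kind)
    det = detected.of_kind(kind)
    if not ref:
        raise EmptyReferenceError(f"reference log has no {kind} events")
    if tolerance_ms is None:
        tolerance_ms = default_tolerance_ms(reference)
    tol_s = tolerance_ms / 1000.0

    if not det:
        return MatchResult(kind, [], list(ref), [], tolerance_ms)

    t_ref = np.array([e.time_s for e in ref])
    t_det = np.array([e.time_s for e in det])
    dt = np.abs(t_ref[:, None] - t_det[None, :])

    # pad to square: a dummy match costs more than any feasible real pair,
    # and a forbidden (out-of-tolerance) pair costs more than two dummies,
    # so cardinality is maximised before total |Δt| is minimised
    dummy = tol_s + 1.0
    n = len(ref) + len(det)
    cost = np.full((n, n), dummy)
    block = np.where(dt <= tol_s, dt, 10.0 * n * dummy)
    cost[: len(ref), : len(det)] = block
    rows, cols = linear_sum_assignment(cost)

    pairs: list[tuple[GaitEvent, GaitEvent]] = []
    matched_ref: set[int] = set()
    matched_det: set[int] = set()
    for r, c in zip(rows, cols):
        if r < len(ref) and c < len(det) and dt[r, c] <= tol_s:
            pairs.append((ref[r], det[c]))
            matched_ref.add(r)
            matched_det.add(c)
    fn = [e for i, e in enumerate(ref) if i not in matched_ref]
    fp = [e for i, e in enumerate(det) if i not in matched_det]
    result = MatchResult(kind, pairs, fn, fp, tolerance_ms)
    result.check_conservation(len(ref), len(det))
    return result


def sensitivity(m: MatchResult) -> float:
    """Percent of reference events recovered: 100 · TP / (TP + FN)."""
    n_ref = m.n_true_positives + len(m.false_negatives)
    if n_ref == 0:
        raise EmptyReferenceError("sensitivity undefined with zero reference events")
    return 100.0 * m.n_true_positives / n_ref


def temporal_error_ms(pair: tuple[GaitEvent, GaitEvent]) -> float:
    """Signed error in ms: detected − reference (negative = detector leads)."""
    ref, det = pair
    return (det.time_s - ref.time_s) * 1000.0


def gait_cycle_durations(reference: EventLog) -> np.ndarray:
    """Successive differences of reference FS times, in seconds."""
    t_fs = reference.times_of("FS")
    if len(t_fs) < 2:
        import warnings

        warnings.warn("fewer than 2 FS events: no gait cycles", stacklevel=2)
        return np.array([])
    return np.diff(np.sort(t_fs))


def error_pct_of_cycle(error_ms: float, cycle_ms: float) -> float:
    """Temporal error as a percentage of the gait cycle duration."""
    if cycle_ms <= 0:
        raise ValueError("cycle duration must be positive")
    return error_ms / cycle_ms * 100.0


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation between order statistics."""
    if len(x) == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(q1), float(med), float(q3)


def evaluate_log(
    detected: EventLog,
    reference: EventLog,
    tolerance_ms: float | None = None,
    kinds: tuple[str, ...] = ("MSW", "FS", "FO"),
    labels: dict | None = None,
) -> list[MatchResult]:
    """Match every event kind present in the reference log."""
    out = []
    for kind in kinds:
        if not reference.of_kind(kind):
            continue
        m = match_events(detected, reference, kind, tolerance_ms)
        m.labels = dict(labels or {})
        out.append(m)
    return out


def summarize(matches: list[MatchResult], group_by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Aggregate matches into one row per (event kind × label group).

    Columns: counts, sensitivity (%), temporal-error median and quartiles
    in ms and in % of the gait cycle (each pair normalised by the mean
    reference cycle attached via ``labels['cycle_s']`` when present, else
    by the per-match value), and the mean ± SD cycle duration.
    """
    if not matches:
        raise ValueError("no matches to summarise")
    group_cols = ["event", *group_by]
    groups: dict[tuple, dict] = {}
    for m in matches:
        key = (m.kind, *(m.labels.get(k) for k in group_by))
        g = groups.setdefault(
            key, {"tp": 0, "fn": 0, "fp": 0, "err": [], "pct": [], "cycles": []}
        )
        g["tp"] += m.n_true_positives
        g["fn"] += len(m.false_negatives)
        g["fp"] += len(m.false_positives)
        errs = m.errors_ms()
        g["err"].extend(errs.tolist())
        cyc = float(m.labels.get("cycle_s", float("nan")))
        if np.isfinite(cyc) and cyc > 0:
            g["cycles"].append(cyc)
            g["pct"].extend((errs / (cyc * 1000.0) * 100.0).tolist())

    out_rows = []
    for key, g in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        q1, med, q3 = _quartiles(np.array(g["err"]))
        p1, pmed, p3 = _quartiles(np.array(g["pct"]))
        n_ref = g["tp"] + g["fn"]
        cycles = np.array(g["cycles"])
        out_rows.append({
            **dict(zip(group_cols, key)),
            "n_reference": n_ref,
            "n_detected": g["tp"] + g["fp"],
            "true_positives": g["tp"],
            "false_negatives": g["fn"],
            "false_positives": g["fp"],
            "sensitivity_pct": 100.0 * g["tp"] / n_ref if n_ref else float("nan"),
            "error_ms_median": med, "error_ms_q1": q1, "error_ms_q3": q3,
            "error_pct_median": pmed, "error_pct_q1": p1, "error_pct_q3": p3,
            "cycle_s_mean": float(cycles.mean()) if len(cycles) else float("nan"),
            "cycle_s_sd": float(cycles.std(ddof=1)) if len(cycles) > 1 else float("nan"),
        })
    return pd.DataFrame(out_rows)
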