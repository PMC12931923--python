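"""Gaze preprocessing, event detection, trial compliance and error summaries.

Detection thresholds follow standard video-oculography practice for this
paradigm: fixations are runs of gaze within 2.5 deg of a target lasting at
least 150 ms; saccades are movements whose velocity exceeds 150 deg/s for
more than 10 ms and whose net displacement from the initial fixation exceeds
9.2 deg (the radius of the perifoveal field).  Each stimulus epoch is the
first second after its onset.  Blinks (pupil zero, or abrupt pupil change
around a closure) are masked before any event statistics.

Compliance is judged per condition:

* no saccade        -- fixation at the cross during both item epochs, and no
                       large saccade in any epoch;
* saccade after 1   -- fixations on both items, a saccade between item-1
                       offset and item-2 onset, none after wheel onset;
* saccade after 2   -- fixations on both items, a saccade to the wheel in the
                       wheel epoch;
* two saccades      -- both required saccades present.

Non-compliant trials are excluded from the behavioural summaries, which
report mean location error (deg), mean colour error (radians in [0, pi]) per
condition x item, and the saccade cost: mean two-saccade location error minus
mean error when the saccade followed the *other* (unprobed) item.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .simulate import GazeTrace
from .task import Condition, TrialDesign

__all__ = [
    "FixationEvent", "SaccadeEvent", "BehaviouralSummary",
    "remove_blinks", "epoch_trace", "detect_fixations", "detect_saccades",
    "classify_compliance", "behavioural_errors", "colour_error", "NoDataError",
    "FIXATION_RADIUS_DEG", "FIXATION_MIN_MS", "SACCADE_VELOCITY_DEG_S",
    "SACCADE_MIN_MS", "SACCADE_MIN_AMPLITUDE_DEG", "EPOCH_MS",
]

FIXATION_RADIUS_DEG = 2.5
FIXATION_MIN_MS = 150.0
SACCADE_VELOCITY_DEG_S = 150.0
SACCADE_MIN_MS = 10.0
SACCADE_MIN_AMPLITUDE_DEG = 9.2
EPOCH_MS = 1000.0


class NoDataError(ValueError):
    """An epoch contains no valid gaze samples."""


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    duration_ms: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    duration_ms: float
    amplitude_deg: float
    peak_velocity: float


@dataclass
class BehaviouralSummary:
    """Condition x item mean errors plus the saccade-cost statistic."""

    table: pd.DataFrame          # columns: condition, item, n, loc_err, col_err
    saccade_cost: float
    missing_cells: list[tuple[str, int]]


def remove_blinks(trace: GazeTrace, rate_percentile: float = 99.5,
                  window_ms: float = 50.0) -> GazeTrace:
    """Mask blink samples: zero pupil, plus abrupt pupil change nearby.

    Samples whose pupil rate-of-change exceeds the given percentile of the
    trace's absolute rate *and* lie within ``window_ms`` of a zero-pupil
    sample are treated as pre/post-blink artefacts.
    """
    t, pupil = trace.time_ms, trace.pupil
    valid = trace.valid & (pupil > 0)
    closed = pupil <= 0
    if closed.any() and len(t) > 2:
        rate = np.abs(np.gradient(pupil, t))
        thresh = np.percentile(rate[np.isfinite(rate)], rate_percentile)
        closed_times = t[closed]
        near = np.min(np.abs(t[:, None] - closed_times[None, :]), axis=1) \
            if len(closed_times) < 5000 else _nearest_gap(t, closed)
        valid &= ~((rate > thresh) & (near <= window_ms))
    return GazeTrace(time_ms=t, x=trace.x, y=trace.y, pupil=pupil, valid=valid)


def _nearest_gap(t: np.ndarray, closed: np.ndarray) -> np.ndarray:
    """Distance (ms) from each sample to the nearest closed sample."""
    idx = np.flatnonzero(closed)
    pos = np.searchsorted(t[idx], t)
    left = np.where(pos > 0, np.abs(t - t[idx][np.clip(pos - 1, 0, None)]),
                    np.inf)
    right = np.where(pos < len(idx), np.abs(t[idx][np.clip(pos, None, len(idx) - 1)] - t),
                     np.inf)
    return np.minimum(left, right)


def epoch_trace(trace: GazeTrace, start_ms: float,
                duration_ms: float = EPOCH_MS) -> GazeTrace:
    """Slice a trace to [start, start + duration)."""
    sel = (trace.time_ms >= start_ms) & (trace.time_ms < start_ms + duration_ms)
    return GazeTrace(time_ms=trace.time_ms[sel], x=trace.x[sel],
                     y=trace.y[sel], pupil=trace.pupil[sel],
                     valid=trace.valid[sel])


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_fixations(trace: GazeTrace, target) -> list[FixationEvent]:
    """Maximal runs of valid samples within 2.5 deg of `target`, >= 150 ms."""
    if not np.any(trace.valid):
        raise NoDataError("epoch contains no valid gaze samples")
    d = np.hypot(trace.x - target[0], trace.y - target[1])
    near = trace.valid & (d <= FIXATION_RADIUS_DEG)
    out = []
    for a, b in _runs(near):
        dur = trace.time_ms[b - 1] - trace.time_ms[a]
        if dur >= FIXATION_MIN_MS:
            out.append(FixationEvent(
                onset_ms=float(trace.time_ms[a]), duration_ms=float(dur),
                centroid=(float(trace.x[a:b].mean()),
                          float(trace.y[a:b].mean()))))
    return out


_VELOCITY_SPAN = 5  # central-difference half-width, samples


def _velocity(trace: GazeTrace) -> np.ndarray:
    """Gaze speed (deg/s): 5-sample median smoothing, then central
    differences over a +/-5-sample span.

    Adjacent-sample differentiation at 1000 Hz turns sub-degree jitter into
    hundreds of deg/s of velocity noise; the wider central difference keeps
    noise an order of magnitude below the saccade threshold while a 30 ms
    saccade still reads at its true mean velocity.
    """
    n = len(trace.time_ms)
    if n < 3:
        return np.zeros(n)
    xs = medfilt(trace.x, kernel_size=5)
    ys = medfilt(trace.y, kernel_size=5)
    ts = trace.time_ms / 1000.0
    k = min(_VELOCITY_SPAN, (n - 1) // 2)
    lo = np.clip(np.arange(n) - k, 0, n - 1)
    hi = np.clip(np.arange(n) + k, 0, n - 1)
    dt = ts[hi] - ts[lo]
    vx = (xs[hi] - xs[lo]) / dt
    vy = (ys[hi] - ys[lo]) / dt
    return np.hypot(vx, vy)


SACCADE_MERGE_GAP_MS = 20.0
_AMPLITUDE_WINDOW_MS = 15.0


def _merge_runs(runs, times, gap_ms):
    """Merge threshold-crossing runs separated by less than `gap_ms`."""
    merged = []
    for a, b in runs:
        if merged and times[a] - times[merged[-1][1] - 1] <= gap_ms:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def _robust_position(trace, sel):
    if not np.any(sel):
        return None
    return (float(np.median(trace.x[sel])), float(np.median(trace.y[sel])))


def detect_saccades(trace: GazeTrace) -> list[SaccadeEvent]:
    """High-velocity events with sufficient duration and net displacement.

    Candidate runs of super-threshold velocity are merged across gaps shorter
    than 20 ms (noise can momentarily dip the velocity estimate mid-saccade),
    and amplitude is the displacement between median gaze positions in short
    windows flanking the run, which is robust to sample-level jitter.
    """
    if len(trace.time_ms) < 3:
        return []
    t = trace.time_ms
    speed = _velocity(trace)
    fast = trace.valid & (speed > SACCADE_VELOCITY_DEG_S)
    events = []
    for a, b in _merge_runs(_runs(fast), t, SACCADE_MERGE_GAP_MS):
        dur = t[b - 1] - t[a]
        if dur <= SACCADE_MIN_MS:
            continue
        before = _robust_position(
            trace, (t >= t[a] - _AMPLITUDE_WINDOW_MS) & (t < t[a]))
        after = _robust_position(
            trace, (t > t[b - 1]) & (t <= t[b - 1] + _AMPLITUDE_WINDOW_MS))
        p0 = before if before is not None else (trace.x[a], trace.y[a])
        p1 = after if after is not None else (trace.x[b - 1], trace.y[b - 1])
        amp = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        if amp <= SACCADE_MIN_AMPLITUDE_DEG:
            continue
        events.append(SaccadeEvent(onset_ms=float(t[a]),
                                   duration_ms=float(dur), amplitude_deg=amp,
                                   peak_velocity=float(speed[a:b].max())))
    return events


def _has_fixation(trace, start_ms, target) -> bool:
    return len(detect_fixations(epoch_trace(trace, start_ms), target)) > 0


def _saccade_in(trace, start_ms, stop_ms) -> bool:
    ep = GazeTrace(*[arr[(trace.time_ms >= start_ms) & (trace.time_ms < stop_ms)]
                     for arr in (trace.time_ms, trace.x, trace.y, trace.pupil,
                                 trace.valid)])
    return len(detect_saccades(ep)) > 0


def classify_compliance(trace: GazeTrace, trial: TrialDesign,
                        ) -> tuple[bool | None, str]:
    """Pass/fail (or indeterminate) with the first violated rule as reason.

    Returns ``(True, "ok")``, ``(False, reason)`` or ``(None,
    "indeterminate: ...")`` when blink-masked data leave an epoch empty.
    """
    tl = trial.timeline
    ms = lambda s: s * 1000.0
    cond = trial.condition
    try:
        if not _has_fixation(trace, ms(tl.t_item1_on), trial.fixation1):
            return (False, "no fixation on item 1")
        if not _has_fixation(trace, ms(tl.t_item2_on), trial.fixation2):
            return (False, "no fixation on item 2")
    except NoDataError as err:
        return (None, f"indeterminate: {err}")

    isi_sacc = _saccade_in(trace, ms(tl.t_item1_off), ms(tl.t_item2_on))
    wheel_sacc = _saccade_in(trace, ms(tl.t_wheel_on),
                             ms(tl.t_wheel_on) + EPOCH_MS)
    if cond is Condition.NO_SACCADE:
        for name, t0 in (("item 1", tl.t_item1_on), ("item 2", tl.t_item2_on),
                         ("wheel", tl.t_wheel_on)):
            if _saccade_in(trace, ms(t0), ms(t0) + EPOCH_MS):
                return (False, f"saccade during {name} epoch")
        if isi_sacc:
            return (False, "saccade during inter-stimulus interval")
        return (True, "ok")
    if cond is Condition.SAC_AFTER_1:
        if not isi_sacc:
            return (False, "missing saccade between items")
        if wheel_sacc:
            return (False, "saccade after wheel onset")
        return (True, "ok")
    if cond is Condition.SAC_AFTER_2:
        if not wheel_sacc:
            return (False, "missing saccade to wheel")
        return (True, "ok")
    if not isi_sacc:
        return (False, "missing saccade between items")
    if not wheel_sacc:
        return (False, "missing saccade to wheel")
    return (True, "ok")


def colour_error(a, b) -> np.ndarray:
    """Shortest arc between two colour-wheel angles, in [0, pi]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float),
               2.0 * np.pi)
    return np.where(d > np.pi, 2.0 * np.pi - d, d)


def behavioural_errors(designs: list[TrialDesign], responses: list[dict],
                       compliance: list[bool] | None = None,
                       ) -> BehaviouralSummary:
    """Condition x item mean errors over compliant trials, plus saccade cost.

    ``responses`` rows need ``resp_x``, ``resp_y`` and ``resp_col``.  The
    saccade cost contrasts the two-saccade condition against trials where the
    single saccade followed the item that was *not* probed (matching
    retention timings but removing the saccade right after the probed item).
    """
    if compliance is None:
        compliance = [True] * len(designs)
    rows = []
    for d, r, ok in zip(designs, responses, compliance):
        if not ok:
            continue
        target = d.item_location(d.probed_item)
        colour = d.item1_colour if d.probed_item == 1 else d.item2_colour
        rows.append({
            "condition": d.condition.value,
            "item": d.probed_item,
            "loc_err": float(np.hypot(r["resp_x"] - target[0],
                                      r["resp_y"] - target[1])),
            "col_err": float(colour_error(r["resp_col"], colour)),
        })
    df = pd.DataFrame(rows, columns=["condition", "item", "loc_err", "col_err"])
    cells = (df.groupby(["condition", "item"])
               .agg(n=("loc_err", "size"), loc_err=("loc_err", "mean"),
                    col_err=("col_err", "mean"))
               .reset_index())
    missing = [(c.value, i) for c in Condition for i in (1, 2)
               if not ((cells.condition == c.value) & (cells.item == i)).any()]

    two = df[df.condition == Condition.TWO_SACCADES.value]
    other = df[((df.condition == Condition.SAC_AFTER_2.value) & (df.item == 1))
               | ((df.condition == Condition.SAC_AFTER_1.value) & (df.item == 2))]
    if len(two) and len(other):
        cost = float(two.loc_err.mean() - other.loc_err.mean())
    else:
        cost = float("nan")
    return BehaviouralSummary(table=cells, saccade_cost=cost,
                              missing_cells=missing)
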