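"""LOCUS trial-design synthesis.

The LOCUS (Location and Colour Updating across Saccades) task presents two
coloured squares in sequence, each inside a 9.8 deg frame centred on a fixation
cross, then probes recall of one item's colour and location on a colour wheel.
Saccade demands are manipulated by moving the second frame and/or the wheel to
a new screen location, giving four conditions: no saccade, a saccade after
item 1, a saccade after item 2, and two saccades.

This module generates trial designs that respect the task geometry: frame
centres on a 3 x 5 screen grid, stimuli at least 3.82 deg from their fixation
cross, and instructed saccades of at least 8.5 deg.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "Condition",
    "Timeline",
    "TrialDesign",
    "FRAME_SIZE",
    "MIN_STIM_DIST",
    "MIN_SACCADE_AMPLITUDE",
    "GRID_SHAPE",
    "GRID_SPACING",
    "frame_grid",
    "place_stimulus",
    "generate_session",
    "saccade_times",
    "condition_timing",
    "InvalidDesignError",
    "MissingEventError",
]

#: Side length of the square stimulus frame (degrees of visual angle).
FRAME_SIZE = 9.8
#: Minimum distance between a stimulus square and its fixation cross (deg).
MIN_STIM_DIST = 3.82
#: Minimum amplitude of an instructed saccade (deg).
MIN_SACCADE_AMPLITUDE = 8.5
#: Screen layout: rows x columns of possible frame locations.
GRID_SHAPE = (3, 5)
#: Centre-to-centre spacing of adjacent frames (frame size + 0.3 deg gap).
GRID_SPACING = FRAME_SIZE + 0.3

# Default event timings (seconds), relative to item-1 onset.
ITEM_DURATION = 1.0
INTER_STIMULUS_INTERVAL = 0.5
WHEEL_DELAY = 0.5          # wheel onset after item-2 offset
COLOUR_LATENCY = 2.0       # colour response after wheel onset
LOCATION_LATENCY = 3.0     # location response after wheel onset
SACCADE_LATENCY = 0.2      # saccade execution after frame change / wheel onset


class InvalidDesignError(ValueError):
    """A requested session or trial violates the task design rules."""


class MissingEventError(ValueError):
    """A trial timeline lacks an event required for timing computations."""


class Condition(str, enum.Enum):
    NO_SACCADE = "NO_SACCADE"
    SAC_AFTER_1 = "SAC_AFTER_1"
    SAC_AFTER_2 = "SAC_AFTER_2"
    TWO_SACCADES = "TWO_SACCADES"

    @property
    def frame_moves(self) -> bool:
        """Second frame appears at a new location (saccade between items)."""
        return self in (Condition.SAC_AFTER_1, Condition.TWO_SACCADES)

    @property
    def wheel_moves(self) -> bool:
        """Colour wheel appears away from the second fixation."""
        return self in (Condition.SAC_AFTER_2, Condition.TWO_SACCADES)

    @property
    def requires_saccade(self) -> bool:
        return self is not Condition.NO_SACCADE


@dataclass(frozen=True)
class Timeline:
    """Ordered event timestamps for one trial, in seconds from item-1 onset."""

    t_item1_on: float
    t_item1_off: float
    t_item2_on: float
    t_item2_off: float
    t_wheel_on: float
    t_col_resp: float
    t_loc_resp: float

    def __post_init__(self) -> None:
        vals = [getattr(self, f.name) for f in fields(self)]
        if any(v is None or not math.isfinite(v) for v in vals):
            raise MissingEventError("timeline has missing or non-finite events")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidDesignError("timeline must be strictly increasing")


@dataclass(frozen=True)
class TrialDesign:
    """One LOCUS trial: condition, geometry and event timeline.

    All coordinates are degrees of visual angle with the origin at screen
    centre, x rightward and y upward.
    """

    trial_id: int
    condition: Condition
    fixation1: tuple[float, float]
    fixation2: tuple[float, float]
    wheel_location: tuple[float, float]
    item1_location: tuple[float, float]
    item2_location: tuple[float, float]
    item1_colour: float
    item2_colour: float
    wheel_rotation: float
    probed_item: int
    timeline: Timeline

    def fixation_of_item(self, item: int) -> tuple[float, float]:
        """Fixation cross at which the given item (1 or 2) was viewed."""
        if item == 1:
            return self.fixation1
        if item == 2:
            return self.fixation2
        raise ValueError(f"item must be 1 or 2, got {item!r}")

    def item_location(self, item: int) -> tuple[float, float]:
        return self.item1_location if item == 1 else self.item2_location


def frame_grid() -> np.ndarray:
    """All possible frame centres, shape (15, 2), centred on the screen."""
    rows, cols = GRID_SHAPE
    ys = (np.arange(rows) - (rows - 1) / 2) * GRID_SPACING
    xs = (np.arange(cols) - (cols - 1) / 2) * GRID_SPACING
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def place_stimulus(frame_centre, rng: np.random.Generator) -> tuple[float, float]:
    """Draw a stimulus location uniformly inside its frame, away from fixation.

    The admissible region is the 9.8 x 9.8 deg frame minus a 3.82 deg disc
    around the central fixation cross; sampling is by rejection, which is
    exact for a uniform target density.
    """
    cx, cy = float(frame_centre[0]), float(frame_centre[1])
    half = FRAME_SIZE / 2.0
    while True:
        dx, dy = rng.uniform(-half, half, size=2)
        if math.hypot(dx, dy) >= MIN_STIM_DIST:
            return (cx + dx, cy + dy)


def _default_timeline() -> Timeline:
    t1_off = ITEM_DURATION
    t2_on = t1_off + INTER_STIMULUS_INTERVAL
    t2_off = t2_on + ITEM_DURATION
    wheel = t2_off + WHEEL_DELAY
    return Timeline(
        t_item1_on=0.0,
        t_item1_off=t1_off,
        t_item2_on=t2_on,
        t_item2_off=t2_off,
        t_wheel_on=wheel,
        t_col_resp=wheel + COLOUR_LATENCY,
        t_loc_resp=wheel + LOCATION_LATENCY,
    )


def generate_session(seed: int, n_trials: int = 160) -> list[TrialDesign]:
    """Generate a balanced LOCUS session.

    Exactly ``n_trials / 4`` trials per saccade condition, in an order
    randomised by ``seed``.  Per-trial randomness is drawn from seed-sequence
    children so that trial ``k`` is reproducible in isolation.
    """
    if n_trials % 4 != 0:
        raise InvalidDesignError(
            f"n_trials must be divisible by 4, got {n_trials}"
        )
    ss = np.random.SeedSequence(seed)
    root = np.random.default_rng(ss.spawn(1)[0])
    conditions = [c for c in Condition for _ in range(n_trials // 4)]
    conditions = [conditions[i] for i in root.permutation(n_trials)]
    child_seeds = ss.spawn(n_trials)

    grid = frame_grid()
    timeline = _default_timeline()
    trials = []
    for k, (cond, child) in enumerate(zip(conditions, child_seeds)):
        rng = np.random.default_rng(child)
        fix1 = tuple(grid[rng.integers(len(grid))])
        fix2 = tuple(grid[_pick_away(grid, fix1, rng)]) if cond.frame_moves else fix1
        wheel = tuple(grid[_pick_away(grid, fix2, rng)]) if cond.wheel_moves else fix2
        trials.append(
            TrialDesign(
                trial_id=k,
                condition=cond,
                fixation1=fix1,
                fixation2=fix2,
                wheel_location=wheel,
                item1_location=place_stimulus(fix1, rng),
                item2_location=place_stimulus(fix2, rng),
                item1_colour=float(rng.uniform(0.0, 2.0 * np.pi)),
                item2_colour=float(rng.uniform(0.0, 2.0 * np.pi)),
                wheel_rotation=float(rng.uniform(0.0, 2.0 * np.pi)),
                probed_item=int(rng.integers(1, 3)),
                timeline=timeline,
            )
        )
    return trials


def _pick_away(grid: np.ndarray, origin, rng: np.random.Generator) -> int:
    """Index of a grid cell at least the minimum saccade amplitude away."""
    d = np.hypot(grid[:, 0] - origin[0], grid[:, 1] - origin[1])
    candidates = np.flatnonzero(d >= MIN_SACCADE_AMPLITUDE)
    return int(candidates[rng.integers(len(candidates))])


def saccade_times(trial: TrialDesign, latency: float = SACCADE_LATENCY) -> list[float]:
    """Instructed-saccade execution times for one trial, in trial seconds.

    Saccades are modelled as occurring one latency after the event that cues
    them: the frame change at item-1 offset, and the wheel onset.
    """
    tl = trial.timeline
    out = []
    if trial.fixation2 != trial.fixation1:
        out.append(tl.t_item1_off + latency)
    if trial.wheel_location != trial.fixation2:
        out.append(tl.t_wheel_on + latency)
    return out


def condition_timing(
    trial: TrialDesign, item: int, latency: float = SACCADE_LATENCY
) -> tuple[float, float, float, int]:
    """Timing variables (tau, t, T, n) for one item of one trial.

    tau  -- time from the item's disappearance to the location response;
    t    -- time since the first saccade executed after the item was viewed
            (0 if none);
    T    -- time since the second such saccade (0 if none);
    n    -- number of saccades executed since the item's fixation.

    These drive the variance schedules of the generative models: retinotopic
    memories decay over tau, fixation memories over t, and saccade-vector
    memories accumulate error per saccade and decay over t + T.
    """
    tl = trial.timeline
    offset = tl.t_item1_off if item == 1 else tl.t_item2_off
    if item not in (1, 2):
        raise ValueError(f"item must be 1 or 2, got {item!r}")
    resp = tl.t_loc_resp
    later = sorted(s for s in saccade_times(trial, latency) if s >= offset)
    tau = resp - offset
    t = resp - later[0] if len(later) >= 1 else 0.0
    T = resp - later[1] if len(later) >= 2 else 0.0
    return (tau, t, T, len(later))
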