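"""Forward simulation: responses from the generative models, and gaze traces.

Responses are sampled exactly from the model densities used for fitting: the
probed (or, with probability w, the distracting) item's coordinates are
perturbed by Gaussian noise whose variance follows the model's schedule at
that trial's timing variables, then mapped back to screen coordinates.
Colour reports are plumbing only (target colour plus wrapped Gaussian noise);
the models describe location recall.

Gaze traces emulate a 1000 Hz eye tracker: piecewise-constant fixations with
optional Gaussian jitter and brief linear saccade ramps.  Non-compliant traces
inject a condition-appropriate rule violation so the compliance classifier can
be exercised in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models as _m
from .task import TrialDesign, condition_timing, generate_session, saccade_times

__all__ = ["GenerativeConfig", "simulate_responses", "simulate_session_data",
           "simulate_gaze", "GazeTrace", "reference_params"]

#: Natural-scale parameter values used as the canonical simulation condition:
#: spatial recall errors of one to a few degrees, angular errors around ten
#: degrees of arc, a modest per-saccade updating cost and a 25% chance of
#: confusing the two memoranda.  Units: deg^2 for spatial variances, rad^2
#: for angular ones, per-second rates for decays.
REFERENCE_PARAMS = {
    "allocentric_encoding": 0.5,
    "allocentric_decay": 0.1,
    "radial_encoding": 0.5,
    "radial_decay": 0.1,
    "angular_encoding": 0.01,
    "angular_decay": 0.005,
    "fixation_decay": 0.05,
    "saccade_encoding": 0.3,
    "saccade_decay": 0.05,
    "interference": 0.25,
}


def reference_params(spec) -> dict[str, float]:
    """Canonical natural-scale parameters for one model (see REFERENCE_PARAMS)."""
    return {name: REFERENCE_PARAMS[name] for name in spec.param_names}

#: Eye-tracker sampling rate emulated by the gaze simulator (Hz).
GAZE_RATE_HZ = 1000
#: Duration of a simulated saccade ramp (s); a 10 deg saccade over 30 ms has
#: a mean velocity of ~335 deg/s, comfortably above the 150 deg/s detector
#: threshold.
SACCADE_RAMP_S = 0.030


@dataclass(frozen=True)
class GenerativeConfig:
    """Settings for forward simulation from one generative model."""

    spec: _m.ModelSpec
    params_natural: dict[str, float]
    colour_noise_sd: float = 0.35  # radians on the colour wheel
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.spec.param_names) - set(self.params_natural)
        if missing:
            raise ValueError(f"missing parameters for {self.spec.name}: {missing}")
        for name in self.spec.param_names:
            v = self.params_natural[name]
            if name == "interference":
                if not 0.0 <= v <= 1.0:
                    raise ValueError("interference weight must lie in [0, 1]")
            elif v < 0.0:
                raise ValueError(f"scale parameter {name} must be non-negative")


@dataclass
class GazeTrace:
    """Raw gaze samples: time (ms), position (deg), pupil, validity mask."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.x, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


def _sample_location(spec, natural, item_xy, origin, timing, rng):
    """Draw one response around `item_xy` under the model's noise at `timing`."""
    tau, t, T, n = timing
    sched = _m.variance_schedule(spec, natural, tau, t, T, n)
    if spec.is_allocentric:
        sd = float(np.sqrt(sched))
        return (item_xy[0] + rng.normal(0.0, sd),
                item_xy[1] + rng.normal(0.0, sd))
    sig_r, sig_th = (float(s) for s in sched)
    dx, dy = item_xy[0] - origin[0], item_xy[1] - origin[1]
    r = np.hypot(dx, dy) + rng.normal(0.0, np.sqrt(sig_r))
    # angular deviation is truncated to (-pi, pi], matching the (normalised)
    # angular density evaluated at fitting time
    while True:
        dth = rng.normal(0.0, np.sqrt(sig_th))
        if abs(dth) <= np.pi:
            break
    th = np.arctan2(dy, dx) + dth
    return (origin[0] + r * np.cos(th), origin[1] + r * np.sin(th))


def simulate_responses(session, config: GenerativeConfig) -> list[dict]:
    """Sample one response per trial from the configured generative model.

    Returns one dict per trial with keys ``trial_id``, ``resp_col`` (radians)
    and ``resp_x``, ``resp_y`` (deg, screen coordinates).
    """
    rng = np.random.default_rng(config.seed)
    spec, natural = config.spec, config.params_natural
    w = natural.get("interference", 0.0) if spec.has_interference else 0.0
    out = []
    for trial in session:
        probed = trial.probed_item
        other = 2 if probed == 1 else 1
        origin = trial.fixation_of_item(probed)
        swap = bool(rng.uniform() < w)
        item = other if swap else probed
        timing = condition_timing(trial, item)
        # The distractor is evaluated in the probed item's reference frame,
        # sharing the response time, but with its own timing variables.
        x, y = _sample_location(spec, natural, trial.item_location(item),
                                origin, timing, rng)
        colour = trial.item1_colour if probed == 1 else trial.item2_colour
        resp_col = float(np.mod(colour + rng.normal(0.0, config.colour_noise_sd),
                                2.0 * np.pi))
        out.append({"trial_id": trial.trial_id, "resp_col": resp_col,
                    "resp_x": float(x), "resp_y": float(y)})
    return out


def simulate_session_data(seed: int, config: GenerativeConfig,
                          n_trials: int = 160):
    """Convenience: generate a session and simulate responses for it.

    Returns ``(session, responses, observations)`` where observations are the
    normalised trials ready for model fitting.
    """
    session = generate_session(seed, n_trials)
    cfg = GenerativeConfig(spec=config.spec, params_natural=config.params_natural,
                           colour_noise_sd=config.colour_noise_sd,
                           seed=np.random.SeedSequence([seed, config.seed]).generate_state(1)[0] % (2**31))
    responses = simulate_responses(session, cfg)
    obs = _m.ObservationSet.from_trials(
        session, [(r["resp_x"], r["resp_y"]) for r in responses])
    return session, responses, obs


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

def _gaze_waypoints(trial: TrialDesign) -> list[tuple[float, tuple[float, float]]]:
    """(time, position) pairs of instructed gaze over one trial."""
    points = [(0.0, trial.fixation1)]
    times = saccade_times(trial)
    targets = []
    if trial.fixation2 != trial.fixation1:
        targets.append(trial.fixation2)
    if trial.wheel_location != trial.fixation2:
        targets.append(trial.wheel_location)
    for s, tgt in zip(times, targets):
        points.append((s, tgt))
    return points


def simulate_gaze(trial: TrialDesign, compliant: bool = True,
                  noise_sd: float = 0.0, seed: int = 0) -> GazeTrace:
    """Simulate a 1000 Hz gaze trace for one trial.

    Compliant traces follow the instructed fixation sequence, with each
    saccade a 30 ms linear ramp.  Non-compliant traces inject a violation
    suited to the condition: a large excursion during retention when no
    saccade is allowed, or omission of the last required saccade otherwise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    tl = trial.timeline
    dt = 1.0 / GAZE_RATE_HZ
    times = np.arange(0.0, tl.t_loc_resp, dt)
    waypoints = _gaze_waypoints(trial)

    if not compliant and trial.condition.requires_saccade:
        waypoints = waypoints[:-1]  # omit the final required saccade

    x = np.full_like(times, waypoints[0][1][0])
    y = np.full_like(times, waypoints[0][1][1])
    prev = waypoints[0][1]
    for s, tgt in waypoints[1:]:
        ramp = (times >= s) & (times < s + SACCADE_RAMP_S)
        frac = (times[ramp] - s) / SACCADE_RAMP_S
        x[ramp] = prev[0] + frac * (tgt[0] - prev[0])
        y[ramp] = prev[1] + frac * (tgt[1] - prev[1])
        after = times >= s + SACCADE_RAMP_S
        x[after], y[after] = tgt[0], tgt[1]
        prev = tgt

    if not compliant and not trial.condition.requires_saccade:
        # 10 deg excursion (out and back) during item-2 retention
        t0 = tl.t_item2_on + 0.3
        for s, delta in ((t0, 10.0), (t0 + 0.25, -10.0)):
            ramp = (times >= s) & (times < s + SACCADE_RAMP_S)
            frac = (times[ramp] - s) / SACCADE_RAMP_S
            x[ramp] += frac * delta
            x[times >= s + SACCADE_RAMP_S] += delta

    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    pupil = np.full_like(times, 1000.0)
    return GazeTrace(time_ms=times * 1000.0, x=x, y=y, pupil=pupil)
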