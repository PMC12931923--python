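"""Generative likelihood models of location-recall error.

Seven competing models of how a remembered location degrades between viewing
and report.  All share a diffusion-style assumption: the variance of the
recalled coordinate grows linearly in elapsed time.  They differ in *which*
coordinates are stored and *which* clocks drive the decay:

1. ``allocentric``          -- screen-centred (u, v), encoding + decay over tau.
2. ``dual``                 -- eye-centred polar (r, theta) about the fixation
                               at which the item was viewed, with separate
                               radial/angular encoding and decay terms.
3. ``dual_fixation``        -- dual + decay of the remembered fixation point,
                               which starts at the first saccade after the
                               stimulus (clock t).
4. ``dual_saccade``         -- dual + saccade-vector updating: each saccade
                               since the item's fixation injects encoding
                               error (n times) and its memory decays over the
                               total time since the saccades (t + T).
5. ``dual_interference``    -- dual + a probability w of responding around the
                               unprobed (distractor) item instead.
6. ``dual_fixation_interference``
7. ``dual_saccade_interference``  -- the saccade-update model with
                               interference; the most complex model.

Scale parameters live on the log scale (natural value ``exp(kappa)``); the
interference weight is a logit parameter (natural value ``sigmoid(kappa)``).
Fixation-decay and saccade terms enter both the radial and angular variances
additively.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .task import TrialDesign, condition_timing

__all__ = [
    "Component",
    "ModelSpec",
    "MODELS",
    "model_by_id",
    "transform_params",
    "inverse_transform_params",
    "variance_schedule",
    "normalize_trial",
    "denormalize_response",
    "ObservationSet",
    "loglik_trial",
    "dataset_loglik",
    "wrap_angle",
    "REFERENCE_ANGLE",
    "OBSERVATION_COLUMNS",
]

#: After normalisation every target sits at this polar angle about its fixation.
REFERENCE_ANGLE = 0.0

OBSERVATION_COLUMNS = [
    "trial_id", "target_r", "target_th", "distr_r", "distr_th",
    "resp_u", "resp_v", "tau", "t", "T", "n",
    "d_tau", "d_t", "d_T", "d_n",
]


class Component(str, enum.Enum):
    ALLOCENTRIC_ENC = "allocentric_encoding"
    ALLOCENTRIC_DECAY = "allocentric_decay"
    RADIAL_ENC = "radial_encoding"
    RADIAL_DECAY = "radial_decay"
    ANGULAR_ENC = "angular_encoding"
    ANGULAR_DECAY = "angular_decay"
    FIXATION_DECAY = "fixation_decay"
    SACCADE_ENC = "saccade_encoding"
    SACCADE_DECAY = "saccade_decay"
    INTERFERENCE = "interference"


_DUAL = (
    Component.RADIAL_ENC, Component.RADIAL_DECAY,
    Component.ANGULAR_ENC, Component.ANGULAR_DECAY,
)


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameterisation of one generative model."""

    model_id: int
    name: str
    components: tuple[Component, ...]

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(c.value for c in self.components)

    @property
    def n_params(self) -> int:
        return len(self.components)

    @property
    def has_interference(self) -> bool:
        return Component.INTERFERENCE in self.components

    @property
    def is_allocentric(self) -> bool:
        return Component.ALLOCENTRIC_ENC in self.components


MODELS: tuple[ModelSpec, ...] = (
    ModelSpec(1, "allocentric",
              (Component.ALLOCENTRIC_ENC, Component.ALLOCENTRIC_DECAY)),
    ModelSpec(2, "dual", _DUAL),
    ModelSpec(3, "dual_fixation", _DUAL + (Component.FIXATION_DECAY,)),
    ModelSpec(4, "dual_saccade",
              _DUAL + (Component.SACCADE_ENC, Component.SACCADE_DECAY)),
    ModelSpec(5, "dual_interference", _DUAL + (Component.INTERFERENCE,)),
    ModelSpec(6, "dual_fixation_interference",
              _DUAL + (Component.FIXATION_DECAY, Component.INTERFERENCE)),
    ModelSpec(7, "dual_saccade_interference",
              _DUAL + (Component.SACCADE_ENC, Component.SACCADE_DECAY,
                       Component.INTERFERENCE)),
)


def model_by_id(model_id: int) -> ModelSpec:
    for m in MODELS:
        if m.model_id == int(model_id):
            return m
    raise KeyError(f"no model with id {model_id!r}")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def transform_params(kappa, spec: ModelSpec) -> dict[str, float]:
    """Map unconstrained parameters to the natural scale.

    Every scale parameter is exponentiated (guaranteeing positivity); the
    interference parameter is passed through a sigmoid so the mixture weight
    lies in (0, 1).
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa.shape != (spec.n_params,):
        raise ValueError(
            f"model {spec.model_id} expects {spec.n_params} parameters, "
            f"got shape {kappa.shape}"
        )
    if not np.all(np.isfinite(kappa)):
        raise ValueError("unconstrained parameters must be finite")
    out = {}
    with np.errstate(over="ignore"):
        for name, k in zip(spec.param_names, kappa):
            if name == Component.INTERFERENCE.value:
                out[name] = float(_sigmoid(k))
            else:
                out[name] = float(np.exp(k))
    return out


def inverse_transform_params(natural: dict[str, float], spec: ModelSpec) -> np.ndarray:
    """Map natural-scale parameters back to the unconstrained space."""
    kappa = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        v = float(natural[name])
        if name == Component.INTERFERENCE.value:
            if not 0.0 < v < 1.0:
                raise ValueError("interference weight must lie in (0, 1)")
            kappa[i] = math.log(v / (1.0 - v))
        else:
            if v <= 0.0:
                raise ValueError(f"scale parameter {name} must be positive")
            kappa[i] = math.log(v)
    return kappa


def variance_schedule(spec: ModelSpec, natural: dict[str, float],
                      tau, t, T, n):
    """Response variance at timing (tau, t, T, n), natural-scale parameters.

    Returns ``(sigma_r, sigma_theta)`` in deg^2 and rad^2 for the dual models,
    or a single isotropic ``sigma_xy`` (deg^2, per axis) for the allocentric
    model.  All inputs may be scalars or broadcastable arrays.
    """
    tau = np.asarray(tau, dtype=float)
    t = np.asarray(t, dtype=float)
    T = np.asarray(T, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(tau < 0) or np.any(t < 0) or np.any(T < 0):
        raise ValueError("timing arguments must be non-negative")
    if np.any((n < 0) | (n > 2)):
        raise ValueError("saccade count must lie in {0, 1, 2}")

    g = natural.get
    if spec.is_allocentric:
        return g("allocentric_encoding") + g("allocentric_decay") * tau

    shared = 0.0
    if Component.FIXATION_DECAY in spec.components:
        shared = shared + g("fixation_decay") * t
    if Component.SACCADE_ENC in spec.components:
        shared = shared + g("saccade_encoding") * n + g("saccade_decay") * (t + T)
    sig_r = g("radial_encoding") + g("radial_decay") * tau + shared
    sig_th = g("angular_encoding") + g("angular_decay") * tau + shared
    return sig_r, sig_th


def wrap_angle(x):
    """Wrap an angle (array) into (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


# ---------------------------------------------------------------------------
# Trial normalisation
# ---------------------------------------------------------------------------

def _rigid_transform(point, origin, rotation):
    """Translate by -origin then rotate by `rotation` (radians, CCW)."""
    px, py = point[0] - origin[0], point[1] - origin[1]
    c, s = math.cos(rotation), math.sin(rotation)
    return (c * px - s * py, s * px + c * py)


def normalize_trial(design: TrialDesign, response, probed_item: int | None = None):
    """Rotate/translate one trial into the canonical model frame.

    The origin becomes the fixation cross at which the probed item was viewed
    and the frame is rotated so the probed item lies at the reference angle.
    The same rigid motion is applied to the response and to the distractor, so
    all distances are preserved.  Returns a dict with the observation-file
    fields (see :data:`OBSERVATION_COLUMNS`).
    """
    probed = design.probed_item if probed_item is None else probed_item
    if probed not in (1, 2):
        raise ValueError(f"probed item must be 1 or 2, got {probed!r}")
    rx, ry = float(response[0]), float(response[1])
    if not (math.isfinite(rx) and math.isfinite(ry)):
        raise ValueError("response coordinates must be finite")
    origin = design.fixation_of_item(probed)
    target = design.item_location(probed)
    distractor_item = 2 if probed == 1 else 1
    distractor = design.item_location(distractor_item)

    raw_angle = math.atan2(target[1] - origin[1], target[0] - origin[0])
    rot = REFERENCE_ANGLE - raw_angle
    tx, ty = _rigid_transform(target, origin, rot)
    dx, dy = _rigid_transform(distractor, origin, rot)
    ru, rv = _rigid_transform((rx, ry), origin, rot)

    tau, t, T, n = condition_timing(design, probed)
    d_tau, d_t, d_T, d_n = condition_timing(design, distractor_item)
    return {
        "trial_id": design.trial_id,
        "target_r": math.hypot(tx, ty),
        "target_th": float(wrap_angle(math.atan2(ty, tx))),
        "distr_r": math.hypot(dx, dy),
        "distr_th": float(wrap_angle(math.atan2(dy, dx))),
        "resp_u": ru,
        "resp_v": rv,
        "tau": tau, "t": t, "T": T, "n": n,
        "d_tau": d_tau, "d_t": d_t, "d_T": d_T, "d_n": d_n,
    }


def denormalize_response(design: TrialDesign, resp_u: float, resp_v: float,
                         probed_item: int | None = None) -> tuple[float, float]:
    """Inverse of the rigid motion applied by :func:`normalize_trial`."""
    probed = design.probed_item if probed_item is None else probed_item
    origin = design.fixation_of_item(probed)
    target = design.item_location(probed)
    raw_angle = math.atan2(target[1] - origin[1], target[0] - origin[0])
    rot = raw_angle - REFERENCE_ANGLE
    c, s = math.cos(rot), math.sin(rot)
    return (c * resp_u - s * resp_v + origin[0],
            s * resp_u + c * resp_v + origin[1])


# ---------------------------------------------------------------------------
# Vectorised dataset container and likelihoods
# ---------------------------------------------------------------------------

class ObservationSet:
    """Normalised trials of one subject, as flat arrays for fast likelihoods."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in OBSERVATION_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        self.table = table.reset_index(drop=True)
        for col in OBSERVATION_COLUMNS:
            setattr(self, col, self.table[col].to_numpy(dtype=float))
        # response in polar coordinates about the (normalised) fixation origin
        self.resp_r = np.hypot(self.resp_u, self.resp_v)
        self.resp_th = np.arctan2(self.resp_v, self.resp_u)

    @classmethod
    def from_trials(cls, designs, responses, probed_items=None) -> "ObservationSet":
        rows = []
        for i, (d, r) in enumerate(zip(designs, responses)):
            probed = None if probed_items is None else probed_items[i]
            rows.append(normalize_trial(d, r, probed))
        return cls(pd.DataFrame(rows, columns=OBSERVATION_COLUMNS))

    def __len__(self) -> int:
        return len(self.table)


_LOG_2PI = math.log(2.0 * math.pi)


def _polar_logdensity(spec, natural, obs: ObservationSet, which: str):
    """Per-trial log-density about the target ('t') or the distractor ('d')."""
    if which == "t":
        r0, th0 = obs.target_r, obs.target_th
        sig_r, sig_th = variance_schedule(spec, natural, obs.tau, obs.t,
                                          obs.T, obs.n)
    else:
        r0, th0 = obs.distr_r, obs.distr_th
        sig_r, sig_th = variance_schedule(spec, natural, obs.d_tau, obs.d_t,
                                          obs.d_T, obs.d_n)
    dr = obs.resp_r - r0
    dth = wrap_angle(obs.resp_th - th0)
    # The angular residual lives on (-pi, pi]; the normal density is therefore
    # renormalised over that interval (a doubly truncated normal) so the trial
    # density integrates to one at any variance and forward simulation samples
    # exactly the density being fitted.  The correction vanishes for small
    # angular variance.
    log_z = np.log(erf(np.pi / np.sqrt(2.0 * sig_th)))
    return (-0.5 * (_LOG_2PI + np.log(sig_r) + dr * dr / sig_r)
            - 0.5 * (_LOG_2PI + np.log(sig_th) + dth * dth / sig_th) - log_z)


def _allocentric_logdensity(spec, natural, obs: ObservationSet, which: str):
    if which == "t":
        x0 = obs.target_r * np.cos(obs.target_th)
        y0 = obs.target_r * np.sin(obs.target_th)
        sig = variance_schedule(spec, natural, obs.tau, obs.t, obs.T, obs.n)
    else:
        x0 = obs.distr_r * np.cos(obs.distr_th)
        y0 = obs.distr_r * np.sin(obs.distr_th)
        sig = variance_schedule(spec, natural, obs.d_tau, obs.d_t, obs.d_T,
                                obs.d_n)
    du = obs.resp_u - x0
    dv = obs.resp_v - y0
    return -(_LOG_2PI + np.log(sig)) - 0.5 * (du * du + dv * dv) / sig


def _trial_loglik_vector(spec: ModelSpec, natural: dict[str, float],
                         obs: ObservationSet) -> np.ndarray:
    dens = _allocentric_logdensity if spec.is_allocentric else _polar_logdensity
    # extreme candidate parameters (overflowing exp, w -> 0 or 1) yield
    # non-finite densities here; callers reject those points
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lt = dens(spec, natural, obs, "t")
        if not spec.has_interference:
            return lt
        w = natural["interference"]
        ld = dens(spec, natural, obs, "d")
        # log of the two-component mixture, stable for w near 0 or 1
        return np.logaddexp(np.log1p(-w) + lt, np.log(w) + ld)


def loglik_trial(spec: ModelSpec, natural: dict[str, float], obs) -> float:
    """Log-density (nats) of one normalised trial's response under a model."""
    if not isinstance(obs, ObservationSet):
        obs = ObservationSet(pd.DataFrame([obs], columns=OBSERVATION_COLUMNS))
    vec = _trial_loglik_vector(spec, natural, obs)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite trial log-density")
    return float(vec[0]) if len(vec) == 1 else float(vec.sum())


def dataset_loglik(spec: ModelSpec, natural: dict[str, float],
                   obs: ObservationSet) -> float:
    """Summed log-likelihood over a subject's trials; empty dataset gives 0."""
    if len(obs) == 0:
        return 0.0
    vec = _trial_loglik_vector(spec, natural, obs)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite trial log-density")
    return float(vec.sum())
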