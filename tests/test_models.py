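"""Likelihood models: transforms, schedules, normalisation, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locus.models import (MODELS, ObservationSet, dataset_loglik, loglik_trial,
                          model_by_id, normalize_trial, denormalize_response,
                          transform_params, inverse_transform_params,
                          variance_schedule, wrap_angle, OBSERVATION_COLUMNS)
from locus.task import generate_session
import pandas as pd


def _natural(spec, **overrides):
    base = {name: 1.0 for name in spec.param_names}
    if "interference" in base:
        base["interference"] = 0.3
    base.update(overrides)
    return base


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def test_zero_kappa_gives_unit_scales_and_half_interference():
    spec = model_by_id(7)
    nat = transform_params(np.zeros(spec.n_params), spec)
    for name, v in nat.items():
        assert v == pytest.approx(0.5 if name == "interference" else 1.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(-5, 5), st.floats(-5, 5))
def test_transform_strictly_monotone_per_coordinate(a, b):
    if abs(a - b) < 1e-9:
        return
    spec = model_by_id(7)
    lo, hi = sorted((a, b))
    va = transform_params(np.full(spec.n_params, lo), spec)
    vb = transform_params(np.full(spec.n_params, hi), spec)
    for name in spec.param_names:
        assert va[name] < vb[name]


def test_transform_round_trip():
    spec = model_by_id(7)
    kappa = np.linspace(-1, 1, spec.n_params)
    back = inverse_transform_params(transform_params(kappa, spec), spec)
    assert np.allclose(back, kappa, atol=1e-12)


# ---------------------------------------------------------------------------
# variance schedules
# ---------------------------------------------------------------------------

def test_schedule_reduces_to_encoding_at_time_zero():
    for spec in MODELS:
        nat = _natural(spec)
        out = variance_schedule(spec, nat, 0.0, 0.0, 0.0, 0)
        if spec.is_allocentric:
            assert out == pytest.approx(nat["allocentric_encoding"])
        else:
            sr, sth = out
            assert sr == pytest.approx(nat["radial_encoding"])
            assert sth == pytest.approx(nat["angular_encoding"])


def test_saccade_model_nests_dual_when_extras_vanish():
    m2, m4 = model_by_id(2), model_by_id(4)
    nat4 = _natural(m4, saccade_encoding=0.0, saccade_decay=0.0)
    nat2 = {k: nat4[k] for k in m2.param_names}
    for tau, t, T, n in [(5, 4.8, 2.8, 2), (3.5, 0, 0, 0), (5, 2.8, 0, 1)]:
        assert variance_schedule(m4, nat4, tau, t, T, n) == \
            pytest.approx(variance_schedule(m2, nat2, tau, t, T, n))


@pytest.mark.parametrize("spec", MODELS, ids=lambda m: m.name)
def test_schedule_nondecreasing_in_every_clock(spec):
    nat = _natural(spec)
    grid = np.linspace(0.0, 6.0, 7)

    def sig(tau, t, T, n):
        out = variance_schedule(spec, nat, tau, t, T, n)
        return (out,) if spec.is_allocentric else out

    for comp in range(1 if spec.is_allocentric else 2):
        base = sig(0, 0, 0, 0)[comp]
        vals_tau = [sig(v, 0, 0, 0)[comp] for v in grid]
        assert np.all(np.diff(vals_tau) >= 0) and vals_tau[0] == base
        vals_t = [sig(6, v, 0, 1)[comp] for v in grid]
        assert np.all(np.diff(vals_t) >= 0)
        vals_T = [sig(6, 6, v, 2)[comp] for v in grid]
        assert np.all(np.diff(vals_T) >= 0)
        vals_n = [sig(6, 6, 3, n)[comp] for n in (0, 1, 2)]
        assert np.all(np.diff(vals_n) >= 0)


def test_negative_timing_rejected():
    spec = model_by_id(2)
    with pytest.raises(ValueError):
        variance_schedule(spec, _natural(spec), -0.1, 0, 0, 0)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_normalisation_is_rigid_and_canonical(session_160):
    rng = np.random.default_rng(0)
    for trial in session_160[:40]:
        target = trial.item_location(trial.probed_item)
        resp = (target[0] + rng.normal(), target[1] + rng.normal())
        obs = normalize_trial(trial, resp)
        # rigid motion preserves the response-to-target distance
        raw_d = math.hypot(resp[0] - target[0], resp[1] - target[1])
        tx = obs["target_r"] * math.cos(obs["target_th"])
        ty = obs["target_r"] * math.sin(obs["target_th"])
        norm_d = math.hypot(obs["resp_u"] - tx, obs["resp_v"] - ty)
        assert norm_d == pytest.approx(raw_d, abs=1e-9)
        assert obs["target_th"] == pytest.approx(0.0, abs=1e-12)
        # round trip back to raw screen coordinates
        back = denormalize_response(trial, obs["resp_u"], obs["resp_v"])
        assert back == pytest.approx(resp, abs=1e-10)


def test_normalised_timing_attached_to_right_items(session_160):
    for trial in session_160[:20]:
        obs = normalize_trial(trial, (0.0, 0.0))
        tau, t, T, n = obs["tau"], obs["t"], obs["T"], obs["n"]
        assert tau >= t >= T >= 0 and n in (0, 1, 2)
        assert obs["d_tau"] >= obs["d_t"] >= obs["d_T"] >= 0


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _single_obs(**kw):
    row = {c: 0.0 for c in OBSERVATION_COLUMNS}
    row.update(trial_id=0, target_r=5.0, distr_r=5.0, distr_th=1.0)
    row.update(kw)
    return ObservationSet(pd.DataFrame([row], columns=OBSERVATION_COLUMNS))


def test_allocentric_peak_density_is_standard_normal_peak():
    spec = model_by_id(1)
    obs = _single_obs(resp_u=5.0, resp_v=0.0)
    nat = {"allocentric_encoding": 1.0, "allocentric_decay": 1.0}
    assert loglik_trial(spec, nat, obs) == pytest.approx(-math.log(2 * math.pi))


def test_interference_weight_zero_matches_target_only_model():
    m5, m2 = model_by_id(5), model_by_id(2)
    obs = _single_obs(resp_u=5.3, resp_v=0.4, tau=5.0, d_tau=3.5)
    nat5 = _natural(m5, interference=0.0)
    nat2 = {k: nat5[k] for k in m2.param_names}
    assert loglik_trial(m5, nat5, obs) == \
        pytest.approx(loglik_trial(m2, nat2, obs), abs=1e-12)


def test_interference_weight_one_matches_distractor_only():
    m5 = model_by_id(5)
    obs = _single_obs(resp_u=5.3, resp_v=0.4, tau=5.0, d_tau=5.0)
    nat_w1 = _natural(m5, interference=1.0)
    # with w = 1 the density must equal a pure-target density evaluated at
    # the distractor's coordinates
    swapped = _single_obs(resp_u=5.3, resp_v=0.4, tau=5.0,
                          target_r=5.0, target_th=1.0)
    m2 = model_by_id(2)
    nat2 = {k: nat_w1[k] for k in m2.param_names}
    assert loglik_trial(m5, nat_w1, obs) == \
        pytest.approx(loglik_trial(m2, nat2, swapped), abs=1e-12)


@pytest.mark.parametrize("model_id,nat_kw", [
    (2, {}),
    (5, {"interference": 0.4}),
    (7, {"interference": 0.4, "saccade_encoding": 0.5, "saccade_decay": 0.2}),
])
def test_trial_density_integrates_to_one(model_id, nat_kw):
    """2-D quadrature of the (r, theta) density over its support (tol 1e-3)."""
    spec = model_by_id(model_id)
    nat = _natural(spec, **nat_kw)
    obs_tpl = dict(tau=5.0, t=4.8, T=2.8, n=2, d_tau=3.5, d_t=2.8, d_T=0.0,
                   d_n=1)
    # the density lives on (r, theta) with r over the whole real line and
    # theta on the circle; probe it on that grid directly
    r_grid = np.linspace(-30.0, 40.0, 1401)
    th_grid = np.linspace(-np.pi, np.pi, 1201)[1:]
    from locus.models import _trial_loglik_vector
    total = 0.0
    for th in th_grid:
        rows = [dict({c: 0.0 for c in OBSERVATION_COLUMNS}, trial_id=0,
                     target_r=5.0, distr_r=4.0, distr_th=1.2, **obs_tpl)
                for _ in r_grid]
        obs = ObservationSet(pd.DataFrame(rows, columns=OBSERVATION_COLUMNS))
        obs.resp_r = r_grid
        obs.resp_th = np.full_like(r_grid, th)
        dens = np.exp(_trial_loglik_vector(spec, nat, obs))
        total += np.trapezoid(dens, r_grid)
    integral = total * (th_grid[1] - th_grid[0])
    assert integral == pytest.approx(1.0, abs=1e-3)


def test_dataset_loglik_is_additive_and_zero_on_empty(model7_dataset):
    spec = model_by_id(7)
    nat = _natural(spec)
    empty = ObservationSet(model7_dataset.table.iloc[:0])
    assert dataset_loglik(spec, nat, empty) == 0.0
    two = ObservationSet(model7_dataset.table.iloc[:2])
    one_a = ObservationSet(model7_dataset.table.iloc[:1])
    one_b = ObservationSet(model7_dataset.table.iloc[1:2])
    assert dataset_loglik(spec, nat, two) == pytest.approx(
        dataset_loglik(spec, nat, one_a) + dataset_loglik(spec, nat, one_b),
        abs=1e-12)


def test_dataset_loglik_matches_per_trial_loop(model7_dataset):
    spec = model_by_id(7)
    nat = _natural(spec)
    subset = ObservationSet(model7_dataset.table.iloc[:50])
    looped = sum(
        loglik_trial(spec, nat, ObservationSet(subset.table.iloc[i:i + 1]))
        for i in range(50))
    assert dataset_loglik(spec, nat, subset) == pytest.approx(looped,
                                                              abs=1e-9)


@pytest.mark.parametrize("full_id,reduced_id,extras", [
    (3, 2, {"fixation_decay": 0.0}),
    (4, 2, {"saccade_encoding": 0.0, "saccade_decay": 0.0}),
    (6, 5, {"fixation_decay": 0.0}),
    (7, 5, {"saccade_encoding": 0.0, "saccade_decay": 0.0}),
])
def test_nested_models_agree_when_extras_vanish(model7_dataset, full_id,
                                                reduced_id, extras):
    full, reduced = model_by_id(full_id), model_by_id(reduced_id)
    nat_full = _natural(full, **extras)
    nat_red = {k: nat_full[k] for k in reduced.param_names}
    lf = dataset_loglik(full, nat_full, model7_dataset)
    lr = dataset_loglik(reduced, nat_red, model7_dataset)
    assert lf == pytest.approx(lr, abs=1e-12 * max(1, abs(lr)))


def test_loglik_invariant_to_rigid_motion_of_raw_data():
    """Rotating/translating the whole screen before normalisation leaves
    every model's dataset log-likelihood unchanged."""
    import dataclasses
    session = generate_session(seed=21, n_trials=40)
    rng = np.random.default_rng(2)
    responses = [(t.item_location(t.probed_item)[0] + rng.normal(),
                  t.item_location(t.probed_item)[1] + rng.normal())
                 for t in session]

    angle, shift = 0.83, (3.7, -1.9)
    c, s = math.cos(angle), math.sin(angle)

    def move(p):
        return (c * p[0] - s * p[1] + shift[0], s * p[0] + c * p[1] + shift[1])

    moved_session = [dataclasses.replace(
        t, fixation1=move(t.fixation1), fixation2=move(t.fixation2),
        wheel_location=move(t.wheel_location),
        item1_location=move(t.item1_location),
        item2_location=move(t.item2_location)) for t in session]
    moved_responses = [move(r) for r in responses]

    obs_a = ObservationSet.from_trials(session, responses)
    obs_b = ObservationSet.from_trials(moved_session, moved_responses)
    for spec in MODELS:
        nat = _natural(spec)
        assert dataset_loglik(spec, nat, obs_a) == pytest.approx(
            dataset_loglik(spec, nat, obs_b), rel=1e-9)


def test_wrap_angle_maps_into_half_open_interval():
    xs = np.array([0.0, np.pi, -np.pi, 3 * np.pi, -2.5 * np.pi, 7.0])
    w = wrap_angle(xs)
    assert np.all((w > -np.pi) & (w <= np.pi))
    assert np.allclose(np.cos(w), np.cos(xs))
    assert np.allclose(np.sin(w), np.sin(xs))
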