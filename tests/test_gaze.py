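"""Gaze preprocessing, event detection, compliance and error summaries."""

import numpy as np
import pytest

from locus.gaze import (NoDataError, behavioural_errors, classify_compliance,
                        colour_error, detect_fixations, detect_saccades,
                        remove_blinks)
from locus.simulate import GazeTrace, simulate_gaze
from locus.task import Condition, generate_session


def _trace(x, y, pupil=None, t0=0.0):
    n = len(x)
    t = t0 + np.arange(n, dtype=float)
    pupil = np.full(n, 900.0) if pupil is None else np.asarray(pupil, float)
    return GazeTrace(time_ms=t, x=np.asarray(x, float),
                     y=np.asarray(y, float), pupil=pupil)


def _step_trace(amplitude, ramp_ms=30, hold_ms=400):
    """Fixation at origin, linear step of `amplitude` deg, fixation again."""
    x = np.concatenate([np.zeros(hold_ms),
                        np.linspace(0, amplitude, ramp_ms),
                        np.full(hold_ms, amplitude)])
    return _trace(x, np.zeros_like(x))


# ---------------------------------------------------------------------------
# blink removal
# ---------------------------------------------------------------------------

def test_constant_pupil_trace_is_untouched():
    tr = _trace(np.zeros(500), np.zeros(500))
    out = remove_blinks(tr)
    assert out.valid.all()


def test_zero_pupil_gap_is_masked():
    pupil = np.full(500, 900.0)
    pupil[200:300] = 0.0
    out = remove_blinks(_trace(np.zeros(500), np.zeros(500), pupil))
    assert not out.valid[200:300].any()
    assert out.valid[:150].all() and out.valid[350:].all()


def test_blink_ramp_artefacts_are_masked():
    """Steep pupil ramps immediately around a closure (hand-built fixture
    with known extent) are treated as part of the blink."""
    n = 15_000  # a realistic trace length; the blink is a small fraction
    pupil = np.full(n, 900.0)
    pupil[7250:7280] = np.linspace(900, 0, 30)   # closing ramp
    pupil[7280:7320] = 0.0
    pupil[7320:7350] = np.linspace(0, 900, 30)   # reopening ramp
    out = remove_blinks(_trace(np.zeros(n), np.zeros(n), pupil))
    assert not out.valid[7255:7345].any()
    assert out.valid[:7200].all() and out.valid[7400:].all()


# ---------------------------------------------------------------------------
# fixation detection
# ---------------------------------------------------------------------------

def test_long_dwell_is_one_fixation_with_matching_duration():
    tr = _trace(np.zeros(300), np.zeros(300))
    fx = detect_fixations(tr, (0.0, 0.0))
    assert len(fx) == 1
    assert fx[0].duration_ms == pytest.approx(299.0)
    assert fx[0].centroid == pytest.approx((0.0, 0.0))


def test_short_dwell_is_not_a_fixation():
    x = np.concatenate([np.zeros(100), np.full(300, 10.0)])
    tr = _trace(x, np.zeros_like(x))
    assert detect_fixations(tr, (0.0, 0.0)) == []


def test_fixation_runs_match_brute_force_oracle():
    rng = np.random.default_rng(0)
    d_target = 2.5 + rng.normal(0, 0.3, size=2000).cumsum() * 0.01
    x = d_target  # distance from target equals |x|
    tr = _trace(x, np.zeros_like(x))
    fx = detect_fixations(tr, (0.0, 0.0))
    # oracle: sample-wise run lengths
    near = np.abs(x) <= 2.5
    runs = []
    start = None
    for i, flag in enumerate(near):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(near)))
    expected = [(a, b) for a, b in runs if (b - 1 - a) >= 150]
    assert len(fx) == len(expected)
    for ev, (a, b) in zip(fx, expected):
        assert ev.onset_ms == pytest.approx(float(a))
        assert ev.duration_ms == pytest.approx(float(b - 1 - a))


def test_empty_epoch_raises_no_data():
    tr = _trace(np.zeros(100), np.zeros(100))
    tr.valid[:] = False
    with pytest.raises(NoDataError):
        detect_fixations(tr, (0.0, 0.0))


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------

def test_constant_gaze_has_no_saccades():
    tr = _trace(np.full(800, 3.0), np.full(800, -2.0))
    assert detect_saccades(tr) == []


def test_ten_degree_step_is_one_saccade():
    evs = detect_saccades(_step_trace(10.0))
    assert len(evs) == 1
    assert evs[0].amplitude_deg == pytest.approx(10.0, abs=0.2)
    assert evs[0].peak_velocity > 150.0
    assert evs[0].duration_ms > 10.0


def test_five_degree_step_is_below_amplitude_threshold():
    assert detect_saccades(_step_trace(5.0)) == []


def test_detection_invariant_to_time_shift_and_rotation():
    base = _step_trace(10.0)
    shifted = GazeTrace(time_ms=base.time_ms + 12345.0, x=base.x, y=base.y,
                        pupil=base.pupil)
    c, s = np.cos(0.7), np.sin(0.7)
    rotated = GazeTrace(time_ms=base.time_ms, x=c * base.x - s * base.y,
                        y=s * base.x + c * base.y, pupil=base.pupil)
    for variant in (shifted, rotated):
        evs = detect_saccades(variant)
        assert len(evs) == 1
        assert evs[0].amplitude_deg == pytest.approx(
            detect_saccades(base)[0].amplitude_deg, abs=1e-6)


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------

def test_compliant_saccade_after_item1_passes():
    session = generate_session(seed=9, n_trials=40)
    trial = next(t for t in session if t.condition == Condition.SAC_AFTER_1)
    trace = simulate_gaze(trial, compliant=True, noise_sd=0.0)
    ok, reason = classify_compliance(trace, trial)
    assert ok is True and reason == "ok"


def test_no_saccade_trial_with_excursion_fails():
    session = generate_session(seed=9, n_trials=40)
    trial = next(t for t in session if t.condition == Condition.NO_SACCADE)
    trace = simulate_gaze(trial, compliant=False, noise_sd=0.0)
    ok, reason = classify_compliance(trace, trial)
    assert ok is False and "saccade" in reason


def test_fully_masked_trace_is_indeterminate():
    session = generate_session(seed=9, n_trials=40)
    trial = session[0]
    trace = simulate_gaze(trial, compliant=True, noise_sd=0.0)
    trace.pupil[:] = 0.0
    masked = remove_blinks(trace)
    ok, reason = classify_compliance(masked, trial)
    assert ok is None and reason.startswith("indeterminate")


@pytest.mark.parametrize("noise_sd,min_accuracy", [(0.0, 1.0), (0.5, 0.95)])
def test_closed_loop_classification_accuracy(noise_sd, min_accuracy):
    session = generate_session(seed=10, n_trials=40)
    hits = total = 0
    for trial in session:
        for compliant in (True, False):
            trace = simulate_gaze(trial, compliant=compliant,
                                  noise_sd=noise_sd, seed=trial.trial_id)
            ok, _ = classify_compliance(trace, trial)
            hits += (ok is compliant)
            total += 1
    assert hits / total >= min_accuracy


# ---------------------------------------------------------------------------
# behavioural errors
# ---------------------------------------------------------------------------

def test_colour_error_symmetric_and_wrapping():
    assert colour_error(0.1, 2 * np.pi - 0.1) == pytest.approx(0.2)
    assert colour_error(1.0, 1.0 + np.pi) == pytest.approx(np.pi)
    a, b = 0.3, 5.9
    assert colour_error(a, b) == pytest.approx(colour_error(b, a))
    assert 0 <= colour_error(a, b) <= np.pi


def test_perfect_responses_give_zero_errors_and_zero_cost():
    session = generate_session(seed=12, n_trials=16)
    responses = []
    for t in session:
        target = t.item_location(t.probed_item)
        colour = t.item1_colour if t.probed_item == 1 else t.item2_colour
        responses.append({"trial_id": t.trial_id, "resp_col": colour,
                          "resp_x": target[0], "resp_y": target[1]})
    summary = behavioural_errors(session, responses)
    assert np.allclose(summary.table.loc_err, 0.0)
    assert np.allclose(summary.table.col_err, 0.0)
    assert summary.saccade_cost == pytest.approx(0.0)


def test_toy_table_matches_hand_computation():
    """Eight hand-crafted trials: condition x item means and the saccade cost
    computed with a calculator."""
    import dataclasses
    session = generate_session(seed=13, n_trials=8)
    # force a known design: probed item 1 everywhere
    session = [dataclasses.replace(t, probed_item=1) for t in session]
    responses = []
    offsets = {Condition.NO_SACCADE: 1.0, Condition.SAC_AFTER_1: 2.0,
               Condition.SAC_AFTER_2: 3.0, Condition.TWO_SACCADES: 5.0}
    for t in session:
        target = t.item_location(1)
        responses.append({"trial_id": t.trial_id,
                          "resp_col": t.item1_colour + 0.25,
                          "resp_x": target[0] + offsets[t.condition],
                          "resp_y": target[1]})
    summary = behavioural_errors(session, responses)
    tab = summary.table.set_index(["condition", "item"])
    for cond, off in offsets.items():
        assert tab.loc[(cond.value, 1), "loc_err"] == pytest.approx(off)
        assert tab.loc[(cond.value, 1), "col_err"] == pytest.approx(0.25)
    # probed item 1: the saccade-after-the-other-item condition is
    # SAC_AFTER_2, so cost = 5 - 3 = 2
    assert summary.saccade_cost == pytest.approx(2.0)
    assert (Condition.NO_SACCADE.value, 2) in summary.missing_cells


def test_noncompliant_trials_are_excluded():
    session = generate_session(seed=14, n_trials=8)
    responses = [{"trial_id": t.trial_id, "resp_col": 0.0,
                  "resp_x": 0.0, "resp_y": 0.0} for t in session]
    summary = behavioural_errors(session, responses,
                                 compliance=[False] * len(session))
    assert len(summary.table) == 0
    assert np.isnan(summary.saccade_cost)
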