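"""Readers and writers for the pipeline's table and record formats.

Tabular data are CSV (UTF-8, '.' decimal, mandatory header), fit and
comparison records are JSON, gaze samples are tab-separated.  Every writer
round-trips through its reader with field-level fidelity (floats to full
repr precision).  Malformed files raise :class:`SchemaError` naming the
offending column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import OBSERVATION_COLUMNS, ObservationSet
from .laplace import PosteriorFit
from .selection import ModelComparison
from .simulate import GazeTrace
from .task import Condition, Timeline, TrialDesign

__all__ = [
    "SchemaError", "SESSION_COLUMNS", "RESPONSE_COLUMNS",
    "write_session", "read_session", "write_responses", "read_responses",
    "write_observations", "read_observations", "write_fit", "read_fit",
    "write_comparison", "read_comparison", "write_gaze", "read_gaze",
]

SESSION_COLUMNS = [
    "trial_id", "condition", "fix1_x", "fix1_y", "fix2_x", "fix2_y",
    "wheel_x", "wheel_y", "item1_x", "item1_y", "item2_x", "item2_y",
    "item1_col", "item2_col", "wheel_rot", "probed",
    "t_item1_on", "t_item1_off", "t_item2_on", "t_item2_off",
    "t_wheel_on", "t_col_resp", "t_loc_resp",
]
RESPONSE_COLUMNS = ["trial_id", "resp_col", "resp_x", "resp_y"]
GAZE_COLUMNS = ["time_ms", "x_deg", "y_deg", "pupil"]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing column(s): {', '.join(missing)}")


def _read_csv(path, expected, what) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, expected, what)
    return df


def write_session(session: list[TrialDesign], path) -> None:
    rows = []
    for t in session:
        tl = t.timeline
        rows.append([
            t.trial_id, t.condition.value,
            t.fixation1[0], t.fixation1[1], t.fixation2[0], t.fixation2[1],
            t.wheel_location[0], t.wheel_location[1],
            t.item1_location[0], t.item1_location[1],
            t.item2_location[0], t.item2_location[1],
            t.item1_colour, t.item2_colour, t.wheel_rotation, t.probed_item,
            tl.t_item1_on, tl.t_item1_off, tl.t_item2_on, tl.t_item2_off,
            tl.t_wheel_on, tl.t_col_resp, tl.t_loc_resp,
        ])
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_session(path) -> list[TrialDesign]:
    df = _read_csv(path, SESSION_COLUMNS, "session")
    out = []
    for _, r in df.iterrows():
        out.append(TrialDesign(
            trial_id=int(r.trial_id), condition=Condition(r.condition),
            fixation1=(r.fix1_x, r.fix1_y), fixation2=(r.fix2_x, r.fix2_y),
            wheel_location=(r.wheel_x, r.wheel_y),
            item1_location=(r.item1_x, r.item1_y),
            item2_location=(r.item2_x, r.item2_y),
            item1_colour=r.item1_col, item2_colour=r.item2_col,
            wheel_rotation=r.wheel_rot, probed_item=int(r.probed),
            timeline=Timeline(r.t_item1_on, r.t_item1_off, r.t_item2_on,
                              r.t_item2_off, r.t_wheel_on, r.t_col_resp,
                              r.t_loc_resp)))
    return out


def write_responses(responses: list[dict], path) -> None:
    pd.DataFrame(responses, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses(path) -> list[dict]:
    df = _read_csv(path, RESPONSE_COLUMNS, "response")
    return df.to_dict("records")


def write_observations(obs: ObservationSet, path) -> None:
    obs.table[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_observations(path) -> ObservationSet:
    df = _read_csv(path, OBSERVATION_COLUMNS, "observation")
    return ObservationSet(df)


def write_fit(fit: PosteriorFit, path) -> None:
    record = {
        "subject": fit.subject_id,
        "model": fit.model_id,
        "param_names": list(fit.param_names),
        "mode": [float(v) for v in fit.mode],
        "covariance": [[float(v) for v in row] for row in fit.covariance],
        "free_energy": float(fit.free_energy),
        "n_iterations": int(fit.n_iterations),
        "converged": bool(fit.converged),
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))


def read_fit(path) -> PosteriorFit:
    record = json.loads(Path(path).read_text())
    for key in ("model", "mode", "covariance", "free_energy"):
        if key not in record:
            raise SchemaError(f"fit record missing field: {key}")
    return PosteriorFit(
        subject_id=record.get("subject"), model_id=int(record["model"]),
        mode=np.asarray(record["mode"], dtype=float),
        covariance=np.asarray(record["covariance"], dtype=float),
        free_energy=float(record["free_energy"]),
        n_iterations=int(record.get("n_iterations", 0)),
        converged=bool(record.get("converged", True)),
        param_names=tuple(record.get("param_names", ())))


def write_comparison(comp: ModelComparison, path) -> None:
    record = {
        "model_ids": list(comp.model_ids),
        "summed_evidence": [float(v) for v in comp.summed_evidence],
        "posterior_prob": [float(v) for v in comp.posterior_prob],
        "bayes_factor_top2": float(comp.bayes_factor_top2),
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))


def read_comparison(path) -> ModelComparison:
    record = json.loads(Path(path).read_text())
    for key in ("model_ids", "summed_evidence", "posterior_prob"):
        if key not in record:
            raise SchemaError(f"comparison record missing field: {key}")
    return ModelComparison(
        model_ids=tuple(int(m) for m in record["model_ids"]),
        summed_evidence=np.asarray(record["summed_evidence"], dtype=float),
        posterior_prob=np.asarray(record["posterior_prob"], dtype=float),
        bayes_factor_top2=float(record["bayes_factor_top2"]))


def write_gaze(trace: GazeTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.time_ms, "x_deg": trace.x,
                  "y_deg": trace.y, "pupil": trace.pupil}).to_csv(
        path, sep="\t", index=False)


def read_gaze(path) -> GazeTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_columns(df, GAZE_COLUMNS, "gaze")
    return GazeTrace(time_ms=df.time_ms.to_numpy(), x=df.x_deg.to_numpy(),
                     y=df.y_deg.to_numpy(), pupil=df.pupil.to_numpy())
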