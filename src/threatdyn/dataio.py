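"""File schemas and joins for trajectory logs, trial metadata, and surveys.

Three tabular schemas are defined (CSV with a JSON mirror each):

* trajectory log — one row per mouse sample:
  ``participant_id, trial_id, t_ms, x_px, y_px, event``; exactly one
  ``load`` row (first) and one terminal ``click`` row per trial.  Optional
  ``screen_w, screen_h`` columns override the default 1920x1080 screen.
* trials — ``participant_id, trial_id, site_type, auth_level, response``
  plus optional ``site`` (website identity, used to join per-site
  familiarity) and ``usable`` (0/1 exclusion flag).
* survey — ``participant_id, knowledge_correct, indicators_correct,
  indicators_incorrect, familiarity_<site>..., age, gender``.

Positions are integer screen pixels, origin top-left, y increasing
downward; the kinematics module owns the conversion to math coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import survey as survey_mod
from .errors import JoinError, SchemaError, ValidationError

SITE_TYPES = ("non_spoof", "spoof")
AUTH_LEVELS = ("PE", "SV", "EV")
RESPONSES = ("login", "back")

#: Linear ordinal contrast for authentication level (centered at SV).
AUTH_CODE = {"PE": -1, "SV": 0, "EV": 1}

DEFAULT_SCREEN = (1920, 1080)

TRAJECTORY_COLUMNS = ["participant_id", "trial_id", "t_ms", "x_px", "y_px", "event"]
TRIAL_COLUMNS = ["participant_id", "trial_id", "site_type", "auth_level", "response"]
SURVEY_BASE_COLUMNS = [
    "participant_id",
    "knowledge_correct",
    "indicators_correct",
    "indicators_incorrect",
    "age",
    "gender",
]


@dataclass
class RawTrajectory:
    """Timestamped screen-pixel mouse samples for a single trial.

    Timestamps are milliseconds since the login page load; positions are
    integer screen pixels (y down).  ``samples`` includes the load and the
    final click events.
    """

    participant_id: str
    trial_id: str
    t: np.ndarray  # int ms
    x: np.ndarray  # int px
    y: np.ndarray  # int px
    page_load_t: int
    final_click: tuple[int, int, int]  # (t, x, y)
    response: str | None = None
    screen: tuple[int, int] = DEFAULT_SCREEN

    def __post_init__(self) -> None:
        # file schemas carry integer pixels/ms, but positions are kept as
        # float64 in memory so exact similarity transforms are expressible
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        key = f"{self.participant_id}/{self.trial_id}"
        if self.t.size < 2:
            raise ValidationError(f"trial {key}: fewer than 2 samples")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError(f"trial {key}: ragged sample arrays")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError(f"trial {key}: timestamps decrease")
        ct, cx, cy = self.final_click
        if ct < self.t[-1]:
            raise ValidationError(f"trial {key}: final click precedes last sample")
        w, h = self.screen
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValidationError(f"trial {key}: final click outside screen")
        if self.page_load_t > self.t[0]:
            raise ValidationError(f"trial {key}: page load after first sample")
        if self.response is not None and self.response not in RESPONSES:
            raise ValidationError(f"trial {key}: bad response {self.response!r}")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


def derive_accuracy(site_type: str, response: str) -> int:
    """1 iff login on a non-spoof site or back on a spoof site."""
    return int(
        (site_type == "non_spoof" and response == "login")
        or (site_type == "spoof" and response == "back")
    )


# ---------------------------------------------------------------------------
# trajectory log

def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _int_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based, plus header line
        raise SchemaError(f"{path}: malformed value in column {col!r} at row {row}")
    return vals.to_numpy().astype(np.int64)


def read_trajectories(path) -> dict[tuple[str, str], RawTrajectory]:
    """Read a trajectory log (CSV or JSON mirror) into RawTrajectory objects.

    Returns a dict keyed by ``(participant_id, trial_id)``.
    """
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)
    for col in ("t_ms", "x_px", "y_px"):
        df[col] = _int_column(df, col, path)
    bad_event = ~df["event"].isin(["load", "move", "click"])
    if bad_event.any():
        row = int(df.index[bad_event][0]) + 2
        raise SchemaError(f"{path}: unknown event at row {row}")

    out: dict[tuple[str, str], RawTrajectory] = {}
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=False):
        events = grp["event"].to_numpy()
        if (events == "load").sum() != 1 or (events == "click").sum() != 1:
            raise SchemaError(
                f"{path}: trial {pid}/{tid} must have exactly one load and one click"
            )
        if events[0] != "load" or events[-1] != "click":
            raise SchemaError(
                f"{path}: trial {pid}/{tid} must start with load and end with click"
            )
        t = grp["t_ms"].to_numpy()
        x = grp["x_px"].to_numpy()
        y = grp["y_px"].to_numpy()
        if "screen_w" in grp.columns and not pd.isna(grp["screen_w"].iloc[0]):
            screen = (int(grp["screen_w"].iloc[0]), int(grp["screen_h"].iloc[0]))
        else:
            screen = DEFAULT_SCREEN
        out[(pid, tid)] = RawTrajectory(
            participant_id=pid,
            trial_id=tid,
            t=t,
            x=x,
            y=y,
            page_load_t=int(t[0]),
            final_click=(int(t[-1]), int(x[-1]), int(y[-1])),
            screen=screen,
        )
    return out


def write_trajectories(trajectories, path) -> None:
    """Write RawTrajectory objects to the trajectory-log schema."""
    path = Path(path)
    rows = []
    trajs = trajectories.values() if isinstance(trajectories, dict) else trajectories
    for traj in trajs:
        n = traj.n_samples
        for i in range(n):
            event = "load" if i == 0 else ("click" if i == n - 1 else "move")
            rows.append(
                {
                    "participant_id": traj.participant_id,
                    "trial_id": traj.trial_id,
                    "t_ms": int(traj.t[i]),
                    "x_px": int(traj.x[i]),
                    "y_px": int(traj.y[i]),
                    "event": event,
                    "screen_w": traj.screen[0],
                    "screen_h": traj.screen[1],
                }
            )
    df = pd.DataFrame(rows)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows))
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trials and survey tables

def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    _require_columns(df, TRIAL_COLUMNS, path)
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)
    for col, allowed in (
        ("site_type", SITE_TYPES),
        ("auth_level", AUTH_LEVELS),
        ("response", RESPONSES),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise SchemaError(f"{path}: bad {col} at row {row}")
    if "usable" not in df.columns:
        df["usable"] = 1
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records")))
    else:
        df.to_csv(path, index=False)


def read_surveys(path) -> pd.DataFrame:
    """Read the survey schema and append derived scores.

    Adds ``knowledge`` (fraction correct) and ``indicator_score`` columns.
    """
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, SURVEY_BASE_COLUMNS, path)
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    kc = _int_column(df, "knowledge_correct", path)
    if np.any((kc < 0) | (kc > survey_mod.N_KNOWLEDGE_ITEMS)):
        raise ValidationError(f"{path}: knowledge_correct outside 0..10")
    df["knowledge"] = kc / survey_mod.N_KNOWLEDGE_ITEMS
    df["indicator_score"] = [
        survey_mod.score_indicators(int(c), int(i))
        for c, i in zip(df["indicators_correct"], df["indicators_incorrect"])
    ]
    fam_cols = [c for c in df.columns if c.startswith("familiarity_")]
    for col in fam_cols:
        vals = _int_column(df, col, path)
        if np.any((vals < 1) | (vals > 5)):
            raise ValidationError(f"{path}: {col} outside 1..5")
    return df


def write_surveys(df: pd.DataFrame, path) -> None:
    path = Path(path)
    drop = [c for c in ("knowledge", "indicator_score") if c in df.columns]
    out = df.drop(columns=drop)
    if path.suffix == ".json":
        path.write_text(json.dumps(out.to_dict(orient="records")))
    else:
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# join

MEASURE_COLUMNS = ("auc", "se_raw", "se_log", "rt_s")


def ensure_survey_scores(surveys: pd.DataFrame) -> pd.DataFrame:
    """Derive knowledge and indicator_score columns if absent."""
    surveys = surveys.copy()
    if "knowledge" not in surveys.columns:
        surveys["knowledge"] = (
            surveys["knowledge_correct"] / survey_mod.N_KNOWLEDGE_ITEMS
        )
    if "indicator_score" not in surveys.columns:
        surveys["indicator_score"] = [
            survey_mod.score_indicators(int(c), int(i))
            for c, i in zip(
                surveys["indicators_correct"], surveys["indicators_incorrect"]
            )
        ]
    return surveys


def flag_single_response_participants(trials: pd.DataFrame) -> pd.Series:
    """True for participants who made only one type of response."""
    n_resp = trials.groupby("participant_id")["response"].nunique()
    single = n_resp[n_resp < 2].index
    return trials["participant_id"].isin(single)


def build_analysis_table(
    trajectories: dict[tuple[str, str], RawTrajectory],
    trials: pd.DataFrame,
    surveys: pd.DataFrame,
    *,
    drop_unusable: bool = True,
    drop_single_response: bool = False,
) -> pd.DataFrame:
    """Join the three schemas into one per-trial analysis table.

    Measure columns (``auc``, ``se_raw``, ``se_log``, ``rt_s``) are created
    empty; the kinematics and entropy stages fill them.  Exclusions are
    flag columns; rows are dropped only when the corresponding switch is on.
    """
    surveys = ensure_survey_scores(surveys)
    surveys = surveys.set_index("participant_id", drop=False)
    missing_surveys = sorted(
        set(trials["participant_id"]) - set(surveys["participant_id"])
    )
    if missing_surveys:
        raise JoinError(f"no survey record for participant(s): {missing_surveys}")
    missing_traj = [
        (p, t)
        for p, t in zip(trials["participant_id"], trials["trial_id"])
        if (p, t) not in trajectories
    ]
    if missing_traj:
        raise JoinError(f"no trajectory for trial(s): {missing_traj[:5]}")

    rows = []
    for rec in trials.to_dict(orient="records"):
        pid = rec["participant_id"]
        srow = surveys.loc[pid]
        traj = trajectories[(pid, rec["trial_id"])]
        traj.response = rec["response"]
        site = rec.get("site")
        fam_col = f"familiarity_{site}" if site is not None else None
        if fam_col is not None and fam_col in surveys.columns:
            familiarity = int(srow[fam_col])
        elif "familiarity" in surveys.columns:
            familiarity = int(srow["familiarity"])
        else:
            raise JoinError(
                f"participant {pid}: no familiarity rating for site {site!r}"
            )
        rows.append(
            {
                "participant_id": pid,
                "trial_id": rec["trial_id"],
                "site": site,
                "site_type": rec["site_type"],
                "auth_level": rec["auth_level"],
                "response": rec["response"],
                "accuracy": derive_accuracy(rec["site_type"], rec["response"]),
                "familiarity": familiarity,
                "knowledge": float(srow["knowledge"]),
                "indicator_score": float(srow["indicator_score"]),
                "usable": int(rec.get("usable", 1)),
            }
        )
    table = pd.DataFrame(rows)
    table["single_response"] = flag_single_response_participants(table).astype(int)
    for col in MEASURE_COLUMNS:
        table[col] = np.nan
    if drop_unusable:
        table = table[table["usable"] == 1].reset_index(drop=True)
    if drop_single_response:
        table = table[table["single_response"] == 0].reset_index(drop=True)
    return table
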