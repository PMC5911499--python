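"""Trajectory normalization and the spatial/temporal decision measures.

A raw screen-pixel trajectory is mapped by a similarity transform
(translate, uniform scale, rotate, plus a single y-axis flip from screen
to math coordinates) into a canonical frame: the first sample sits at the
origin and the final response click sits at distance 1, on the 45-degree
ray for login responses and the 135-degree ray for back responses.

AUC is the signed shoelace area of the closed curve formed by the
trajectory and the reversed chord; positive values indicate net deviation
toward the non-chosen response's side of the chord.  AUC is purely
spatial — timestamps are carried through but never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import RawTrajectory
from .errors import DegenerateTrajectoryError, ValidationError

LOGIN_ANGLE = np.pi / 4  # 45 degrees
BACK_ANGLE = 3 * np.pi / 4  # 135 degrees


@dataclass
class NormalizedTrajectory:
    """Trajectory in the canonical unit frame (math coordinates, y up)."""

    t: np.ndarray  # ms, unchanged from the raw trajectory
    x: np.ndarray
    y: np.ndarray
    response: str

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def response_angle(response: str) -> float:
    if response == "login":
        return LOGIN_ANGLE
    if response == "back":
        return BACK_ANGLE
    raise ValidationError(f"unknown response {response!r}")


def normalize_trajectory(
    raw: RawTrajectory, response: str | None = None
) -> NormalizedTrajectory:
    """Map a raw screen-pixel trajectory into the canonical unit frame.

    ``response`` overrides ``raw.response`` (useful before the trial join
    has attached responses to trajectories).
    """
    response = response or raw.response
    if response is None:
        raise ValidationError(
            f"trial {raw.participant_id}/{raw.trial_id}: response unknown"
        )
    t = np.asarray(raw.t, dtype=float)
    x = np.asarray(raw.x, dtype=float)
    y = np.asarray(raw.y, dtype=float)
    ct, cx, cy = raw.final_click
    if x[-1] != cx or y[-1] != cy:
        # ensure the final click is the last point of the path
        x = np.append(x, float(cx))
        y = np.append(y, float(cy))
        t = np.append(t, float(ct))

    # screen -> math coordinates: flip y once
    px = x - x[0]
    py = -(y - y[0])
    chord = np.array([px[-1], py[-1]])
    length = float(np.hypot(*chord))
    if length == 0.0:
        raise DegenerateTrajectoryError(
            f"trial {raw.participant_id}/{raw.trial_id}: zero-length chord"
        )
    theta = response_angle(response) - np.arctan2(chord[1], chord[0])
    c, s = np.cos(theta), np.sin(theta)
    nx = (c * px - s * py) / length
    ny = (s * px + c * py) / length
    return NormalizedTrajectory(t=t, x=nx, y=ny, response=response)


def compute_auc(traj: NormalizedTrajectory) -> float:
    """Signed area between the trajectory and its chord.

    Shoelace area of the polygon (path followed by the reversed chord),
    signed so that deviation toward the non-chosen alternative's side of
    the chord is positive.
    """
    x, y = traj.x, traj.y
    if x.size < 2:
        raise ValidationError("need at least 2 samples for AUC")
    # closed polygon: the chord is the straight closing edge
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    shoelace = 0.5 * float(np.sum(cross))
    # Walking the chord toward 45 deg (login), the alternative's (135 deg)
    # side is the left, where shoelace area is negative -> flip for login.
    return shoelace if traj.response == "back" else -shoelace


def compute_rt(raw: RawTrajectory) -> float:
    """Seconds from page load to the final response click."""
    ct = raw.final_click[0]
    if ct <= raw.page_load_t:
        raise ValidationError(
            f"trial {raw.participant_id}/{raw.trial_id}: "
            "final click does not follow page load"
        )
    return (ct - raw.page_load_t) / 1000.0


def distance_to_endpoint_series(traj: NormalizedTrajectory) -> np.ndarray:
    """Euclidean distance of every sample from the final response point.

    The series that the entropy stage operates on; invariant to the
    normalization's rotation (it is an isometry).
    """
    if traj.x.size < 2:
        raise ValidationError("need at least 2 samples")
    return np.hypot(traj.x - traj.x[-1], traj.y - traj.y[-1])
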