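"""Track-quality filtering and phase labelling.

Tracking software occasionally swaps or teleports identities, producing
physically impossible steps.  Points implying an instantaneous speed above
50 cm/s, or a single-step Euclidean displacement above 50 cm, from the
previously *retained* detection of the same fish are removed.  Removal is
implemented as marking the point invisible rather than deleting the row, so
that visibility-based refuge accounting stays consistent: a filtered point is
one the tracker effectively never saw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .arena import ArenaConfig
from .errors import CoverageError
from .io import validate_trajectories

__all__ = ["filter_tracks", "label_phases", "TrackFilter"]


def _flag_impossible(
    frames: np.ndarray, x: np.ndarray, y: np.ndarray, fps: float,
    speed_limit: float, jump_limit: float,
) -> np.ndarray:
    """Boolean mask of points to remove, walking visible detections in order.

    The comparison is always against the last retained point, so a removed
    point does not become the reference for the next one; speed across a
    frame gap uses the elapsed time over the gap.
    """
    n = len(frames)
    remove = np.zeros(n, dtype=bool)
    if n == 0:
        return remove
    last = 0
    for i in range(1, n):
        dt = (frames[i] - frames[last]) / fps
        d = float(np.hypot(x[i] - x[last], y[i] - y[last]))
        if d > jump_limit or d / dt > speed_limit:
            remove[i] = True
        else:
            last = i
    return remove


def filter_tracks(traj: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Mark impossible detections invisible; return a copy.

    After filtering, every consecutive pair of retained detections of the
    same fish satisfies both the speed and the displacement limit, which
    makes the operation idempotent.
    """
    out = traj.copy()
    if out.empty:
        return out
    visible = out[out["visible"]]
    for _, idx in visible.groupby(["trial_id", "fish_id"], sort=False).indices.items():
        rows = visible.index[idx]
        sub = out.loc[rows]
        remove = _flag_impossible(
            sub["frame"].to_numpy(),
            sub["x"].to_numpy(),
            sub["y"].to_numpy(),
            arena.fps,
            arena.speed_limit_cm_s,
            arena.jump_limit_cm,
        )
        out.loc[rows[remove], "visible"] = False
    return out


def label_phases(
    traj: pd.DataFrame, screen_lift_frame: int, arena: ArenaConfig
) -> pd.DataFrame:
    """Attach a ``phase`` column ('before' / 'during' / '' = excluded).

    The 'before' window is the 7 minutes immediately prior to the screen
    starting to lift; 'during' is the 7 minutes starting 30 s after the
    lift.  Raises CoverageError when the recording cannot cover both
    windows.
    """
    windows = arena.phase_windows(screen_lift_frame)
    frame_min = int(traj["frame"].min())
    frame_max = int(traj["frame"].max())
    shortfalls = []
    if windows.before[0] < frame_min:
        shortfalls.append(
            f"'before' window starts at frame {windows.before[0]} but the "
            f"recording starts at {frame_min}"
        )
    if windows.during[1] > frame_max + 1:
        shortfalls.append(
            f"'during' window ends at frame {windows.during[1]} but the "
            f"recording ends at {frame_max + 1}"
        )
    if shortfalls:
        raise CoverageError("; ".join(shortfalls))
    out = traj.copy()
    out["phase"] = windows.label(out["frame"].to_numpy())
    return out


class TrackFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapping quality filtering and phase labelling.

    Parameters
    ----------
    arena : ArenaConfig
        Geometry and thresholds.
    screen_lift_frames : mapping trial_id -> int, optional
        Per-trial screen-lift frame (determined manually per video).  When
        given, transform also labels phases.
    """

    def __init__(self, arena: ArenaConfig | None = None,
                 screen_lift_frames: dict | None = None):
        self.arena = arena
        self.screen_lift_frames = screen_lift_frames

    def fit(self, X: pd.DataFrame, y=None):
        validate_trajectories(X)
        self.arena_ = self.arena if self.arena is not None else ArenaConfig()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "arena_"):
            self.fit(X)
        out = filter_tracks(X, self.arena_)
        if self.screen_lift_frames is not None:
            parts = []
            for trial_id, sub in out.groupby("trial_id", sort=False):
                parts.append(
                    label_phases(sub, int(self.screen_lift_frames[trial_id]), self.arena_)
                )
            out = pd.concat(parts, ignore_index=True)
        return out
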