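"""Per-fish inspection behaviour and refuge use.

An *inspection* is operationalized as presence of a tracked fish within
30 cm of the predator model while the model is visible (the 'during' phase).
An inspection *event* is a maximal run of consecutive visible in-zone
frames; a gap of invisibility or an out-of-zone frame ends the event (a
configurable gap tolerance, default 0 frames, can bridge short tracking
dropouts).  Five response variables are computed per fish:

- number of inspections,
- mean duration of its inspection events (s),
- overall proportion of the 7-minute phase spent inspecting,
- mean distance of its inspections (mean over events of the per-event mean
  distance to the model, cm),
- distance of its closest inspection (cm).

Refuge use is the proportion of a phase the fish was not visible to the
tracker, since fish under plant cover cannot be tracked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from sklearn.base import BaseEstimator, TransformerMixin

from .arena import ArenaConfig
from .errors import CoverageError

__all__ = [
    "distance_to_predator",
    "distances_to_predator",
    "detect_inspections",
    "summarize_behavior",
    "refuge_use",
    "group_inspections",
    "BehaviorScorer",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "trial_id",
    "fish_id",
    "start_frame",
    "end_frame",
    "duration_s",
    "min_distance_cm",
    "mean_distance_cm",
]


def distance_to_predator(pos: tuple[float, float], arena: ArenaConfig) -> float:
    """Minimum Euclidean distance (cm) from a point to any part of the
    predator model; 0 if the point lies on or inside the outline."""
    return arena.distance_to_predator(pos[0], pos[1])


def distances_to_predator(xy: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Vectorised distance to the predator polygon for an (n, 2) array."""
    pts = shapely.points(np.asarray(xy, dtype=float))
    return shapely.distance(arena.predator_shape, pts)


def detect_inspections(
    traj: pd.DataFrame,
    arena: ArenaConfig,
    gap_tolerance_frames: int = 0,
) -> pd.DataFrame:
    """Detect inspection events in the 'during' phase.

    Returns a tidy table with one row per event (columns EVENT_COLUMNS).
    ``start_frame``/``end_frame`` are half-open; durations are in seconds;
    distances are the min and mean of the per-frame distances to the model.
    """
    if "phase" not in traj.columns:
        raise ValueError("trajectory must be phase-labelled (run label_phases first)")
    during = traj[(traj["phase"] == "during") & traj["visible"]]
    records: list[dict] = []
    for (trial_id, fish_id), sub in during.groupby(["trial_id", "fish_id"], sort=False):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        dist = distances_to_predator(sub[["x", "y"]].to_numpy(), arena)
        in_zone = dist <= arena.inspection_radius_cm
        for i, j in _zone_runs(frames, in_zone, gap_tolerance_frames):
            d = dist[i:j][in_zone[i:j]]
            start, end = int(frames[i]), int(frames[j - 1]) + 1
            records.append(
                {
                    "trial_id": trial_id,
                    "fish_id": fish_id,
                    "start_frame": start,
                    "end_frame": end,
                    "duration_s": (end - start) / arena.fps,
                    "min_distance_cm": float(d.min()),
                    "mean_distance_cm": float(d.mean()),
                }
            )
    return pd.DataFrame(records, columns=EVENT_COLUMNS)


def _zone_runs(
    frames: np.ndarray, in_zone: np.ndarray, gap_tolerance: int
) -> list[tuple[int, int]]:
    """Maximal runs (as [i, j) row-index ranges) of in-zone rows.

    Rows strictly between two consecutive in-zone rows are, by
    construction, out-of-zone or missing frames; the two rows belong to the
    same event when that frame gap is at most ``gap_tolerance`` (default 0:
    events must be frame-contiguous).
    """
    idx = np.flatnonzero(in_zone)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if frames[i] - frames[prev] - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def refuge_use(
    traj: pd.DataFrame, phase: str, arena: ArenaConfig | None = None
) -> pd.Series:
    """Proportion of the phase each fish was not visible (refuge proxy).

    The denominator is the full phase window (phase_duration_s * fps
    frames); a fish with no row at a frame counts as not visible there.
    """
    if phase not in ("before", "during"):
        raise ValueError(f"phase must be 'before' or 'during', got {phase!r}")
    arena = arena if arena is not None else ArenaConfig()
    sub = traj[traj["phase"] == phase]
    if sub.empty:
        raise CoverageError(f"no frames labelled {phase!r} in trajectory")
    total = arena.phase_frames
    visible = sub[sub["visible"]].groupby(["trial_id", "fish_id"])["frame"].nunique()
    all_fish = traj.groupby(["trial_id", "fish_id"]).size().index
    visible = visible.reindex(all_fish, fill_value=0)
    return (1.0 - visible / total).rename(f"refuge_prop_{phase}")


def summarize_behavior(
    events: pd.DataFrame, traj: pd.DataFrame, arena: ArenaConfig | None = None
) -> pd.DataFrame:
    """Per-fish behaviour summary joining inspection metrics and refuge use.

    One row per (trial_id, fish_id) present in ``traj``.  Distance and
    duration fields are NaN for fish with no inspection events;
    ``prop_time_inspecting`` is total inspecting time over the 420 s phase.
    """
    arena = arena if arena is not None else ArenaConfig()
    fish = traj.groupby(["trial_id", "fish_id"]).size().index.to_frame(index=False)
    if len(events):
        agg = events.groupby(["trial_id", "fish_id"]).agg(
            n_inspections=("duration_s", "size"),
            mean_event_duration_s=("duration_s", "mean"),
            total_inspecting_s=("duration_s", "sum"),
            min_inspection_distance_cm=("min_distance_cm", "min"),
            mean_inspection_distance_cm=("mean_distance_cm", "mean"),
        )
    else:
        agg = pd.DataFrame(
            columns=[
                "trial_id",
                "fish_id",
                "n_inspections",
                "mean_event_duration_s",
                "total_inspecting_s",
                "min_inspection_distance_cm",
                "mean_inspection_distance_cm",
            ]
        ).set_index(["trial_id", "fish_id"])
    out = fish.merge(agg, on=["trial_id", "fish_id"], how="left")
    out["n_inspections"] = (
        pd.to_numeric(out["n_inspections"]).fillna(0).astype(int)
    )
    out["total_inspecting_s"] = pd.to_numeric(out["total_inspecting_s"]).fillna(0.0)
    out["prop_time_inspecting"] = out["total_inspecting_s"] / arena.phase_duration_s
    out = out.drop(columns="total_inspecting_s")
    for phase in ("before", "during"):
        r = refuge_use(traj, phase, arena)
        out = out.merge(r.reset_index(), on=["trial_id", "fish_id"], how="left")
    return out


def group_inspections(events: pd.DataFrame) -> pd.DataFrame:
    """Merge temporally overlapping inspection events into group inspections.

    Events whose half-open frame intervals overlap are merged transitively
    (connected components of the interval-overlap graph) within a trial.
    Returns one row per group inspection with the merged interval, the set
    of inspector ids and their count.
    """
    records = []
    for trial_id, sub in events.groupby("trial_id", sort=False):
        sub = sub.sort_values(["start_frame", "end_frame"]).reset_index(drop=True)
        cur_start = cur_end = None
        members: set = set()
        for row in sub.itertuples(index=False):
            if cur_start is None or row.start_frame >= cur_end:
                if cur_start is not None:
                    records.append(
                        _group_record(trial_id, cur_start, cur_end, members)
                    )
                cur_start, cur_end = row.start_frame, row.end_frame
                members = {row.fish_id}
            else:
                cur_end = max(cur_end, row.end_frame)
                members.add(row.fish_id)
        if cur_start is not None:
            records.append(_group_record(trial_id, cur_start, cur_end, members))
    return pd.DataFrame(
        records,
        columns=["trial_id", "start_frame", "end_frame", "inspector_ids", "n_inspectors"],
    )


def _group_record(trial_id, start, end, members: set) -> dict:
    return {
        "trial_id": trial_id,
        "start_frame": int(start),
        "end_frame": int(end),
        "inspector_ids": tuple(sorted(members)),
        "n_inspectors": len(members),
    }


class BehaviorScorer(BaseEstimator, TransformerMixin):
    """Transformer: phase-labelled trajectories -> per-fish behaviour table.

    ``transform`` returns the BehaviorSummary table; the detected events and
    merged group inspections from the last call are kept on ``events_`` and
    ``group_inspections_``.
    """

    def __init__(self, arena: ArenaConfig | None = None, gap_tolerance_frames: int = 0):
        self.arena = arena
        self.gap_tolerance_frames = gap_tolerance_frames

    def fit(self, X: pd.DataFrame, y=None):
        self.arena_ = self.arena if self.arena is not None else ArenaConfig()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "arena_"):
            self.fit(X)
        self.events_ = detect_inspections(X, self.arena_, self.gap_tolerance_frames)
        self.group_inspections_ = group_inspections(self.events_)
        return summarize_behavior(self.events_, X, self.arena_)
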