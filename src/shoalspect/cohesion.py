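"""Group cohesion and sub-group structure.

Cohesion is measured as group density: the Voronoi tessellation of the
visible fish positions is clipped to the arena rectangle (so boundary cells
are finite), each fish's local density is the inverse of its cell area, and
the group value is the median over fish.  Densities are computed once per
second (using each fish's first visible detection in that second), then
aggregated to a per-minute median, giving a 14-point series per trial
(7 minutes before the predator is revealed, 7 during).

Sub-groups are density-connected clusters under DBSCAN with a reachability
distance of 6 cm (about four guppy body lengths) and a minimum
neighbourhood of 2, which makes the procedure equivalent to chain-rule
connectivity while excluding lone individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN

from .arena import ArenaConfig

__all__ = [
    "voronoi_cell_areas",
    "voronoi_density",
    "subgroups",
    "density_series",
    "subgroup_series",
    "cohesion_series",
    "CohesionScorer",
]


def voronoi_cell_areas(positions: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Area (cm^2) of each fish's Voronoi cell, clipped to the arena.

    Coincident points are perturbed by 1e-6 cm with a warning.  The areas
    partition the arena: they sum to width * height.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (x, y) positions")
    if len(np.unique(pts, axis=0)) < len(pts):
        warnings.warn("coincident positions perturbed by 1e-6 cm", stacklevel=2)
        rng = np.random.default_rng(0)
        while len(np.unique(pts, axis=0)) < len(pts):
            dup = pd.DataFrame(pts).duplicated().to_numpy()
            pts[dup] += rng.uniform(-1e-6, 1e-6, size=(dup.sum(), 2))
    arena_box = box(0.0, 0.0, arena.width_cm, arena.height_cm)
    cells = voronoi_diagram(MultiPoint(pts), envelope=arena_box)
    areas = np.empty(len(pts))
    areas.fill(np.nan)
    clipped = [cell.intersection(arena_box) for cell in cells.geoms]
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for cell in clipped:
            if cell.covers(p):
                areas[i] = cell.area
                break
    if np.isnan(areas).any():  # point on a cell edge after clipping
        for i in np.flatnonzero(np.isnan(areas)):
            p = Point(pts[i])
            areas[i] = min(clipped, key=lambda c: c.distance(p)).area
    return areas


def voronoi_density(positions: np.ndarray, arena: ArenaConfig) -> float:
    """Median over fish of 1 / Voronoi-cell-area (1/cm^2).

    Returns NaN when fewer than two fish are visible.
    """
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 2:
        return float("nan")
    return float(np.median(1.0 / voronoi_cell_areas(pts, arena)))


def subgroups(positions: np.ndarray, reach_cm: float = 6.0) -> list[int]:
    """Sizes of shoaling sub-groups among the given positions.

    DBSCAN with eps = ``reach_cm`` and min_samples = 2: clusters are the
    connected components of the <= reach_cm proximity graph; singletons are
    not clusters.  Returns sizes (each >= 2), descending.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        return []
    if len(pts) == 1:
        return []
    labels = DBSCAN(eps=reach_cm, min_samples=2).fit(pts).labels_
    sizes = np.bincount(labels[labels >= 0]) if (labels >= 0).any() else np.array([], int)
    return sorted((int(s) for s in sizes if s >= 2), reverse=True)


def _second_positions(traj: pd.DataFrame, arena: ArenaConfig):
    """Yield (trial_id, phase, minute_index, positions) per second.

    The fish's position in a second is its first visible detection within
    that second; minutes are indexed 1..7 (before) and 8..14 (during).
    """
    if "phase" not in traj.columns:
        raise ValueError("trajectory must be phase-labelled (run label_phases first)")
    fps = arena.fps
    phased = traj[traj["phase"].isin(["before", "during"])]
    for (trial_id, phase), sub in phased.groupby(["trial_id", "phase"], sort=False):
        # anchor seconds to the phase-window start (first frame of the phase)
        window_start = int(sub["frame"].min())
        vis = sub[sub["visible"]]
        if vis.empty:
            continue
        second = (vis["frame"].to_numpy() - window_start) // fps
        firsts = (
            vis.assign(second=second)
            .sort_values("frame")
            .groupby(["second", "fish_id"], sort=True)
            .first()
        )
        for sec, grp in firsts.groupby(level="second"):
            minute_in_phase = int(sec) // 60
            if minute_in_phase >= 7:
                continue
            minute_index = minute_in_phase + 1 + (7 if phase == "during" else 0)
            yield trial_id, phase, minute_index, grp[["x", "y"]].to_numpy()


def density_series(traj: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Per-minute median group density (1/cm^2): 14 rows per trial.

    Seconds with fewer than two visible fish contribute no value; a minute
    with no valid seconds yields NaN.
    """
    return _minute_series(traj, arena, "median_density", _density_of_second)


def subgroup_series(traj: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Per-minute median sub-group size: 14 rows per trial.

    Seconds in which no cluster of >= 2 fish exists contribute no value.
    """
    return _minute_series(traj, arena, "median_subgroup_size", _subgroup_of_second)


def _density_of_second(positions: np.ndarray, arena: ArenaConfig) -> float:
    if len(positions) < 2:
        return float("nan")
    return voronoi_density(positions, arena)


def _subgroup_of_second(positions: np.ndarray, arena: ArenaConfig) -> float:
    sizes = subgroups(positions)
    return float(np.median(sizes)) if sizes else float("nan")


def _minute_series(traj, arena, value_name, second_fn) -> pd.DataFrame:
    rows: dict[tuple, list[float]] = {}
    trials = traj["trial_id"].unique()
    for trial_id, phase, minute_index, positions in _second_positions(traj, arena):
        v = second_fn(positions, arena)
        if np.isfinite(v):
            rows.setdefault((trial_id, minute_index, phase), []).append(v)
    records = []
    for trial_id in trials:
        for minute_index in range(1, 15):
            phase = "before" if minute_index <= 7 else "during"
            vals = rows.get((trial_id, minute_index, phase), [])
            records.append(
                {
                    "trial_id": trial_id,
                    "minute_index": minute_index,
                    "phase": phase,
                    value_name: float(np.median(vals)) if vals else float("nan"),
                }
            )
    return pd.DataFrame(records)


def cohesion_series(traj: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Joint per-minute table of median density and median sub-group size."""
    dens = density_series(traj, arena)
    sub = subgroup_series(traj, arena)
    return dens.merge(sub, on=["trial_id", "minute_index", "phase"])


class CohesionScorer(BaseEstimator, TransformerMixin):
    """Transformer: phase-labelled trajectories -> per-minute cohesion table."""

    def __init__(self, arena: ArenaConfig | None = None):
        self.arena = arena

    def fit(self, X: pd.DataFrame, y=None):
        self.arena_ = self.arena if self.arena is not None else ArenaConfig()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "arena_"):
            self.fit(X)
        return cohesion_series(X, self.arena_)
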