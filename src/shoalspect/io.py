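"""Ingest of tracker-style CSV exports and trial metadata.

A trajectory table holds one row per (fish, frame): columns ``trial_id``,
``fish_id``, ``frame``, ``x``, ``y``, ``visible``.  Positions are arena-frame
centimetres.  Rows without coordinates are kept but flagged invisible —
invisibility doubles as the refuge-use proxy, so dropped detections must not
silently vanish from the denominator.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaConfig
from .errors import DataError, FormatError

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_tracking",
    "read_trial_meta",
    "validate_trajectories",
]

TRAJECTORY_COLUMNS = ["trial_id", "fish_id", "frame", "x", "y", "visible"]

_REQUIRED_META = ["trial_id", "group_size", "temperature_c", "mean_length_mm"]
_VALID_GROUP_SIZES = (5, 10, 20)


def read_tracking(
    path: str | Path, arena: ArenaConfig, trial_id: str | None = None
) -> pd.DataFrame:
    """Read one trial's tracking CSV into a validated trajectory table.

    The file must have columns ``frame``, ``id``, ``x``, ``y`` and may have a
    boolean ``visible`` column.  Rows with missing coordinates are flagged
    ``visible=False``; coordinates outside the arena raise a warning and are
    likewise flagged.

    Raises
    ------
    FormatError
        If a required column is missing.
    DataError
        If (fish, frame) pairs are duplicated or frames are unsorted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"frame", "id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing required columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "trial_id": trial_id if trial_id is not None else path.stem,
            "fish_id": df["id"],
            "frame": df["frame"].astype(int),
            "x": pd.to_numeric(df["x"], errors="coerce"),
            "y": pd.to_numeric(df["y"], errors="coerce"),
        }
    )
    if "visible" in df.columns:
        out["visible"] = df["visible"].astype(bool)
    else:
        out["visible"] = True
    no_coords = out["x"].isna() | out["y"].isna()
    out.loc[no_coords, "visible"] = False

    in_arena = (
        (out["x"] >= 0)
        & (out["x"] <= arena.width_cm)
        & (out["y"] >= 0)
        & (out["y"] <= arena.height_cm)
    )
    bad = out["visible"] & ~no_coords & ~in_arena
    if bad.any():
        warnings.warn(
            f"{path.name}: {int(bad.sum())} positions outside the arena flagged invalid",
            stacklevel=2,
        )
        out.loc[bad, "visible"] = False

    validate_trajectories(out)
    return out.reset_index(drop=True)


def validate_trajectories(traj: pd.DataFrame) -> None:
    """Check trajectory-table invariants, raising DataError on violation."""
    for col in ("trial_id", "fish_id", "frame", "x", "y", "visible"):
        if col not in traj.columns:
            raise FormatError(f"trajectory table missing column {col!r}")
    dup = traj.duplicated(subset=["trial_id", "fish_id", "frame"])
    if dup.any():
        pair = traj.loc[dup.idxmax(), ["fish_id", "frame"]].tolist()
        raise DataError(f"duplicated (fish, frame) pair, e.g. {tuple(pair)}")
    frames = traj.groupby(["trial_id", "fish_id"], sort=False)["frame"]
    if (frames.diff().dropna() <= 0).any():
        raise DataError("frames not strictly increasing within a fish track")


def read_trial_meta(path: str | Path) -> pd.DataFrame:
    """Read the trial metadata table.

    Required columns: trial_id, group_size (one of 5/10/20), temperature_c,
    mean_length_mm; an optional screen_lift_frame column carries the manually
    determined frame at which the concealing screen began to lift.
    """
    meta = pd.read_csv(path)
    missing = set(_REQUIRED_META) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing required columns {sorted(missing)}")
    if meta["trial_id"].duplicated().any():
        raise DataError("duplicated trial_id in metadata")
    bad = ~meta["group_size"].isin(_VALID_GROUP_SIZES)
    if bad.any():
        raise DataError(
            f"group_size must be one of {_VALID_GROUP_SIZES}; "
            f"got {sorted(meta.loc[bad, 'group_size'].unique())}"
        )
    return meta
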