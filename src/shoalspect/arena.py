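"""Arena and predator geometry, recording parameters, and analysis phases.

The experimental setting is a square pool in which a shoal of guppies
interacts with a stationary model predator.  All trajectory coordinates are
expressed in arena-frame centimetres with the origin at one pool corner and
y increasing away from it.  Two 7-minute observation phases are analysed:
``before`` (predator concealed) and ``during`` (predator visible, starting
30 s after the concealing screen begins to lift).  All frame intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = ["ArenaConfig", "DEFAULT_PREDATOR_POLYGON", "PhaseWindows"]

# Footprint of the model predator (roughly 17 cm x 5.5 cm), placed near the
# middle of one arena wall, in arena coordinates (cm).
DEFAULT_PREDATOR_POLYGON: tuple[tuple[float, float], ...] = (
    (66.5, 17.25),
    (83.5, 17.25),
    (83.5, 22.75),
    (66.5, 22.75),
)


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open frame windows ``[start, end)`` for the two analysis phases."""

    before: tuple[int, int]
    during: tuple[int, int]

    def label(self, frames: np.ndarray) -> np.ndarray:
        """Vectorised phase label per frame: 'before', 'during' or ''."""
        frames = np.asarray(frames)
        out = np.full(frames.shape, "", dtype=object)
        b0, b1 = self.before
        d0, d1 = self.during
        out[(frames >= b0) & (frames < b1)] = "before"
        out[(frames >= d0) & (frames < d1)] = "during"
        return out


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and timing of a trial.

    Parameters
    ----------
    width_cm, height_cm : float
        Arena dimensions (the pool is 150 cm x 150 cm).
    fps : int
        Video frame rate (25 frames per second).
    predator_polygon : sequence of (x, y)
        Vertices of the predator model outline, arena coordinates in cm.
    inspection_radius_cm : float
        Distance from the predator polygon within which a fish counts as
        inspecting (30 cm).
    speed_limit_cm_s : float
        Track-quality threshold: implied speeds above this are impossible
        (50 cm/s).
    jump_limit_cm : float
        Track-quality threshold on single-step Euclidean displacement (50 cm).
    phase_delay_s : float
        Delay between the screen starting to lift and the start of the
        'during' phase (30 s).
    phase_duration_s : float
        Length of each analysis phase (7 min = 420 s).
    """

    width_cm: float = 150.0
    height_cm: float = 150.0
    fps: int = 25
    predator_polygon: tuple[tuple[float, float], ...] = field(
        default=DEFAULT_PREDATOR_POLYGON
    )
    inspection_radius_cm: float = 30.0
    speed_limit_cm_s: float = 50.0
    jump_limit_cm: float = 50.0
    phase_delay_s: float = 30.0
    phase_duration_s: float = 420.0

    def __post_init__(self) -> None:
        for name in (
            "width_cm",
            "height_cm",
            "fps",
            "inspection_radius_cm",
            "speed_limit_cm_s",
            "jump_limit_cm",
            "phase_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.inspection_radius_cm >= min(self.width_cm, self.height_cm):
            raise ValueError("inspection_radius_cm must be smaller than the arena")
        poly = self.predator_shape
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("predator_polygon is not a valid polygon")
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0 or miny < 0 or maxx > self.width_cm or maxy > self.height_cm:
            raise ValueError("predator_polygon lies outside the arena")

    @property
    def predator_shape(self) -> Polygon:
        return Polygon(self.predator_polygon)

    @property
    def phase_frames(self) -> int:
        """Number of frames in one analysis phase."""
        return int(round(self.phase_duration_s * self.fps))

    @property
    def delay_frames(self) -> int:
        return int(round(self.phase_delay_s * self.fps))

    def phase_windows(self, screen_lift_frame: int) -> PhaseWindows:
        """Half-open frame windows for both phases given the screen-lift frame.

        'before' is the phase_duration window ending at the lift frame;
        'during' starts phase_delay after the lift.
        """
        n = self.phase_frames
        before = (screen_lift_frame - n, screen_lift_frame)
        d0 = screen_lift_frame + self.delay_frames
        during = (d0, d0 + n)
        return PhaseWindows(before=before, during=during)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width_cm and 0.0 <= y <= self.height_cm

    def distance_to_predator(self, x: float, y: float) -> float:
        """Minimum Euclidean distance from (x, y) to any part of the predator
        model; 0 for points on or inside the outline."""
        return float(self.predator_shape.distance(Point(x, y)))
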