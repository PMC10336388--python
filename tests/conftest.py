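import numpy as np
import pandas as pd
import pytest

from shoalspect import ArenaConfig
from shoalspect.simulate import TrialScenario, generate_trajectories


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


def make_traj(rows, trial_id="T01"):
    """Build a trajectory table from (fish_id, frame, x, y, visible) tuples."""
    df = pd.DataFrame(rows, columns=["fish_id", "frame", "x", "y", "visible"])
    df.insert(0, "trial_id", trial_id)
    return df


@pytest.fixture(scope="session")
def small_generated(arena):
    """One generated trial per group size, with ground truth (shared across
    tests; generation is deterministic in the seed)."""
    scenario = TrialScenario(n_trials_per_size={5: 1, 10: 1, 20: 1}, seed=3)
    traj, meta, truth = generate_trajectories(scenario, arena)
    return traj, meta, truth


@pytest.fixture(scope="session")
def labeled_generated(small_generated, arena):
    import shoalspect as ss

    traj, meta, truth = small_generated
    traj = ss.filter_tracks(traj, arena)
    lifts = dict(zip(meta["trial_id"], meta["screen_lift_frame"]))
    parts = [
        ss.label_phases(sub, lifts[tid], arena)
        for tid, sub in traj.groupby("trial_id")
    ]
    return pd.concat(parts, ignore_index=True), meta, truth
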