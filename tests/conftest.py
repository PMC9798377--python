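"""Shared fixtures: small simulated ensembles and hand-built trajectories."""

import numpy as np
import pytest

import trajmodes as tm


@pytest.fixture(scope="session")
def brownian_ensemble():
    """50 Brownian trajectories, D = 3 μm²/s, 500 frames at 50 fps."""
    sims = tm.matched_brownian_ensemble(3.0, [500] * 50, 0.02, seed=101)
    return tm.ensemble_from_ground_truth(sims)


@pytest.fixture(scope="session")
def brownian_sims():
    """Ground-truth objects backing ``brownian_ensemble``."""
    return tm.matched_brownian_ensemble(3.0, [500] * 50, 0.02, seed=101)


@pytest.fixture()
def square_walk():
    """Deterministic 4-point walk with hand-computable MSD: 1, 2, 5 μm²."""
    return tm.Trajectory(
        id="sq",
        frames=np.arange(4),
        x=np.array([0.0, 1.0, 1.0, 2.0]),
        y=np.array([0.0, 0.0, 1.0, 1.0]),
        dt=1.0,
    )


@pytest.fixture(scope="session")
def msd_oracle():
    """Independent TA-MSD oracle: explicit double loop over frame pairs."""

    def brute_force_ta_msd(traj):
        frames = list(traj.frames)
        pos = {f: (x, y) for f, x, y in zip(frames, traj.x, traj.y)}
        span = frames[-1] - frames[0]
        taus, values, counts = [], [], []
        for k in range(1, span + 1):
            sq = []
            for f in frames:
                if f + k in pos:
                    dx = pos[f + k][0] - pos[f][0]
                    dy = pos[f + k][1] - pos[f][1]
                    sq.append(dx * dx + dy * dy)
            if sq:
                taus.append(k * traj.dt)
                values.append(sum(sq) / len(sq))
                counts.append(len(sq))
        return taus, values, counts

    return brute_force_ta_msd


@pytest.fixture()
def stationary_trajectory():
    return tm.Trajectory(
        id="still",
        frames=np.arange(10),
        x=np.zeros(10),
        y=np.zeros(10),
        dt=0.5,
    )
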