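"""Shared fixtures: small synthetic runs and hand-built micro-systems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgblister import (BilayerAnalysis, RegionPartition, Topology, Trajectory,
                       center_frames, density_profile, generate_trajectory,
                       partition_regions, preset)


@pytest.fixture(scope="session")
def uni2_run():
    """A 30 µs (557-frame) UNI2 run with its planted truth."""
    cfg = preset("UNI2", seed=11, duration_scaled_us=30.0)
    traj, topo, truth = generate_trajectory(cfg)
    return cfg, traj, topo, truth


@pytest.fixture(scope="session")
def uni2_centered(uni2_run):
    """Centered UNI2 trajectory with its fitted region partition."""
    cfg, traj, topo, truth = uni2_run
    ctraj = center_frames(traj, topo)
    to_prof = density_profile(ctraj, topo, species="TO",
                              roles=("GLYC_A1", "GLYC_B", "GLYC_A3"))
    ph_prof = density_profile(ctraj, topo, species="POPC", role="PHOS")
    regions = partition_regions(to_prof, ph_prof)
    return cfg, ctraj, topo, truth, regions


@pytest.fixture(scope="session")
def sixteen_run():
    """A 101-frame SIXTEENX5 run (planted 17 nm disc aggregate)."""
    cfg = preset("SIXTEENX5", seed=5, duration_scaled_us=5.4)
    traj, topo, truth = generate_trajectory(cfg)
    return cfg, traj, topo, truth


@pytest.fixture
def regions_pm085():
    return RegionPartition(-0.85, 0.85)


def make_to_points_system(points_xy: np.ndarray, box_xy: float,
                          box_z: float = 9.0, z: float = 0.0,
                          n_frames: int = 1) -> tuple[Trajectory, Topology]:
    """Minimal TO system: one molecule (3 coincident-ish glycerol beads) per
    xy point, at midplane height ``z``.  For clustering-geometry tests."""
    points_xy = np.asarray(points_xy, dtype=float)
    n = len(points_xy)
    rows = []
    for m in range(n):
        for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
            rows.append((len(rows), m, "TO", role))
    topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule", "species",
                                                "role"]))
    off = np.array([[0.02, 0.0, 0.02], [0.0, 0.0, -0.02], [-0.02, 0.0, 0.0]])
    pos = np.zeros((n_frames, 3 * n, 3))
    for m in range(n):
        base = np.array([points_xy[m, 0], points_xy[m, 1], z])
        pos[:, 3 * m: 3 * m + 3, :] = base + off
    pos[:, :, :2] %= box_xy
    boxes = np.tile([box_xy, box_xy, box_z], (n_frames, 1))
    times = np.arange(n_frames) * 13500.0
    return Trajectory(pos, boxes, times), topo


@pytest.fixture
def to_points_factory():
    return make_to_points_system
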