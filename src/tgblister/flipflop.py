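"""Inter-leaflet translocation (flip-flop) detection and rate estimation.

A flip-flop event is recorded every time the glycerol-backbone centre of mass
of a molecule translocates from one interfacial region to the other.  The
detector is a three-state machine over the region-state sequence (LOWER /
MIDDLE / UPPER): an event fires when a molecule whose last interfacial state
was one interface first reaches the opposite one; excursions into the middle
that return to the same interface emit nothing.  Rates are reported
system-wide in events per µs of *scaled* sampling time with a Poisson
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, Trajectory, glycerol_com_z
from .density import RegionPartition

STATE_NAMES = {-1: "LOWER", 0: "MIDDLE", 1: "UPPER"}


@dataclass
class FlipFlopResult:
    """Detected events and the system-wide rate in scaled time."""

    events: pd.DataFrame          # columns: molecule, frame, time_us, direction
    rate_per_us: float
    rate_se_per_us: float         # Poisson standard error sqrt(N)/T
    analyzed_time_us: float
    species: str
    n_molecules: int
    per_molecule_rate_per_us: float = 0.0
    extra: dict = field(default_factory=dict)


def region_state_series(traj: Trajectory, topology: Topology,
                        regions: RegionPartition, species: str = "TO",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame region state of every molecule of a species.

    Returns (molecule ids (m,), states (n_frames, m)) with states -1/0/+1 for
    LOWER/MIDDLE/UPPER, classified from the glycerol-backbone COM z (exact
    boundary hits are MIDDLE).  Molecules without glycerol beads raise.
    """
    mols, z = glycerol_com_z(traj, topology, species)
    return mols, regions.classify(z)


def detect_events(states: np.ndarray) -> list[tuple[int, int]]:
    """Flip-flop events in one molecule's state sequence.

    Returns a list of (frame index, direction) with direction +1 (up) or -1
    (down).  Initial MIDDLE frames are skipped until the first interfacial
    state; thereafter an event fires whenever the opposite interface is first
    reached.  No dwell-time filter: the "last interfacial state" memory
    already suppresses boundary-recrossing double counts.
    """
    states = np.asarray(states)
    if states.size == 0:
        return []
    events: list[tuple[int, int]] = []
    last_interface = 0
    for i, s in enumerate(states):
        if s == 0:
            continue
        if last_interface == 0:
            last_interface = int(s)
        elif s != last_interface:
            events.append((i, int(s)))
            last_interface = int(s)
    return events


def flipflop_rate(traj: Trajectory, topology: Topology,
                  regions: RegionPartition, species: str = "TO",
                  time_scale_factor: float | None = None) -> FlipFlopResult:
    """System-wide flip-flop rate of a species over the trajectory.

    ``analyzed_time`` is the scaled time between the first and last frame.
    The time scale factor defaults to the trajectory's own; passing one
    overrides it.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate a rate")
    tsf = traj.time_scale_factor if time_scale_factor is None else time_scale_factor
    times_us = traj.times_ps * tsf * 1e-6
    analyzed = float(times_us[-1] - times_us[0])
    mols, states = region_state_series(traj, topology, regions, species)
    rows = []
    for j, mol in enumerate(mols):
        for frame, direction in detect_events(states[:, j]):
            rows.append((int(mol), int(frame), float(times_us[frame]),
                         "up" if direction > 0 else "down"))
    events = pd.DataFrame(rows, columns=["molecule", "frame", "time_us",
                                         "direction"])
    events = events.sort_values(["frame", "molecule"]).reset_index(drop=True)
    n = len(events)
    rate = n / analyzed
    se = np.sqrt(n) / analyzed
    return FlipFlopResult(
        events=events, rate_per_us=rate, rate_se_per_us=se,
        analyzed_time_us=analyzed, species=species, n_molecules=len(mols),
        per_molecule_rate_per_us=rate / len(mols) if len(mols) else 0.0,
    )
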