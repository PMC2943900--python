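"""Core containers: trajectory frames, topology role tables, and PBC utilities.

All positions are in nm, times in ps (unscaled simulation time). Coarse-grained
dynamics sample phase space faster than atomistic dynamics, so analysis times
are conventionally multiplied by a scale factor (default 4); conversions to
"scaled" microseconds live on :class:`Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conventional speed-up factor applied to CG simulation times.
DEFAULT_TIME_SCALE_FACTOR = 4.0

SPECIES = ("POPC", "TO", "W")

#: Roles a bead may carry.  Acyl-tail beads are ``TAIL{chain}_{k}`` with
#: chain in 1..3 (sn1..sn3) and k counting outward from the glycerol bead.
GLYCEROL_ROLES = ("GLYC_A1", "GLYC_B", "GLYC_A3")
PHOSPHATE_ROLE = "PHOS"
WATER_ROLE = "W"


@dataclass
class Frame:
    """A single snapshot: bead positions (n, 3) nm, box lengths (3,) nm, time in ps."""

    positions: np.ndarray
    box: np.ndarray
    time_ps: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths")


class Trajectory:
    """Ordered frames of bead positions with per-frame box and timestamp.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_beads, 3)
    boxes : ndarray, shape (n_frames, 3)
    times_ps : ndarray, shape (n_frames,)
        Unscaled simulation time of each frame in ps.
    time_scale_factor : float
        Multiplier converting simulation time to scaled (effective) time.
    """

    def __init__(self, positions, boxes, times_ps,
                 time_scale_factor: float = DEFAULT_TIME_SCALE_FACTOR):
        positions = np.asarray(positions)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        boxes = np.asarray(boxes, dtype=np.float64)
        times_ps = np.asarray(times_ps, dtype=np.float64)
        if boxes.shape != (positions.shape[0], 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if times_ps.shape != (positions.shape[0],):
            raise ValueError("times_ps must have shape (n_frames,)")
        if not np.all(boxes > 0):
            raise ValueError("box lengths must be positive")
        self.positions = positions
        self.boxes = boxes
        self.times_ps = times_ps
        self.time_scale_factor = float(time_scale_factor)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.boxes[i], float(self.times_ps[i]))

    @property
    def scaled_times_us(self) -> np.ndarray:
        """Scaled (effective) time of each frame, in microseconds."""
        return self.times_ps * self.time_scale_factor * 1e-6

    @property
    def analyzed_time_us(self) -> float:
        """Scaled time spanned by the trajectory (last minus first frame), µs."""
        t = self.scaled_times_us
        return float(t[-1] - t[0])

    def copy(self) -> "Trajectory":
        return Trajectory(self.positions.copy(), self.boxes.copy(),
                          self.times_ps.copy(), self.time_scale_factor)


class Topology:
    """Per-bead role table: bead index, molecule id, species, role.

    Wraps a :class:`pandas.DataFrame` with columns ``bead``, ``molecule``,
    ``species`` and ``role`` and caches the selectors every analysis uses.
    """

    COLUMNS = ("bead", "molecule", "species", "role")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"topology table missing columns: {missing}")
        table = table.reset_index(drop=True)
        if not np.array_equal(table["bead"].to_numpy(), np.arange(len(table))):
            raise ValueError("bead indices must be 0..n-1 in order")
        bad = set(table["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species: {sorted(bad)}")
        self.table = table
        self._species = table["species"].to_numpy()
        self._role = table["role"].to_numpy()
        self._molecule = table["molecule"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    # -- selectors ---------------------------------------------------------
    def indices(self, species: str | None = None,
                role: str | None = None,
                roles: tuple[str, ...] | None = None) -> np.ndarray:
        mask = np.ones(len(self.table), dtype=bool)
        if species is not None:
            mask &= self._species == species
        if role is not None:
            mask &= self._role == role
        if roles is not None:
            mask &= np.isin(self._role, list(roles))
        return np.nonzero(mask)[0]

    def molecules(self, species: str) -> np.ndarray:
        """Sorted molecule ids of a species."""
        return np.unique(self._molecule[self._species == species])

    def glycerol_indices_by_molecule(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(molecule ids (m,), bead indices (m, n_glyc)) of glycerol beads.

        Requires each molecule of the species to carry the same number of
        glycerol beads, which the topology contract guarantees.
        """
        mask = (self._species == species) & np.isin(self._role, list(GLYCEROL_ROLES))
        beads = np.nonzero(mask)[0]
        if beads.size == 0:
            raise ValueError(f"species {species!r} has no glycerol beads")
        mols = self._molecule[beads]
        order = np.lexsort((self._role[beads], mols))
        beads, mols = beads[order], mols[order]
        uniq, counts = np.unique(mols, return_counts=True)
        if counts.min() != counts.max():
            raise ValueError("inconsistent glycerol bead counts per molecule")
        return uniq, beads.reshape(len(uniq), counts[0])

    def mol_first_bead(self) -> np.ndarray:
        """For each bead, the index of the first bead of its molecule."""
        first = pd.Series(np.arange(len(self.table))).groupby(
            self._molecule).transform("min").to_numpy()
        return first

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the species role contracts (3 glycerols + 3 tails for TO, etc.)."""
        df = self.table
        for mol, grp in df[df.species == "TO"].groupby("molecule"):
            roles = set(grp.role)
            if not set(GLYCEROL_ROLES) <= roles:
                raise ValueError(f"TO molecule {mol} lacks the three glycerol roles")
            chains = {r.split("_")[0] for r in roles if r.startswith("TAIL")}
            if chains != {"TAIL1", "TAIL2", "TAIL3"}:
                raise ValueError(f"TO molecule {mol} must have exactly 3 tail chains")
        for mol, grp in df[df.species == "POPC"].groupby("molecule"):
            roles = set(grp.role)
            if list(grp.role).count(PHOSPHATE_ROLE) != 1:
                raise ValueError(f"POPC molecule {mol} must have exactly 1 phosphate")
            if not roles & set(GLYCEROL_ROLES):
                raise ValueError(f"POPC molecule {mol} has no glycerol beads")
            chains = {r.split("_")[0] for r in roles if r.startswith("TAIL")}
            if chains != {"TAIL1", "TAIL2"}:
                raise ValueError(f"POPC molecule {mol} must have exactly 2 tail chains")


# ---------------------------------------------------------------------------
# PBC utilities
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return d - box * np.round(d / box)


def make_whole(frame: Frame, topology: Topology) -> Frame:
    """Rewrap each molecule so its beads form a connected minimum-image cluster.

    Each bead is moved to the periodic image nearest to the first bead of its
    molecule, which is exact for molecules smaller than half the box in every
    direction (checked; wider molecules raise).  Idempotent.
    """
    first = topology.mol_first_bead()
    pos = frame.positions
    ref = pos[first]
    new = ref + minimum_image(pos - ref, frame.box)
    # verify the compact-molecule precondition
    df = pd.DataFrame(new, columns=["x", "y", "z"])
    df["mol"] = topology.table["molecule"].to_numpy()
    extent = df.groupby("mol").max() - df.groupby("mol").min()
    if np.any(extent[["x", "y", "z"]].to_numpy() >= frame.box / 2):
        wide = extent.index[(extent[["x", "y", "z"]].to_numpy()
                             >= frame.box / 2).any(axis=1)]
        raise ValueError(
            f"molecule(s) wider than half the box after rewrapping: {list(wide[:5])}")
    return Frame(new, frame.box.copy(), frame.time_ps)


def make_whole_trajectory(traj: Trajectory, topology: Topology) -> Trajectory:
    """Vectorized :func:`make_whole` over all frames (no width check)."""
    first = topology.mol_first_bead()
    ref = traj.positions[:, first, :]
    box = traj.boxes[:, None, :]
    new = ref + (traj.positions - ref) - box * np.round((traj.positions - ref) / box)
    return Trajectory(new, traj.boxes.copy(), traj.times_ps.copy(),
                      traj.time_scale_factor)


def subsample(traj: Trajectory, target_spacing_ns: float) -> Trajectory:
    """Keep every k-th frame, k = target spacing / native spacing (exact multiple).

    The native spacing is taken from the first two frame timestamps.  No
    interpolation: a non-integer multiple raises.  The first frame is always
    retained and kept timestamps are preserved exactly.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to determine native spacing")
    native_ns = (traj.times_ps[1] - traj.times_ps[0]) * 1e-3
    if native_ns <= 0:
        raise ValueError("frame timestamps must be strictly increasing")
    ratio = target_spacing_ns / native_ns
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"target spacing {target_spacing_ns} ns is not an integer multiple "
            f"of the native spacing {native_ns} ns")
    return Trajectory(traj.positions[::k], traj.boxes[::k], traj.times_ps[::k],
                      traj.time_scale_factor)


def glycerol_com_z(traj: Trajectory, topology: Topology,
                   species: str = "TO") -> tuple[np.ndarray, np.ndarray]:
    """Per-frame z of each molecule's glycerol-backbone centre of mass.

    Returns (molecule ids (m,), z array (n_frames, m)).  No rewrapping is
    needed along z: the membrane never spans the z boundary in this package's
    conventions, and glycerol beads of one molecule are tightly bonded.
    """
    mols, beads = topology.glycerol_indices_by_molecule(species)
    z = traj.positions[:, beads, 2].astype(np.float64)
    return mols, z.mean(axis=2)


def glycerol_com_xy(frame: Frame, topology: Topology,
                    species: str = "TO") -> tuple[np.ndarray, np.ndarray]:
    """Molecule glycerol-COM xy positions in one frame, minimum-image safe.

    COM is accumulated relative to each molecule's first glycerol bead so a
    molecule straddling the xy boundary is handled correctly; the result is
    wrapped back into the primary box.
    """
    mols, beads = topology.glycerol_indices_by_molecule(species)
    pos = frame.positions[beads][:, :, :2].astype(np.float64)
    box = frame.box[:2]
    ref = pos[:, :1, :]
    rel = minimum_image(pos - ref, box)
    com = (ref[:, 0, :] + rel.mean(axis=1)) % box
    return mols, com
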