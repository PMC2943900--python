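"""GRO multi-frame trajectory I/O and topology role tables.

The GRO dialect used throughout the package is fixed-width, positions in nm,
one box line per frame, velocities optional and ignored on read.  Bead naming
is chosen so that the full role table can be reconstructed from the GRO file
alone: residue name = species (POPC / TO / W), residue number = molecule id
(modulo the format's 5-digit field), and atom name encodes the role:

====================  =========
role                  atom name
====================  =========
PHOS                  PO4
GLYC_A1 / B / A3      GLA1 / GLB / GLA3
TAIL{c}_{k}           C{k}{A|B|C}   (chain 1->A, 2->B, 3->C)
W                     W
====================  =========

Frame timestamps are written into the title line as ``t= <ps>``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import DEFAULT_TIME_SCALE_FACTOR, Topology, Trajectory

_CHAIN_LETTER = {1: "A", 2: "B", 3: "C"}
_LETTER_CHAIN = {v: k for k, v in _CHAIN_LETTER.items()}

ROLE_TO_NAME = {
    "PHOS": "PO4",
    "GLYC_A1": "GLA1",
    "GLYC_B": "GLB",
    "GLYC_A3": "GLA3",
    "W": "W",
}
NAME_TO_ROLE = {v: k for k, v in ROLE_TO_NAME.items()}


def role_to_atom_name(role: str) -> str:
    if role in ROLE_TO_NAME:
        return ROLE_TO_NAME[role]
    if role.startswith("TAIL"):
        chain, k = role[4:].split("_")
        return f"C{k}{_CHAIN_LETTER[int(chain)]}"
    raise ValueError(f"unknown role {role!r}")


def atom_name_to_role(name: str) -> str:
    name = name.strip()
    if name in NAME_TO_ROLE:
        return NAME_TO_ROLE[name]
    if len(name) >= 3 and name[0] == "C" and name[-1] in _LETTER_CHAIN:
        return f"TAIL{_LETTER_CHAIN[name[-1]]}_{name[1:-1]}"
    raise ValueError(f"cannot map atom name {name!r} to a role")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def write_gro(traj: Trajectory, topology: Topology, path: str | os.PathLike,
              title: str = "tgblister synthetic CG trajectory") -> None:
    """Write a multi-frame fixed-width GRO file (positions in nm)."""
    tab = topology.table
    resnums = (tab["molecule"].to_numpy() % 100000).astype(int)
    resnames = tab["species"].to_numpy()
    names = [role_to_atom_name(r) for r in tab["role"]]
    atomnums = (np.arange(len(tab)) + 1) % 100000
    prefix = [f"{rn:>5d}{resname:<5s}{nm:>5s}{an:>5d}"
              for rn, resname, nm, an in zip(resnums, resnames, names, atomnums)]
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            pos = traj.positions[i]
            box = traj.boxes[i]
            fh.write(f"{title}, t= {traj.times_ps[i]:.3f}\n")
            fh.write(f"{traj.n_beads:d}\n")
            fh.writelines(
                f"{p}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                for p, (x, y, z) in zip(prefix, pos.astype(float))
            )
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def read_gro(path: str | os.PathLike,
             time_scale_factor: float = DEFAULT_TIME_SCALE_FACTOR,
             ) -> tuple[Trajectory, pd.DataFrame]:
    """Read a (multi-frame) GRO file.

    Returns the trajectory and a per-bead name table (resnum, resname,
    atom_name) from the first frame; :func:`topology_from_names` rebuilds a
    full role table from it.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty GRO file")
    frames_pos: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    names: pd.DataFrame | None = None
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        title = lines[i]
        if i + 1 >= len(lines):
            raise ValueError(f"frame {frame_idx}: truncated after title line")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise ValueError(
                f"frame {frame_idx}: malformed atom count line {lines[i + 1]!r}")
        body = lines[i + 2: i + 2 + natoms]
        if len(body) < natoms or i + 2 + natoms >= len(lines):
            raise ValueError(f"frame {frame_idx}: truncated (expected {natoms} atoms)")
        pos = np.empty((natoms, 3), dtype=np.float64)
        try:
            for j, ln in enumerate(body):
                pos[j, 0] = float(ln[20:28])
                pos[j, 1] = float(ln[28:36])
                pos[j, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise ValueError(f"frame {frame_idx}: malformed atom line {j}")
        if names is None:
            names = pd.DataFrame({
                "resnum": [int(ln[0:5]) for ln in body],
                "resname": [ln[5:10].strip() for ln in body],
                "atom_name": [ln[10:15].strip() for ln in body],
            })
        box_fields = lines[i + 2 + natoms].split()
        if len(box_fields) < 3:
            raise ValueError(f"frame {frame_idx}: malformed box line")
        boxes.append(np.array([float(v) for v in box_fields[:3]]))
        t = _parse_time(title, default=float(frame_idx))
        times.append(t)
        frames_pos.append(pos)
        i += 2 + natoms + 1
        frame_idx += 1
    if not frames_pos:
        raise ValueError(f"{path}: no frames found")
    traj = Trajectory(np.stack(frames_pos), np.stack(boxes), np.array(times),
                      time_scale_factor=time_scale_factor)
    return traj, names


def _parse_time(title: str, default: float) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            pass
    return default


def topology_from_names(names: pd.DataFrame) -> Topology:
    """Rebuild the role table from GRO bead names (see module docstring)."""
    resnum = names["resnum"].to_numpy()
    # contiguous runs of equal residue number = one molecule (robust to the
    # 5-digit wraparound of the GRO resnum field)
    new_mol = np.ones(len(names), dtype=bool)
    new_mol[1:] = resnum[1:] != resnum[:-1]
    molecule = np.cumsum(new_mol) - 1
    table = pd.DataFrame({
        "bead": np.arange(len(names)),
        "molecule": molecule,
        "species": names["resname"].to_numpy(),
        "role": [atom_name_to_role(n) for n in names["atom_name"]],
    })
    return Topology(table)


# ---------------------------------------------------------------------------
# Topology TSV
# ---------------------------------------------------------------------------

def write_topology_tsv(topology: Topology, path: str | os.PathLike) -> None:
    topology.table.to_csv(path, sep="\t", index=False)


def read_topology_tsv(path: str | os.PathLike) -> Topology:
    return Topology(pd.read_csv(path, sep="\t"))
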