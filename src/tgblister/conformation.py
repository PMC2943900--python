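"""Tail vectors, splay-angle classification, and bond order parameters.

Each acyl tail is described by the vector from its glycerol bead to the last
tail bead.  Triolein conformations are classified from the two adjacent-tail
angles θ₁₂ (sn1–sn2) and θ₂₃ (sn2–sn3): FULL if both exceed the threshold
(default 90°), PARTIAL if exactly one does, NOT otherwise.  POPC, with two
tails, gets the single inter-tail angle.  All vectors are computed with
minimum-image displacements so molecules split by the periodic boundary are
handled without a separate rewrapping pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory, minimum_image
from .density import RegionPartition
from .flipflop import region_state_series

SPLAY_CLASSES = ("NOT", "PARTIAL", "FULL")
DEFAULT_THRESHOLD_DEG = 90.0

_CHAIN_GLYC = {  # chain index -> anchoring glycerol role
    "TO": {1: "GLYC_A1", 2: "GLYC_B", 3: "GLYC_A3"},
    "POPC": {1: "GLYC_A1", 2: "GLYC_B"},
}


def _chain_endpoints(topology: Topology, species: str
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(molecule ids (m,), glycerol bead idx (m, c), terminal bead idx (m, c))."""
    df = topology.table
    sub = df[df.species == species]
    if sub.empty:
        raise ValueError(f"no molecules of species {species!r}")
    chains = sorted(_CHAIN_GLYC[species])
    mols = np.sort(sub.molecule.unique())
    glyc = np.empty((len(mols), len(chains)), dtype=int)
    term = np.empty((len(mols), len(chains)), dtype=int)
    by_mol_role = sub.set_index(["molecule", "role"]).bead
    for c_i, c in enumerate(chains):
        tail_roles = sorted((r for r in sub.role.unique()
                             if r.startswith(f"TAIL{c}_")),
                            key=lambda r: int(r.split("_")[1]))
        if not tail_roles:
            raise ValueError(f"species {species!r} chain {c} has no tail beads")
        last = tail_roles[-1]
        for m_i, m in enumerate(mols):
            try:
                glyc[m_i, c_i] = by_mol_role.loc[(m, _CHAIN_GLYC[species][c])]
                term[m_i, c_i] = by_mol_role.loc[(m, last)]
            except KeyError:
                raise ValueError(
                    f"molecule {m} is missing the glycerol or terminal bead of "
                    f"chain {c}")
    return mols, glyc, term


def tail_vectors(frame: Frame, topology: Topology, molecule: int) -> np.ndarray:
    """Tail vectors of one molecule in one frame, shape (n_chains, 3).

    Vector = terminal tail bead minus that chain's glycerol bead, under the
    minimum image (PBC-split chains are handled).  TO gives 3 vectors, POPC 2.
    """
    species = topology.table.loc[
        topology.table.molecule == molecule, "species"]
    if species.empty:
        raise ValueError(f"unknown molecule {molecule}")
    sp = species.iloc[0]
    if sp not in _CHAIN_GLYC:
        raise ValueError(f"species {sp!r} has no acyl chains")
    mols, glyc, term = _chain_endpoints(topology, sp)
    j = int(np.searchsorted(mols, molecule))
    d = frame.positions[term[j]] - frame.positions[glyc[j]]
    return minimum_image(d, frame.box)


def _all_tail_vectors(traj: Trajectory, topology: Topology, species: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(molecule ids (m,), unit-ish tail vectors (n_frames, m, c, 3))."""
    mols, glyc, term = _chain_endpoints(topology, species)
    d = (traj.positions[:, term, :].astype(np.float64)
         - traj.positions[:, glyc, :].astype(np.float64))
    box = traj.boxes[:, None, None, :]
    d -= box * np.round(d / box)
    return mols, d


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("degenerate zero-length tail vector")
    c = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def classify_splay(theta_12: float | np.ndarray, theta_23: float | np.ndarray,
                   threshold_deg: float = DEFAULT_THRESHOLD_DEG):
    """FULL if both angles > threshold, PARTIAL if exactly one, NOT otherwise."""
    t12 = np.asarray(theta_12, dtype=float)
    t23 = np.asarray(theta_23, dtype=float)
    if np.any((t12 < 0) | (t12 > 180) | (t23 < 0) | (t23 > 180)):
        raise ValueError("angles must be in [0, 180] degrees")
    n_over = (t12 > threshold_deg).astype(int) + (t23 > threshold_deg).astype(int)
    classes = np.array(["NOT", "PARTIAL", "FULL"])[n_over]
    return classes if classes.ndim else str(classes)


def splay_angles(traj: Trajectory, topology: Topology
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(molecule ids, θ₁₂ (F, m), θ₂₃ (F, m)) for all TO molecules, degrees."""
    mols, vec = _all_tail_vectors(traj, topology, "TO")
    t12 = _angles_deg(vec[:, :, 0, :], vec[:, :, 1, :])
    t23 = _angles_deg(vec[:, :, 1, :], vec[:, :, 2, :])
    return mols, t12, t23


def splay_fractions_by_region(traj: Trajectory, topology: Topology,
                              regions: RegionPartition,
                              threshold_deg: float = DEFAULT_THRESHOLD_DEG
                              ) -> dict[str, dict[str, float]]:
    """Splay-class fractions of TO molecule-frames per region.

    Regions are "interface" (either interfacial slab) and "middle"; molecule
    region assignment uses the same machinery as flip-flop detection.  Classes
    sum to 1 in each region present; a region with no TO molecule-frames is
    absent from the result (not reported as zero).
    """
    mols, t12, t23 = splay_angles(traj, topology)
    smols, states = region_state_series(traj, topology, regions, "TO")
    assert np.array_equal(mols, smols)
    n_over = (t12 > threshold_deg).astype(int) + (t23 > threshold_deg).astype(int)
    out: dict[str, dict[str, float]] = {}
    for name, mask in (("interface", states != 0), ("middle", states == 0)):
        n = int(mask.sum())
        if n == 0:
            continue
        sel = n_over[mask]
        out[name] = {cls: float((sel == k).sum() / n)
                     for k, cls in enumerate(SPLAY_CLASSES)}
    if t12.size:
        sel = n_over.ravel()
        out["overall"] = {cls: float((sel == k).sum() / sel.size)
                          for k, cls in enumerate(SPLAY_CLASSES)}
    return out


def splay_table(traj: Trajectory, topology: Topology,
                regions: RegionPartition,
                threshold_deg: float = DEFAULT_THRESHOLD_DEG) -> pd.DataFrame:
    """Per-molecule-frame splay records (molecule, frame, θ₁₂, θ₂₃, class, region)."""
    mols, t12, t23 = splay_angles(traj, topology)
    _, states = region_state_series(traj, topology, regions, "TO")
    F, m = t12.shape
    frames = np.repeat(np.arange(F), m)
    mol_col = np.tile(mols, F)
    region = np.where(states.ravel() == 0, "middle", "interface")
    return pd.DataFrame({
        "molecule": mol_col,
        "frame": frames,
        "theta_12_deg": t12.ravel(),
        "theta_23_deg": t23.ravel(),
        "class": classify_splay(t12.ravel(), t23.ravel(), threshold_deg),
        "region": region,
    })


def intertail_angle_fraction(traj: Trajectory, topology: Topology,
                             species: str = "POPC",
                             threshold_deg: float = DEFAULT_THRESHOLD_DEG
                             ) -> float:
    """Fraction of molecule-frames whose inter-tail angle exceeds the threshold.

    Only defined for two-tailed species; three-tailed molecules should use the
    splay operations instead.
    """
    if species in _CHAIN_GLYC and len(_CHAIN_GLYC[species]) != 2:
        raise ValueError(f"{species} has {len(_CHAIN_GLYC[species])} tails; use "
                         "the splay operations for 3-tailed species")
    mols, vec = _all_tail_vectors(traj, topology, species)
    theta = _angles_deg(vec[:, :, 0, :], vec[:, :, 1, :])
    return float((theta > threshold_deg).mean())


def order_parameters(traj: Trajectory, topology: Topology,
                     bonds: list[tuple[str, str]] | None = None,
                     species: str = "POPC") -> pd.Series:
    """Time-averaged bond order parameter P₂ = ½(3 cos²θ − 1) per bond.

    θ is the angle between the bond vector (consecutive tail beads, or any
    supplied role pair) and the leaflet normal (+z for upper-leaflet
    molecules, −z for lower, by glycerol-COM sign; P₂ is insensitive to the
    sign but the convention is applied for consistency).
    """
    if bonds is None:
        chains = _CHAIN_GLYC[species]
        bonds = []
        for c in sorted(chains):
            roles = [chains[c]] + [f"TAIL{c}_{k}"
                                   for k in range(1, 100)
                                   if f"TAIL{c}_{k}" in set(topology.table.role)]
            bonds += list(zip(roles[:-1], roles[1:]))
    df = topology.table
    sub = df[df.species == species]
    mols = np.sort(sub.molecule.unique())
    by_mol_role = sub.set_index(["molecule", "role"]).bead
    from .core import glycerol_com_z
    _, gz = glycerol_com_z(traj, topology, species)
    normal_sign = np.sign(gz)  # (F, m)
    out = {}
    for a, b in bonds:
        try:
            ia = by_mol_role.loc[[(m, a) for m in mols]].to_numpy()
            ib = by_mol_role.loc[[(m, b) for m in mols]].to_numpy()
        except KeyError:
            raise ValueError(f"bond ({a}, {b}) not defined for every {species} "
                             "molecule")
        d = (traj.positions[:, ib, :].astype(np.float64)
             - traj.positions[:, ia, :].astype(np.float64))
        box = traj.boxes[:, None, :]
        d -= box * np.round(d / box)
        norm = np.linalg.norm(d, axis=-1)
        if np.any(norm == 0):
            raise ValueError(f"zero-length bond ({a}, {b})")
        cos = d[..., 2] / norm * normal_sign
        out[f"{a}-{b}"] = float(np.mean(0.5 * (3 * cos ** 2 - 1)))
    return pd.Series(out, name="P2")
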