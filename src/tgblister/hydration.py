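"""Radial distribution functions of water around glycerol beads.

g(r) is the pair correlation of a selection group (water) around a reference
group, normalised by shell volume 4πr²dr, frame count, reference count and
the mean selection density, so an ideal gas gives g(r) = 1.  The first-shell
coordination number N = 4πρ ∫ g(r) r² dr quantifies the hydration ordering
(the β glycerol bead, sitting deeper in the interface, is less hydrated than
the two α beads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory, minimum_image

DEFAULT_DR = 0.02   # nm
DEFAULT_R_MAX = 1.5  # nm


@dataclass
class RDFResult:
    r: np.ndarray            # bin centres, nm
    g: np.ndarray            # dimensionless
    reference: str
    selection: str
    selection_density: float  # beads/nm^3 (global mean)
    n_frames: int
    n_reference: float        # mean reference beads per frame

    def smoothed(self, window: int = 5) -> np.ndarray:
        kernel = np.ones(window) / window
        pad = window // 2
        return np.convolve(np.pad(self.g, pad, mode="edge"), kernel, "valid")


def radial_distribution(traj: Trajectory, topology: Topology,
                        reference_role: str, selection_role: str = "W",
                        r_max: float = DEFAULT_R_MAX, dr: float = DEFAULT_DR,
                        reference_species: str | None = "TO",
                        reference_mask: np.ndarray | None = None,
                        frame_stride: int = 1) -> RDFResult:
    """Pair RDF of ``selection_role`` beads around ``reference_role`` beads.

    Distances use the minimum image in the orthorhombic box; ``r_max`` must
    stay below half the smallest box dimension.  ``reference_mask`` (n_frames,
    n_ref) optionally restricts which reference beads count in which frame
    (e.g. only interfacial TO molecules); the normalisation uses the actual
    number of contributing reference beads.
    """
    ref_idx = topology.indices(species=reference_species, role=reference_role)
    sel_idx = topology.indices(role=selection_role)
    if ref_idx.size == 0:
        raise ValueError(f"empty reference group {reference_role!r}")
    if sel_idx.size == 0:
        raise ValueError(f"empty selection group {selection_role!r}")
    half_min = float(traj.boxes.min()) / 2
    if r_max >= half_min:
        raise ValueError(f"r_max={r_max} nm must be below half the smallest "
                         f"box dimension ({half_min} nm)")
    frames = range(0, traj.n_frames, frame_stride)
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_ref_total = 0
    volume = float(np.mean(np.prod(traj.boxes, axis=1)))
    for f in frames:
        ref = traj.positions[f, ref_idx, :].astype(np.float64)
        if reference_mask is not None:
            ref = ref[reference_mask[f]]
        if ref.size == 0:
            continue
        sel = traj.positions[f, sel_idx, :].astype(np.float64)
        d = minimum_image(ref[:, None, :] - sel[None, :, :], traj.boxes[f])
        r = np.sqrt((d ** 2).sum(axis=-1)).ravel()
        # exclude exact self-pairs when reference and selection overlap
        counts += np.histogram(r[(r > 1e-9) & (r < r_max)], bins=edges)[0]
        n_ref_total += len(ref)
    if n_ref_total == 0:
        raise ValueError("reference mask leaves no reference beads in any frame")
    n_frames_used = len(list(frames))
    rho_sel = sel_idx.size / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    # exact shell volumes (the 4*pi*r^2*dr approximation fails near r = 0)
    shell = 4 * np.pi / 3 * (edges[1:] ** 3 + -(edges[:-1] ** 3))
    g = counts / (n_ref_total * shell * rho_sel)
    return RDFResult(r=centers, g=g, reference=reference_role,
                     selection=selection_role, selection_density=rho_sel,
                     n_frames=n_frames_used,
                     n_reference=n_ref_total / max(n_frames_used, 1))


def coordination_number(rdf: RDFResult,
                        r_cut: float | str = "first-minimum") -> float:
    """N = 4πρ ∫₀^r_cut g(r) r² dr (trapezoidal).

    ``r_cut`` may be a radius in nm or ``"first-minimum"``, which locates the
    minimum of the smoothed g(r) after its first maximum; if g has no interior
    maximum an explicit radius must be supplied.
    """
    r, g = rdf.r, rdf.g
    if isinstance(r_cut, str):
        if r_cut != "first-minimum":
            raise ValueError("r_cut must be a radius or 'first-minimum'")
        gs = rdf.smoothed()
        peaks = np.nonzero((gs[1:-1] > gs[:-2]) & (gs[1:-1] >= gs[2:]))[0] + 1
        if peaks.size == 0 or peaks[0] >= len(gs) - 2:
            raise ValueError("g(r) has no interior first maximum; pass an "
                             "explicit r_cut")
        p = peaks[0]
        rest = gs[p:]
        mins = np.nonzero((rest[1:-1] < rest[:-2]) & (rest[1:-1] <= rest[2:]))[0] + 1
        if mins.size == 0:
            raise ValueError("no minimum after the first maximum of g(r); pass "
                             "an explicit r_cut")
        r_cut = float(r[p + mins[0]])
    if not 0 < r_cut <= r[-1] + (r[1] - r[0]):
        raise ValueError(f"r_cut={r_cut} outside the computed range")
    mask = r <= r_cut
    # integrate over the full [0, r_cut] interval: prepend r = 0 (integrand
    # 0) and append r_cut with interpolated g, so the closed form is
    # recovered to O(dr^2)
    rr = np.concatenate([[0.0], r[mask]])
    gg = np.concatenate([[0.0], g[mask] * r[mask] ** 2])
    if r_cut > rr[-1]:
        g_end = float(np.interp(r_cut, r, g))
        rr = np.append(rr, r_cut)
        gg = np.append(gg, g_end * r_cut ** 2)
    integral = np.trapezoid(gg, rr)
    return float(4 * np.pi * rdf.selection_density * integral)


def glycerol_hydration(traj: Trajectory, topology: Topology,
                       interfacial_mask_by_molecule: np.ndarray | None = None,
                       r_max: float = DEFAULT_R_MAX, dr: float = DEFAULT_DR,
                       r_cut: float = DEFAULT_R_MAX,
                       frame_stride: int = 1) -> dict[str, dict[str, float]]:
    """Water RDF and coordination number for each TO glycerol bead role.

    ``interfacial_mask_by_molecule`` (n_frames, n_TO_molecules, matching the
    sorted molecule order) restricts the comparison to interfacial TO
    molecule-frames, mirroring the interfacial context of the hydration
    ordering; None uses all TO.
    """
    out = {}
    for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
        rdf = radial_distribution(
            traj, topology, role, "W", r_max=r_max, dr=dr,
            reference_species="TO",
            reference_mask=interfacial_mask_by_molecule,
            frame_stride=frame_stride)
        out[role] = {
            "coordination_number": coordination_number(rdf, r_cut),
            "rdf_r": rdf.r, "rdf_g": rdf.g,
        }
    return out
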