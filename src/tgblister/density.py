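"""Bilayer centering, number-density profiles, region partitioning and geometry.

The central construction is the three-region partition of the bilayer along
its normal: two interfacial slabs and one middle slab, with boundaries placed
at the minima of the (smoothed) triolein-glycerol density profile between the
central population and each interfacial peak.  Everything downstream
(flip-flop detection, splay-by-region, the partition coefficient, aggregate
selection) classifies molecules against this single partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory, glycerol_com_z

DEFAULT_BIN_WIDTH = 0.1  # nm
SMOOTH_BINS = 3          # moving-average window for minima detection
FALLBACK_FRACTION = 0.5  # fallback boundary at +-f * (half phosphate distance)


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def center_frames(traj: Trajectory, topology: Topology) -> Trajectory:
    """Shift every frame along z so the mean POPC-phosphate z is zero.

    Per-frame (not global) so slow bilayer drift cancels exactly; x and y are
    untouched.  Idempotent.
    """
    phos = topology.indices(species="POPC", role="PHOS")
    if phos.size == 0:
        raise ValueError("no POPC phosphate beads; cannot centre the bilayer")
    shift = traj.positions[:, phos, 2].astype(np.float64).mean(axis=1)
    pos = traj.positions.copy()
    pos[:, :, 2] = pos[:, :, 2] - shift[:, None].astype(pos.dtype)
    return Trajectory(pos, traj.boxes.copy(), traj.times_ps.copy(),
                      traj.time_scale_factor)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Frame-averaged number density along the bilayer normal.

    ``edges`` are midplane-centred bin edges (nm); ``density`` is in
    beads/nm^3; the integral of density x bin volume equals the mean bead
    count of the group per frame.
    """

    edges: np.ndarray
    density: np.ndarray
    n_frames: int
    group: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def smoothed(self, window: int = SMOOTH_BINS) -> np.ndarray:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(self.density, pad, mode="edge")
        return np.convolve(padded, kernel, mode="valid")


def density_profile(traj: Trajectory, topology: Topology,
                    species: str | None = None, role: str | None = None,
                    roles: tuple[str, ...] | None = None,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    bead_indices: np.ndarray | None = None) -> DensityProfile:
    """Number-density histogram of a bead group along z (centred trajectory).

    Normalised per bin volume (Lx * Ly * bin_width) and per frame.  The bin
    grid is symmetric about z = 0 and spans all selected beads, so the
    integral recovers the mean group count exactly.
    """
    if bead_indices is None:
        idx = topology.indices(species=species, role=role, roles=roles)
    else:
        idx = np.asarray(bead_indices)
    if idx.size == 0:
        raise ValueError(
            f"empty bead group (species={species!r}, role={role!r}, roles={roles!r})")
    z = traj.positions[:, idx, 2].astype(np.float64).ravel()
    zmax = float(np.abs(z).max()) + bin_width
    m = int(np.ceil(zmax / bin_width))
    edges = np.arange(-m, m + 1) * bin_width
    counts, _ = np.histogram(z, bins=edges)
    area = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]))
    density = counts / (traj.n_frames * area * bin_width)
    label = species or ""
    if role or roles:
        label += f":{role or ','.join(roles)}"
    return DensityProfile(edges=edges, density=density,
                          n_frames=traj.n_frames, group=label)


# ---------------------------------------------------------------------------
# region partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPartition:
    """Middle region = [z_lower, z_upper]; interfacial slabs outside."""

    z_lower_boundary: float
    z_upper_boundary: float

    def __post_init__(self) -> None:
        if not self.z_lower_boundary < 0 < self.z_upper_boundary:
            raise ValueError("boundaries must straddle the midplane "
                             "(z_lower < 0 < z_upper)")

    def classify(self, z: np.ndarray) -> np.ndarray:
        """Vectorised state classification: -1 LOWER, 0 MIDDLE, +1 UPPER.

        A z exactly on a boundary is assigned to MIDDLE (documented,
        conservative tie-break).
        """
        z = np.asarray(z)
        out = np.zeros(z.shape, dtype=np.int8)
        out[z < self.z_lower_boundary] = -1
        out[z > self.z_upper_boundary] = 1
        return out


def _local_maxima(values: np.ndarray) -> list[int]:
    """Interior local maxima (plateau-tolerant, strictly positive)."""
    out = []
    n = len(values)
    for i in range(1, n - 1):
        if values[i] <= 0:
            continue
        if values[i] >= values[i - 1] and values[i] >= values[i + 1] \
                and (values[i] > values[i - 1] or values[i] > values[i + 1]):
            out.append(i)
    return out


def _plateau_argmin(values: np.ndarray) -> int:
    """Index of the minimum; ties broken by the centre of the minimal plateau."""
    lo = values.min()
    where = np.nonzero(values <= lo + 1e-12)[0]
    return int(where[len(where) // 2])


def partition_regions(profile: DensityProfile,
                      phosphate_profile: DensityProfile | None = None,
                      fallback_fraction: float = FALLBACK_FRACTION,
                      central_threshold: float = 0.05) -> RegionPartition:
    """Three-region boundaries from a TO-glycerol density profile.

    The profile is smoothed (3-bin moving average); the interfacial peaks are
    the maxima on each side of the midplane, and each boundary is the minimum
    of the smoothed density between the central population and that peak
    (plateau ties resolved at the plateau centre, keeping mirror symmetry).

    If no central population exists (central density below
    ``central_threshold`` x the mean interfacial peak), boundaries fall back
    to +-``fallback_fraction`` x (half the phosphate peak-to-peak distance),
    which requires ``phosphate_profile``.
    """
    sm = profile.smoothed()
    centers = profile.centers
    if phosphate_profile is not None:
        # anchor the interfacial-peak search near the phosphate planes: the
        # interfacial TO population can be orders of magnitude below the
        # central one ("very little TO at the interface" in the large
        # patches), so prominence filtering alone cannot find it
        half = _phosphate_half_distance(phosphate_profile)

        def _side_peak(sign: int) -> int:
            window = ((sign * centers >= 0.4 * half)
                      & (sign * centers <= 1.6 * half))
            if not window.any() or sm[window].max() <= 0:
                raise ValueError(
                    "profile has no interfacial peak on each side of the "
                    "midplane; cannot partition regions")
            return int(np.nonzero(window)[0][np.argmax(sm[window])])

        iu, il = _side_peak(+1), _side_peak(-1)
    else:
        maxima = _local_maxima(sm)
        up_peaks = [i for i in maxima if centers[i] > 0]
        lo_peaks = [i for i in maxima if centers[i] < 0]
        if not up_peaks or not lo_peaks:
            raise ValueError("profile has no interfacial peak on each side of "
                             "the midplane; cannot partition regions")
        # interfacial peak = outermost significant local maximum on each side
        # (the central population can dominate the per-side maximum)
        rel = 0.02
        up_sig = [i for i in up_peaks
                  if sm[i] >= rel * max(sm[j] for j in up_peaks)]
        lo_sig = [i for i in lo_peaks
                  if sm[i] >= rel * max(sm[j] for j in lo_peaks)]
        iu = max(up_sig)
        il = min(lo_sig)
    # central population present?
    third = (centers[iu] - centers[il]) / 6.0
    central_mask = np.abs(centers) <= max(third, profile.bin_width)
    central_peak = sm[central_mask].max() if central_mask.any() else 0.0
    peak_mean = 0.5 * (sm[iu] + sm[il])
    if central_peak < central_threshold * peak_mean:
        if phosphate_profile is None:
            raise ValueError(
                "no central TO population; supply a phosphate profile for the "
                "fallback boundary placement")
        half = _phosphate_half_distance(phosphate_profile)
        b = fallback_fraction * half
        return RegionPartition(-b, b)
    icen = int(np.nonzero(central_mask)[0][np.argmax(sm[central_mask])])
    # minima between the central maximum and each interfacial peak
    up_slice = sm[icen:iu + 1]
    lo_slice = sm[il:icen + 1]
    z_up = centers[icen + _plateau_argmin(up_slice)]
    z_lo = centers[il + _plateau_argmin(lo_slice)]
    return RegionPartition(float(z_lo), float(z_up))


def _phosphate_half_distance(phosphate_profile: DensityProfile) -> float:
    sm = phosphate_profile.smoothed()
    centers = phosphate_profile.centers
    up, lo = centers > 0, centers < 0
    zu = centers[up][np.argmax(sm[up])]
    zl = centers[lo][np.argmax(sm[lo])]
    return float(zu - zl) / 2.0


# ---------------------------------------------------------------------------
# partition coefficient
# ---------------------------------------------------------------------------

def partition_coefficient(traj: Trajectory, topology: Topology,
                          regions: RegionPartition, species: str = "TO",
                          ) -> tuple[float, float, np.ndarray]:
    """Middle/interfacial occupancy ratio of TO glycerol COMs.

    Returns ``(ratio, standard_error, per_frame_middle_counts)`` where ratio =
    (time-averaged middle count) / (time-averaged interfacial count).  The
    standard error is the delta-method propagation of the binomial occupancy
    fraction treating frames as independent (exact for the generator's
    occupancy model; an upper bound to precision for correlated data).
    """
    import warnings

    if traj.n_frames < 100:
        warnings.warn("fewer than 100 frames: partition-coefficient estimate "
                      "may be unstable", stacklevel=2)
    _, z = glycerol_com_z(traj, topology, species)
    states = regions.classify(z)
    middle = (states == 0).sum(axis=1).astype(np.float64)
    interf = (states != 0).sum(axis=1).astype(np.float64)
    if interf.sum() == 0:
        raise ValueError("no interfacial occupancy in any frame; the "
                         "middle/interfacial ratio is undefined")
    ratio = middle.sum() / interf.sum()
    n_tot = states.size
    p = middle.sum() / n_tot
    se_p = np.sqrt(max(p * (1 - p), 1e-300) / n_tot)
    se = se_p / (1 - p) ** 2
    return float(ratio), float(se), middle


# ---------------------------------------------------------------------------
# bilayer geometry
# ---------------------------------------------------------------------------

def bilayer_geometry(traj: Trajectory, topology: Topology,
                     bin_width: float = DEFAULT_BIN_WIDTH) -> dict:
    """Bilayer thickness and area per lipid (centred trajectory).

    Thickness is the distance between the phosphate-density peaks of the two
    leaflets, refined by the centre of mass of phosphate z within +-2 bins of
    each peak bin (so planted jitter-free planes are recovered exactly).
    Area per lipid = 2 * Lx * Ly / N with N all lipids, plus the POPC-only
    variant.  Returned with per-frame-scatter standard errors where defined.
    """
    phos = topology.indices(species="POPC", role="PHOS")
    if phos.size == 0:
        raise ValueError("no POPC phosphate beads")
    z = traj.positions[:, phos, 2].astype(np.float64)
    if (z > 0).all() or (z < 0).all():
        raise ValueError("single-leaflet system: cannot measure thickness")
    prof = density_profile(traj, topology, species="POPC", role="PHOS",
                           bin_width=bin_width)
    centers = prof.centers
    peaks = {}
    for name, mask in (("upper", centers > 0), ("lower", centers < 0)):
        i = np.nonzero(mask)[0][np.argmax(prof.density[mask])]
        lo, hi = prof.edges[max(i - 2, 0)], prof.edges[min(i + 3, len(prof.edges) - 1)]
        sel = z[(z >= lo) & (z < hi)]
        peaks[name] = float(sel.mean())
    thickness = peaks["upper"] - peaks["lower"]
    # per-frame thickness scatter from leaflet-mean phosphate planes
    up_mean = np.where(z > 0, z, np.nan)
    lo_mean = np.where(z < 0, z, np.nan)
    per_frame = np.nanmean(up_mean, axis=1) - np.nanmean(lo_mean, axis=1)
    se = float(np.std(per_frame, ddof=1) / np.sqrt(len(per_frame))) \
        if len(per_frame) > 1 else 0.0
    area = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]))
    n_popc = len(topology.molecules("POPC"))
    n_to = len(topology.molecules("TO"))
    return {
        "thickness_nm": thickness,
        "thickness_se_nm": se,
        "area_per_lipid_nm2": 2 * area / (n_popc + n_to),
        "area_per_lipid_popc_only_nm2": 2 * area / n_popc,
        "phosphate_peaks_nm": (peaks["lower"], peaks["upper"]),
    }
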