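"""Centering, density normalisation, region partitioning and geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tgblister import (DensityProfile, RegionPartition, Topology, Trajectory,
                       bilayer_geometry, center_frames, density_profile,
                       generate_trajectory, partition_coefficient,
                       partition_regions, preset)
from tgblister.generator import GeneratorConfig


def _popc_phos_system(z_planes, n_frames=1, drift=0.0, box=5.0):
    """Two phosphate beads per frame at the given z planes (+ optional drift)."""
    rows = []
    for m, _ in enumerate(z_planes):
        rows.append((m, m, "POPC", "PHOS"))
    topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule", "species",
                                                "role"]))
    pos = np.zeros((n_frames, len(z_planes), 3))
    for f in range(n_frames):
        pos[f, :, 2] = np.asarray(z_planes) + drift * f
    boxes = np.tile([box, box, 10.0], (n_frames, 1))
    return Trajectory(pos, boxes, np.arange(n_frames) * 900.0), topo


class TestCentering:
    def test_mean_phosphate_shifted_to_zero(self):
        traj, topo = _popc_phos_system([1.8, 2.2])
        out = center_frames(traj, topo)
        np.testing.assert_allclose(out.positions[0, :, 2], [-0.2, 0.2],
                                   atol=1e-12)

    def test_idempotent_on_centered_frames(self):
        traj, topo = _popc_phos_system([-0.2, 0.2])
        out = center_frames(traj, topo)
        np.testing.assert_allclose(out.positions, traj.positions, atol=1e-12)

    def test_uniform_drift_cancels_exactly(self):
        traj, topo = _popc_phos_system([1.8, 2.2], n_frames=5, drift=0.5)
        out = center_frames(traj, topo)
        for f in range(1, 5):
            np.testing.assert_allclose(out.positions[f], out.positions[0],
                                       atol=1e-12)

    def test_no_phosphates_raises(self):
        topo = Topology(pd.DataFrame({"bead": [0], "molecule": [0],
                                      "species": ["W"], "role": ["W"]}))
        traj = Trajectory(np.zeros((1, 1, 3)), [[5, 5, 5]], [0.0])
        with pytest.raises(ValueError, match="phosphate"):
            center_frames(traj, topo)


class TestDensityProfile:
    def test_single_fixed_bead_normalisation(self):
        # one bead at z=0.03, 100 frames, 5x5 box, 0.1 nm bins -> 0.4 nm^-3
        topo = Topology(pd.DataFrame({"bead": [0], "molecule": [0],
                                      "species": ["W"], "role": ["W"]}))
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 2] = 0.03
        traj = Trajectory(pos, np.tile([5, 5, 10.0], (100, 1)),
                          np.arange(100.0))
        prof = density_profile(traj, topo, role="W", bin_width=0.1)
        nz = prof.density[prof.density > 0]
        assert len(nz) == 1
        np.testing.assert_allclose(nz[0], 1 / (5 * 5 * 0.1), rtol=1e-12)
        assert prof.density.sum() * 0.1 * 25 == pytest.approx(1.0)

    def test_uniform_water_profile_flat_within_poisson_noise(self):
        rng = np.random.default_rng(0)
        n, frames, box = 2000, 30, 6.0
        topo = Topology(pd.DataFrame({
            "bead": np.arange(n), "molecule": np.arange(n),
            "species": ["W"] * n, "role": ["W"] * n}))
        pos = rng.random((frames, n, 3)) * box
        pos[:, :, 2] -= box / 2
        traj = Trajectory(pos, np.tile([box, box, box], (frames, 1)),
                          np.arange(float(frames)))
        prof = density_profile(traj, topo, role="W", bin_width=0.2)
        inside = np.abs(prof.centers) < box / 2 - 0.2
        expected = n / box ** 3
        counts_per_bin = expected * box * box * 0.2 * frames
        sigma = expected / np.sqrt(counts_per_bin)
        assert np.all(np.abs(prof.density[inside] - expected) < 4 * sigma)

    def test_integral_recovers_mean_count_for_every_group(self, uni2_centered):
        _, traj, topo, _, _ = uni2_centered
        area = traj.boxes[0, 0] * traj.boxes[0, 1]
        for kw, count in [
            (dict(species="TO", roles=("GLYC_A1", "GLYC_B", "GLYC_A3")), 18),
            (dict(species="POPC", role="PHOS"), 256),
            (dict(role="W"), len(topo.indices(role="W"))),
        ]:
            prof = density_profile(traj, topo, **kw)
            integral = prof.density.sum() * prof.bin_width * area
            assert integral == pytest.approx(count, rel=1e-3)

    def test_symmetric_preset_profile_is_mirror_symmetric(self):
        # structural symmetry: static interfacial TO (the dynamic leaflet
        # balance is covered by the 20-seed test in test_generator)
        cfg = preset("SYMMETRIC2", seed=21, duration_scaled_us=20.0,
                     hop_rate=0.0, to_center_fraction=0.0)
        traj, topo, _ = generate_trajectory(cfg)
        traj = center_frames(traj, topo)
        prof = density_profile(traj, topo, species="TO",
                               roles=("GLYC_A1", "GLYC_B", "GLYC_A3"))
        d = prof.density
        asym = np.abs(d - d[::-1])
        # per-bin Poisson noise (frames are independent under jitter only)
        area = traj.boxes[0, 0] * traj.boxes[0, 1]
        counts = d * area * prof.bin_width * traj.n_frames
        sigma = np.sqrt(np.maximum(counts + counts[::-1], 1.0)) / (
            area * prof.bin_width * traj.n_frames)
        assert np.mean(asym <= 4 * sigma) > 0.95

    def test_empty_group_raises_naming_selector(self, uni2_run):
        _, traj, topo, _ = uni2_run
        with pytest.raises(ValueError, match="NOPE"):
            density_profile(traj, topo, role="NOPE")


class TestPartitionRegions:
    @staticmethod
    def _gaussian_mixture_profile(mus, sigma=0.3, weights=None,
                                  bin_width=0.05, zmax=3.0):
        edges = np.arange(-zmax, zmax + bin_width, bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        weights = weights or [1.0] * len(mus)
        dens = sum(w * norm.pdf(centers, mu, sigma)
                   for mu, w in zip(mus, weights))
        return DensityProfile(edges=edges, density=dens, n_frames=1, group="x")

    def test_trimodal_boundaries_match_brute_force_minima(self):
        prof = self._gaussian_mixture_profile([-1.6, 0.0, 1.6])
        regions = partition_regions(prof)
        # independent oracle: dense-grid minima of the analytic mixture
        grid = np.linspace(0.05, 1.55, 20001)
        mix = sum(norm.pdf(grid, m, 0.3) for m in (-1.6, 0.0, 1.6))
        z_min = grid[np.argmin(mix)]
        assert regions.z_upper_boundary == pytest.approx(z_min, abs=0.1)
        assert regions.z_lower_boundary == pytest.approx(-z_min, abs=0.1)
        assert regions.z_upper_boundary == pytest.approx(0.8, abs=0.1)

    def test_bimodal_profile_falls_back_to_phosphate_fraction(self):
        prof = self._gaussian_mixture_profile([-1.35, 1.35])
        phos = self._gaussian_mixture_profile([-1.9, 1.9])
        regions = partition_regions(prof, phosphate_profile=phos)
        assert regions.z_upper_boundary == pytest.approx(0.5 * 1.9, abs=0.06)
        assert regions.z_lower_boundary == pytest.approx(-0.5 * 1.9, abs=0.06)

    def test_bimodal_without_phosphate_profile_raises(self):
        prof = self._gaussian_mixture_profile([-1.35, 1.35])
        with pytest.raises(ValueError, match="phosphate"):
            partition_regions(prof)

    def test_mirror_image_profile_gives_mirror_boundaries(self):
        prof = self._gaussian_mixture_profile([-1.7, -0.1, 1.5],
                                              weights=[1.0, 0.5, 0.8])
        mirrored = DensityProfile(edges=prof.edges,
                                  density=prof.density[::-1].copy(),
                                  n_frames=1, group="x")
        r1 = partition_regions(prof)
        r2 = partition_regions(mirrored)
        assert r1.z_upper_boundary == pytest.approx(-r2.z_lower_boundary,
                                                    abs=1e-9)
        assert r1.z_lower_boundary == pytest.approx(-r2.z_upper_boundary,
                                                    abs=1e-9)

    def test_no_interfacial_peaks_raises(self):
        prof = self._gaussian_mixture_profile([0.0], weights=[0.0])
        with pytest.raises(ValueError, match="interfacial peak"):
            partition_regions(prof)

    def test_regions_tile_membrane_without_overlap(self, uni2_centered):
        _, _, _, _, regions = uni2_centered
        assert regions.z_lower_boundary < 0 < regions.z_upper_boundary


class TestPartitionCoefficient:
    @staticmethod
    def _pinned_to_system(z_values, n_frames=200):
        rows = []
        for m in range(len(z_values)):
            for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
                rows.append((len(rows), m, "TO", role))
        # one phosphate so centering-adjacent ops work if needed
        topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule",
                                                    "species", "role"]))
        pos = np.zeros((n_frames, 3 * len(z_values), 3))
        for m, z in enumerate(z_values):
            pos[:, 3 * m: 3 * m + 3, 2] = z
        traj = Trajectory(pos, np.tile([5, 5, 9.0], (n_frames, 1)),
                          np.arange(float(n_frames)))
        return traj, topo

    def test_two_middle_six_interfacial_gives_exactly_one_third(self,
                                                                regions_pm085):
        traj, topo = self._pinned_to_system([0.0, 0.1] + [1.3] * 4 + [-1.3] * 2)
        ratio, se, series = partition_coefficient(traj, topo, regions_pm085)
        assert ratio == pytest.approx(1 / 3, abs=1e-12)
        assert np.all(series == 2)

    def test_all_interfacial_gives_zero(self, regions_pm085):
        traj, topo = self._pinned_to_system([1.3, -1.3, 1.2])
        ratio, _, _ = partition_coefficient(traj, topo, regions_pm085)
        assert ratio == 0.0

    def test_all_middle_raises_undefined_ratio(self, regions_pm085):
        traj, topo = self._pinned_to_system([0.0, 0.1])
        with pytest.raises(ValueError, match="undefined"):
            partition_coefficient(traj, topo, regions_pm085)

    def test_few_frames_warns(self, regions_pm085):
        traj, topo = self._pinned_to_system([0.0, 1.3], n_frames=10)
        with pytest.warns(UserWarning, match="100 frames"):
            partition_coefficient(traj, topo, regions_pm085)

    def test_invariant_under_frame_permutation(self, uni2_centered):
        _, traj, topo, _, regions = uni2_centered
        ratio1, _, _ = partition_coefficient(traj, topo, regions)
        rng = np.random.default_rng(1)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(traj.positions[perm], traj.boxes[perm],
                              traj.times_ps.copy(), traj.time_scale_factor)
        ratio2, _, _ = partition_coefficient(shuffled, topo, regions)
        assert ratio1 == pytest.approx(ratio2, rel=1e-12)


class TestBilayerGeometry:
    def test_planted_planes_zero_jitter_exact_thickness(self):
        cfg = GeneratorConfig(n_popc_upper=128, n_popc_lower=128, n_to=6,
                              box_xy=8.78, jitter_sd=0.0, water_density=0.0,
                              duration_scaled_us=0.2, seed=1)
        traj, topo, _ = generate_trajectory(cfg)
        geo = bilayer_geometry(traj, topo)
        assert geo["thickness_nm"] == pytest.approx(3.8, abs=1e-5)
        assert geo["area_per_lipid_popc_only_nm2"] == pytest.approx(
            2 * 8.78 ** 2 / 256, rel=1e-9)
        assert geo["area_per_lipid_nm2"] == pytest.approx(
            2 * 8.78 ** 2 / 262, rel=1e-9)

    def test_jittered_planes_within_bin_width(self):
        cfg = GeneratorConfig(n_popc_upper=128, n_popc_lower=128, n_to=0,
                              box_xy=8.78, jitter_sd=0.1, water_density=0.0,
                              duration_scaled_us=2.0, seed=2)
        traj, topo, _ = generate_trajectory(cfg)
        geo = bilayer_geometry(traj, topo)
        assert abs(geo["thickness_nm"] - 3.8) <= 0.1

    def test_single_leaflet_raises(self):
        rows = [(i, i, "POPC", "PHOS") for i in range(4)]
        topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule",
                                                    "species", "role"]))
        pos = np.full((3, 4, 3), 1.9)
        traj = Trajectory(pos, np.tile([5, 5, 9.0], (3, 1)), np.arange(3.0))
        with pytest.raises(ValueError, match="[Ss]ingle-leaflet"):
            bilayer_geometry(traj, topo)
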