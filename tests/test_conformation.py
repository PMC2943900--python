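"""Tail vectors, splay classification, Monte-Carlo oracle, order parameters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgblister import (Frame, Topology, Trajectory, classify_splay,
                       generate_trajectory, intertail_angle_fraction,
                       order_parameters, preset, splay_fractions_by_region,
                       tail_vectors)
from tgblister.generator import (BEADS_PER_CHAIN, BOND_LENGTH,
                                 sample_uniform_dirs)


def _to_molecule_frame(glyc=(0.0, 0.0, 0.0), terminals=None, box=10.0):
    """One TO molecule with 1-bead chains anchored at coincident glycerols."""
    terminals = terminals or [(0, 0, -1.5), (0.5, 0, -1.4), (-0.5, 0, -1.4)]
    rows, pos = [], []
    for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
        rows.append((len(rows), 0, "TO", role))
        pos.append(glyc)
    for c, t in enumerate(terminals, start=1):
        rows.append((len(rows), 0, "TO", f"TAIL{c}_1"))
        pos.append(t)
    topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule", "species",
                                                "role"]))
    frame = Frame(np.asarray(pos, dtype=float), np.array([box, box, box]), 0.0)
    return frame, topo


class TestTailVectors:
    def test_vector_from_glycerol_to_terminal_bead(self):
        frame, topo = _to_molecule_frame()
        v = tail_vectors(frame, topo, 0)
        assert v.shape == (3, 3)
        np.testing.assert_allclose(v[0], [0, 0, -1.5])

    def test_pbc_split_chain_uses_minimum_image(self):
        frame, topo = _to_molecule_frame(glyc=(0.2, 5.0, 5.0),
                                         terminals=[(9.8, 5.0, 5.0),
                                                    (0.2, 5.0, 4.0),
                                                    (0.2, 5.0, 6.0)])
        v = tail_vectors(frame, topo, 0)
        np.testing.assert_allclose(v[0], [-0.4, 0.0, 0.0], atol=1e-12)

    def test_popc_has_exactly_two_vectors(self, uni2_run):
        _, traj, topo, _ = uni2_run
        popc_mol = int(topo.molecules("POPC")[0])
        v = tail_vectors(traj.frame(0), topo, popc_mol)
        assert v.shape == (2, 3)

    def test_unknown_molecule_raises(self):
        frame, topo = _to_molecule_frame()
        with pytest.raises(ValueError, match="unknown molecule"):
            tail_vectors(frame, topo, 99)


class TestClassifySplay:
    @pytest.mark.parametrize("t12,t23,expected", [
        (0.0, 0.0, "NOT"),
        (120.0, 30.0, "PARTIAL"),
        (30.0, 120.0, "PARTIAL"),
        (135.0, 135.0, "FULL"),
        (90.0, 90.0, "NOT"),  # threshold is strict
    ])
    def test_rule_table(self, t12, t23, expected):
        assert classify_splay(t12, t23) == expected

    @pytest.mark.parametrize("t12,t23", [(-1, 10), (10, 181)])
    def test_out_of_range_raises(self, t12, t23):
        with pytest.raises(ValueError, match="0, 180"):
            classify_splay(t12, t23)

    @given(st.floats(0, 180), st.floats(0, 180), st.floats(10, 170))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_under_angle_swap(self, a, b, thr):
        assert classify_splay(a, b, thr) == classify_splay(b, a, thr)


class TestSplayFractions:
    def test_class_fractions_sum_to_one_per_region(self, uni2_centered):
        _, traj, topo, _, regions = uni2_centered
        fr = splay_fractions_by_region(traj, topo, regions)
        for region, classes in fr.items():
            assert sum(classes.values()) == pytest.approx(1.0)

    def test_middle_more_fully_splayed_than_interface(self, uni2_centered):
        _, traj, topo, _, regions = uni2_centered
        fr = splay_fractions_by_region(traj, topo, regions)
        assert fr["middle"]["FULL"] > fr["interface"]["FULL"]

    def test_invariant_under_quarter_turn_about_z(self, uni2_centered):
        _, traj, topo, _, regions = uni2_centered
        fr1 = splay_fractions_by_region(traj, topo, regions)
        L = traj.boxes[0, 0]
        pos = traj.positions.copy().astype(float)
        x, y = pos[..., 0].copy(), pos[..., 1].copy()
        pos[..., 0], pos[..., 1] = y, (L - x) % L
        rot = Trajectory(pos, traj.boxes.copy(), traj.times_ps.copy(),
                         traj.time_scale_factor)
        fr2 = splay_fractions_by_region(rot, topo, regions)
        for region in fr1:
            for cls in fr1[region]:
                assert fr1[region][cls] == pytest.approx(fr2[region][cls],
                                                         abs=1e-12)

    def test_middle_region_matches_independent_monte_carlo_oracle(self):
        # pipeline route: generator with all TO mid-plane, uniform tail axes
        cfg = preset("UNI2", seed=17, duration_scaled_us=54.0, hop_rate=0.0,
                     to_center_fraction=1.0, water_density=0.0)
        traj, topo, _ = generate_trajectory(cfg)
        from tgblister import RegionPartition
        fr = splay_fractions_by_region(traj, topo,
                                       RegionPartition(-0.85, 0.85))
        n_pipeline = 6 * traj.n_frames
        # independent oracle: fresh Monte Carlo of the isotropic tail model
        rng = np.random.default_rng(99)
        n_mc = 400_000
        tails = sample_uniform_dirs(rng, (3, n_mc)) * (
            BOND_LENGTH * BEADS_PER_CHAIN)
        tails += rng.normal(0.0, 0.1 * np.sqrt(2), tails.shape)
        over12 = np.einsum("ij,ij->i", tails[0], tails[1]) < 0
        over23 = np.einsum("ij,ij->i", tails[1], tails[2]) < 0
        mc = {"FULL": (over12 & over23).mean(),
              "PARTIAL": (over12 ^ over23).mean(),
              "NOT": (~over12 & ~over23).mean()}
        for cls, p_mc in mc.items():
            sigma = np.sqrt(p_mc * (1 - p_mc) * (1 / n_pipeline + 1 / n_mc))
            assert abs(fr["middle"][cls] - p_mc) < 4 * sigma

    def test_all_parallel_tails_are_not_splayed(self, to_points_factory):
        # build TO molecules with explicitly parallel chains
        frame_traj, topo = _parallel_tail_system()
        from tgblister import RegionPartition
        fr = splay_fractions_by_region(frame_traj, topo,
                                       RegionPartition(-0.85, 0.85))
        for region, classes in fr.items():
            assert classes["NOT"] == pytest.approx(1.0)


def _parallel_tail_system():
    rows, pos = [], []
    for m, zc in enumerate([1.3, -1.3, 0.0]):  # both regions populated
        for role in ("GLYC_A1", "GLYC_B", "GLYC_A3"):
            rows.append((len(rows), m, "TO", role))
            pos.append((1.0 + m, 1.0, zc))
        for c in (1, 2, 3):
            rows.append((len(rows), m, "TO", f"TAIL{c}_1"))
            pos.append((1.0 + m, 1.0, zc - 1.0))
    topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule", "species",
                                                "role"]))
    arr = np.asarray(pos)[None, :, :]
    traj = Trajectory(arr, [[8.0, 8.0, 9.0]], [0.0])
    return traj, topo


class TestIntertail:
    def _popc_like(self, angle_deg):
        rows, pos = [], []
        rows += [(0, 0, "POPC", "PHOS"), (1, 0, "POPC", "GLYC_A1"),
                 (2, 0, "POPC", "GLYC_B")]
        pos += [(1, 1, 1.9), (1, 1, 1.45), (1, 1, 1.2)]
        a = np.radians(angle_deg)
        rows.append((3, 0, "POPC", "TAIL1_1"))
        pos.append((1, 1, 1.45 - 1.5))
        rows.append((4, 0, "POPC", "TAIL2_1"))
        pos.append((1 + 1.5 * np.sin(a), 1, 1.2 - 1.5 * np.cos(a)))
        topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule",
                                                    "species", "role"]))
        traj = Trajectory(np.asarray(pos)[None], [[8, 8, 9.0]], [0.0])
        return traj, topo

    def test_parallel_tails_fraction_zero(self):
        traj, topo = self._popc_like(0.0)
        assert intertail_angle_fraction(traj, topo) == 0.0

    def test_antiparallel_tails_fraction_one(self):
        traj, topo = self._popc_like(180.0)
        assert intertail_angle_fraction(traj, topo) == 1.0

    def test_three_tailed_species_redirected_to_splay(self, uni2_run):
        _, traj, topo, _ = uni2_run
        with pytest.raises(ValueError, match="splay"):
            intertail_angle_fraction(traj, topo, species="TO")


class TestOrderParameters:
    def _bond_system(self, direction, n_mol=1, upper=True, rng=None):
        """POPC-like single-chain molecules with 2-bead tails along a vector."""
        rows, pos = [], []
        z0 = 1.45 if upper else -1.45
        for m in range(n_mol):
            d = direction if rng is None else rng
            if callable(d):
                d = d(m)
            d = np.asarray(d, dtype=float)
            d /= np.linalg.norm(d)
            anchor = np.array([1.0 + 0.01 * m, 1.0, z0])
            rows.append((len(rows), m, "POPC", "PHOS"))
            pos.append(anchor + [0, 0, 0.45 if upper else -0.45])
            rows.append((len(rows), m, "POPC", "GLYC_A1"))
            pos.append(anchor)
            rows.append((len(rows), m, "POPC", "GLYC_B"))
            pos.append(anchor)
            for c in (1, 2):
                for k in (1, 2):
                    rows.append((len(rows), m, "POPC", f"TAIL{c}_{k}"))
                    pos.append(anchor + d * 0.47 * k)
        topo = Topology(pd.DataFrame(rows, columns=["bead", "molecule",
                                                    "species", "role"]))
        traj = Trajectory(np.asarray(pos)[None], [[50, 50, 50.0]], [0.0])
        return traj, topo

    def test_bonds_along_normal_give_one(self):
        traj, topo = self._bond_system([0, 0, -1.0])
        p2 = order_parameters(traj, topo,
                              bonds=[("TAIL1_1", "TAIL1_2")])
        assert p2["TAIL1_1-TAIL1_2"] == pytest.approx(1.0)

    def test_bonds_perpendicular_to_normal_give_minus_half(self):
        traj, topo = self._bond_system([1.0, 0, 0])
        p2 = order_parameters(traj, topo, bonds=[("TAIL1_1", "TAIL1_2")])
        assert p2["TAIL1_1-TAIL1_2"] == pytest.approx(-0.5)

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(5)
        dirs = sample_uniform_dirs(rng, 4000)
        traj, topo = self._bond_system(None, n_mol=4000,
                                       rng=lambda m: dirs[m])
        p2 = order_parameters(traj, topo, bonds=[("TAIL1_1", "TAIL1_2")])
        # isotropic average of P2 is 0; sd of P2 per bond is sqrt(1/5)
        assert abs(p2["TAIL1_1-TAIL1_2"]) < 3 * np.sqrt(0.2 / 4000)

    def test_undefined_bond_raises(self, uni2_run):
        _, traj, topo, _ = uni2_run
        with pytest.raises(ValueError, match="bond"):
            order_parameters(traj, topo, bonds=[("TAIL1_1", "NOPE")])


class TestSplayTable:
    def test_per_molecule_frame_records(self, uni2_centered):
        from tgblister.conformation import splay_table
        _, traj, topo, _, regions = uni2_centered
        table = splay_table(traj, topo, regions)
        assert len(table) == traj.n_frames * 6
        assert set(table.columns) == {"molecule", "frame", "theta_12_deg",
                                      "theta_23_deg", "class", "region"}
        assert table["class"].isin(("NOT", "PARTIAL", "FULL")).all()
        assert table["theta_12_deg"].between(0, 180).all()
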