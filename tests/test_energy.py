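"""Energy terms against independent scalar oracles, invariances, and forces."""

import math

import numpy as np
import pytest
import scipy.constants as const

from bfbdna.dynamics import build_ideal_duplex
from bfbdna.energy import (CompiledDuplex, bfb_energy, class2,
                           class2_fanbond_energy, debye_huckel_energy,
                           forces, seq_specific_energy, total_energy)
from bfbdna.forcefield import Class2Coefficients
from bfbdna.geometry import DegenerateGeometryError
from bfbdna.topology import build_duplex_topology, complement


# --------------------------------------------------------------------------- #
# independent scalar geometry (oracle-side implementations)


def _angle(a, b, c):
    u, v = a - b, c - b
    return math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return math.atan2(y, np.dot(n1, n2))


def _c2(x, c):
    d = x - c.x0
    return c.k2 * d**2 + c.k3 * d**3 + c.k4 * d**4


class TestClass2:
    @pytest.mark.parametrize("x,c,expected", [
        (0.5, Class2Coefficients(3.0, 1.0, 2.0, 0.5), 0.0),
        (1.5, Class2Coefficients(1.0, 0.0, 0.0, 0.5), 1.0),
        (2.0, Class2Coefficients(1.0, 1.0, 1.0, 1.0), 3.0),
    ])
    def test_spot_values(self, x, c, expected):
        assert class2(x, c) == pytest.approx(expected)


class TestSeqSpecific:
    def test_site_matches_scalar_oracle(self, ff):
        """One interior site evaluated term by term with independent scalar code."""
        topo = build_duplex_topology("ACG")
        rng = np.random.default_rng(7)
        pos = build_ideal_duplex(3) + rng.normal(scale=0.08, size=(6, 3))
        rec = ff.trimers["ACG"]
        # beads: site i=1 pairs j=4; neighbours 0,2 on strand A and 3,5 on B
        expected = (
            _c2(np.linalg.norm(pos[1] - pos[2]), rec.bond_i)
            + _c2(np.linalg.norm(pos[4] - pos[3]), rec.bond_j)
            + _c2(_angle(pos[0], pos[1], pos[2]), rec.angle_i)
            + _c2(_angle(pos[3], pos[4], pos[5]), rec.angle_j)
            + _c2(np.linalg.norm(pos[1] - pos[4]), rec.bond_cross)
            + rec.k_theta_cross * (
                (_angle(pos[1], pos[4], pos[3]) - rec.theta_m) ** 2
                + (_angle(pos[0], pos[1], pos[4]) - rec.theta_m) ** 2
                + (_angle(pos[1], pos[4], pos[5]) - rec.theta_p) ** 2
                + (_angle(pos[2], pos[1], pos[4]) - rec.theta_p) ** 2)
            + rec.k_phi * (
                (1 + math.cos(_dihedral(pos[3], pos[4], pos[1], pos[0]) + rec.phi_m))
                + (1 + math.cos(_dihedral(pos[5], pos[4], pos[1], pos[2]) + rec.phi_p)))
        )
        assert seq_specific_energy(pos, topo, ff) == pytest.approx(expected, rel=1e-12)

    def test_ideal_duplex_is_at_the_minimum(self, ff):
        topo = build_duplex_topology("ACGTACGTACGT")
        pos = build_ideal_duplex(12)
        assert seq_specific_energy(pos, topo, ff) == pytest.approx(0.0, abs=1e-18)

    def test_single_base_pair_has_no_seqspec_terms(self, ff):
        topo = build_duplex_topology("A")
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert total_energy(pos, topo, ff).v_seqspec == 0.0


class TestFanBonds:
    def test_ideal_geometry_contributes_minus_depth_per_pair(self, ff):
        topo = build_duplex_topology("ACGTACGTACGT")
        pos = build_ideal_duplex(12)
        expected = -sum(ff.fan[fp.l].depth for fp in topo.fan_pairs)
        assert bfb_energy(pos, topo, ff) == pytest.approx(expected, rel=1e-9)

    def test_bounded_below_and_above(self, ff, duplex8):
        topo, _, _ = duplex8
        rng = np.random.default_rng(0)
        bound = sum(ff.fan[fp.l].depth for fp in topo.fan_pairs)
        for _ in range(20):
            pos = rng.normal(scale=2.0, size=(16, 3))
            v = bfb_energy(pos, topo, ff)
            assert -bound - 1e-9 <= v <= 0.0

    def test_rupture_cost_is_finite_depth(self, ff, duplex8):
        topo, ideal, _ = duplex8
        far = ideal.copy()
        far[0] += [200.0, 0, 0]  # rip bead 0 out of every fan contact
        lost = bfb_energy(far, topo, ff) - bfb_energy(ideal, topo, ff)
        broken_depth = sum(ff.fan[fp.l].depth for fp in topo.fan_pairs if fp.i == 0
                           or fp.m == 0)
        # fan pairs of bead 0 (and its appearance as partner target) rupture,
        # plus the perturbation of neighbouring sites: cost stays finite
        assert 0 < lost < 2 * broken_depth + 50

    def test_class2_mode_diverges_where_gaussian_plateaus(self, ff, duplex8):
        """Fan-term restoring force: plateaus to zero in gaussian mode, grows
        without bound in class2 mode, as one fan distance is stretched."""
        topo, ideal, _ = duplex8

        def fan_force(energy_fn, stretch, h=1e-5):
            def e(x):
                pos = ideal.copy()
                pos[0] += [x, 0, 0]
                return energy_fn(pos, topo)
            return -(e(stretch + h) - e(stretch - h)) / (2 * h)

        prev_g, prev_c = None, None
        for stretch in (2.0, 8.0, 32.0):
            fg = abs(fan_force(lambda p, t: bfb_energy(p, t, ff), stretch))
            fc = abs(fan_force(lambda p, t: class2_fanbond_energy(p, t, ff.with_mode("class2")),
                               stretch))
            if prev_c is not None:
                assert fc > 3 * prev_c      # unbounded growth
                assert fg < prev_g / 3      # force plateaus toward zero
            prev_g, prev_c = fg, fc
        assert fg < 0.05  # negligible vs the ~100 kJ/mol/nm bonded scale

    def test_class2_equilibrium_zero_and_modes_differ(self, ff, duplex8):
        topo, ideal, perturbed = duplex8
        assert class2_fanbond_energy(ideal, topo, ff) == pytest.approx(0.0, abs=1e-9)
        g = bfb_energy(perturbed, topo, ff)
        c = class2_fanbond_energy(perturbed, topo, ff)
        assert g != pytest.approx(c)


class TestDebyeHuckel:
    def test_single_pair_matches_constants_first_oracle(self, ff):
        """Two charges at 1 nm vs an evaluation built from CODATA constants."""
        es = ff.electrostatics
        topo = build_duplex_topology("A")
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        r = 1e-9
        lam = math.sqrt(const.epsilon_0 * es.dielectric * const.k * es.temperature
                        / (2 * const.N_A * 150.0 * const.e**2))
        v_joule = ((-0.6 * const.e) ** 2 * const.N_A / (4 * math.pi * const.epsilon_0
                   * es.dielectric * r) * math.exp(-r / lam))
        expected_kj = const.N_A * (-0.6) ** 2 * const.e**2 / (
            4 * math.pi * const.epsilon_0 * es.dielectric * r) * math.exp(-r / lam) / 1000.0
        assert debye_huckel_energy(pos, topo, es) == pytest.approx(expected_kj, rel=1e-6)
        assert v_joule > 0  # like charges repel

    def test_monotone_decay(self, ff):
        es = ff.electrostatics
        topo = build_duplex_topology("A")
        vals = [debye_huckel_energy(np.array([[0, 0, 0], [r, 0, 0]], float), topo, es)
                for r in (0.5, 1.0, 1.5, 2.0)]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))

    def test_zero_charge_contributes_nothing(self, ff, duplex8):
        topo, _, pos = duplex8
        es = ff.electrostatics
        q = np.full(16, es.charge)
        q[3] = 0.0
        moved = pos.copy()
        moved[3] += [0.2, 0, 0]
        assert (debye_huckel_energy(pos, topo, es, charges=q)
                == pytest.approx(debye_huckel_energy(moved, topo, es, charges=q)))

    def test_coincident_beads_raise(self, ff):
        topo = build_duplex_topology("A")
        pos = np.zeros((2, 3))
        with pytest.raises(DegenerateGeometryError):
            debye_huckel_energy(pos, topo, ff.electrostatics)


class TestTotalEnergy:
    def test_total_is_sum_of_parts(self, ff, duplex8):
        topo, _, pos = duplex8
        eb = total_energy(pos, topo, ff, ledger=True)
        assert eb.v_total == pytest.approx(eb.v_seqspec + eb.v_dhelix + eb.v_elec)
        assert eb.site_ledger.sum() == pytest.approx(eb.v_seqspec)
        assert eb.fan_ledger.sum() == pytest.approx(eb.v_dhelix)

    def test_rigid_motion_invariance(self, ff, duplex8):
        from scipy.spatial.transform import Rotation

        topo, _, pos = duplex8
        eb0 = total_energy(pos, topo, ff)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pos @ rot.T + np.array([5.0, -3.0, 11.0])
        eb1 = total_energy(moved, topo, ff)
        for attr in ("v_seqspec", "v_dhelix", "v_elec"):
            assert getattr(eb1, attr) == pytest.approx(getattr(eb0, attr), rel=1e-8)

    def test_reverse_complement_relabeling_invariance(self, ff):
        rng = np.random.default_rng(5)
        for seq in ("ACGTTGCA", "GGGACGTA", "TTACGCAT"):
            n = len(seq)
            topo = build_duplex_topology(seq)
            pos = build_ideal_duplex(n) + rng.normal(scale=0.05, size=(2 * n, 3))
            rc_topo = build_duplex_topology(complement(seq))
            rc_pos = np.vstack([pos[n:], pos[:n]])
            e1 = total_energy(pos, topo, ff).v_total
            e2 = total_energy(rc_pos, rc_topo, ff).v_total
            assert e2 == pytest.approx(e1, rel=1e-8)


class TestForces:
    def test_matches_central_finite_differences(self, ff, duplex8):
        topo, _, pos = duplex8
        for mode in ("gaussian", "class2"):
            cd = CompiledDuplex(topo, ff.with_mode(mode))
            _, F = cd.energy_forces(pos)
            scale = np.abs(F).max()
            h = 1e-5
            for bead in range(16):
                for k in range(3):
                    p1, p2 = pos.copy(), pos.copy()
                    p1[bead, k] += h
                    p2[bead, k] -= h
                    fd = -(cd.energy(p1) - cd.energy(p2)) / (2 * h)
                    assert abs(fd - F[bead, k]) <= 1e-4 * scale

    def test_net_force_and_torque_vanish(self, ff):
        rng = np.random.default_rng(11)
        topo = build_duplex_topology("ACGTTGCA")
        for _ in range(5):
            pos = build_ideal_duplex(8) + rng.normal(scale=0.05, size=(16, 3))
            F = forces(pos, topo, ff)
            scale = np.abs(F).max()
            assert np.abs(F.sum(axis=0)).max() <= 1e-8 * scale
            tau = np.cross(pos, F).sum(axis=0)
            assert np.abs(tau).max() <= 1e-8 * scale

    def test_near_zero_on_equilibrium_built_duplex(self, ff):
        """Bonded terms are exactly minimized on the ideal helix; only the
        weak electrostatic repulsion remains."""
        topo = build_duplex_topology("ACGTACGTACGTACGT")
        pos = build_ideal_duplex(16)
        F = forces(pos, topo, ff)
        assert np.abs(F[4:-4]).max() < 3.0  # kJ/mol/nm, electrostatic residue

    def test_degenerate_geometry_raises(self, ff, duplex8):
        topo, ideal, _ = duplex8
        bad = ideal.copy()
        bad[2] = bad[3]  # coincident strand neighbours
        with pytest.raises(DegenerateGeometryError):
            forces(bad, topo, ff)
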