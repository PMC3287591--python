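"""Occupancy statistics and dipole order parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaperm.synthetic_data import (
    make_oriented_waters,
    oriented_waters_channel_def,
)
from aquaperm.water_structure import (
    occupancy_histogram,
    order_parameters,
    water_dipole,
    water_triples,
)
from conftest import make_scripted_channel


def pooled(profile):
    """Sample-weighted overall P1 and P2 of a profile."""
    w = profile.n_samples
    ok = w > 0
    return (
        float(np.sum(profile.P1[ok] * w[ok]) / w[ok].sum()),
        float(np.sum(profile.P2[ok] * w[ok]) / w[ok].sum()),
    )


class TestOccupancy:
    def test_scripted_sequence(self):
        # frames alternating between 7 and 8 waters inside
        z = np.full((4, 8), 0.0)
        z[0, 7] = z[2, 7] = 50.0  # 8th water out in frames 0 and 2
        z[:, :7] += np.linspace(-8, 8, 7)[None, :]
        traj, cdef = make_scripted_channel(z)
        occ = occupancy_histogram(traj, cdef)
        assert occ.mean == pytest.approx(7.5)
        assert occ.sd == pytest.approx(np.std([7, 8, 7, 8], ddof=1))
        assert occ.frame_counts[7] == 2 and occ.frame_counts[8] == 2

    def test_empty_channel(self):
        traj, cdef = make_scripted_channel(np.full((5, 3), 50.0))
        occ = occupancy_histogram(traj, cdef)
        assert occ.mean == 0.0
        assert occ.sd == 0.0

    def test_mean_consistent_with_histogram(self, small_sim):
        _, traj, _, _, cdefs = small_sim
        occ = occupancy_histogram(traj, cdefs[0])
        assert occ.frame_counts.sum() == occ.n_frames  # validator also enforces


class TestWaterDipole:
    def test_symmetric_water_points_along_bisector(self):
        d = water_dipole([0, 0, 0], [0.76, 0.59, 0], [-0.76, 0.59, 0])
        np.testing.assert_allclose(d, [0, 1, 0], atol=1e-12)

    def test_both_hydrogens_up(self):
        d = water_dipole([0, 0, 0], [0.3, 0, 0.9], [-0.3, 0, 0.9])
        np.testing.assert_allclose(d, [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        o = rng.normal(size=3)
        h1, h2 = o + rng.normal(size=3) * 0.5, o + rng.normal(size=3) * 0.5
        R = Rotation.random(random_state=3).as_matrix()
        d = water_dipole(o, h1, h2)
        d_rot = water_dipole(R @ o, R @ h1, R @ h2)
        np.testing.assert_allclose(d_rot, R @ d, atol=1e-10)

    def test_coincident_atoms_error(self):
        with pytest.raises(ValueError, match="dipole"):
            water_dipole([0, 0, 0], [0, 0, 0], [0, 0, 0])

    def test_charge_weighted_matches_geometric_for_symmetric_charges(self):
        o, h1, h2 = np.zeros(3), np.array([0.76, 0.59, 0]), np.array([-0.76, 0.59, 0])
        geo = water_dipole(o, h1, h2)
        chg = water_dipole(o, h1, h2, charges=(-0.834, 0.417, 0.417))
        np.testing.assert_allclose(geo, chg, atol=1e-12)


class TestOrderParameters:
    def test_aligned_plus_z_limits(self):
        traj = make_oriented_waters(400, "aligned+z", seed=1)
        prof = order_parameters(traj, oriented_waters_channel_def())
        p1, p2 = pooled(prof)
        assert p1 == pytest.approx(1.0, abs=1e-9)
        assert p2 == pytest.approx(1.0, abs=1e-9)

    def test_perpendicular_limits(self):
        traj = make_oriented_waters(400, "perpendicular", seed=2)
        prof = order_parameters(traj, oriented_waters_channel_def())
        p1, p2 = pooled(prof)
        assert p1 == pytest.approx(0.0, abs=1e-9)
        assert p2 == pytest.approx(-0.5, abs=1e-9)

    def test_isotropic_averages_to_zero(self):
        traj = make_oriented_waters(100_000, "isotropic", seed=3)
        prof = order_parameters(traj, oriented_waters_channel_def(), bin_width=2.0)
        p1, p2 = pooled(prof)
        assert abs(p1) <= 0.01
        assert abs(p2) <= 0.01

    def test_flipping_dipoles_negates_P1_only(self):
        traj = make_oriented_waters(300, "bipolar", seed=4)
        cdef = oriented_waters_channel_def()
        prof = order_parameters(traj, cdef)
        # mirror every H through its O: dipoles flip exactly
        triples = water_triples(traj)
        coords = traj.frames[0].coords.copy()
        for o, h1, h2 in triples:
            coords[h1] = 2 * coords[o] - coords[h1]
            coords[h2] = 2 * coords[o] - coords[h2]
        flipped = type(traj)(
            traj.topology,
            [type(traj.frames[0])(time=0.0, coords=coords)],
            traj.frame_interval,
        )
        prof_f = order_parameters(flipped, cdef)
        np.testing.assert_allclose(prof_f.P1, -prof.P1, atol=1e-9)
        np.testing.assert_allclose(prof_f.P2, prof.P2, atol=1e-9)

    def test_bipolar_signature(self):
        traj = make_oriented_waters(2000, "bipolar", midplane=2.0, seed=5)
        prof = order_parameters(traj, oriented_waters_channel_def(), bin_width=1.0)
        sign = np.sign(prof.P1)
        flips = prof.z_centers[:-1][np.diff(sign) != 0]
        assert len(flips) == 1
        assert abs(flips[0] - 2.0) <= 1.0
        assert abs(prof.z_centers[np.nanargmin(prof.P2)] - 2.0) <= 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds_always_hold(self, seed):
        traj = make_oriented_waters(50, "isotropic", seed=seed)
        prof = order_parameters(traj, oriented_waters_channel_def(), bin_width=4.0)
        ok = prof.n_samples > 0
        assert np.all(prof.P1[ok] >= -1 - 1e-12) and np.all(prof.P1[ok] <= 1 + 1e-12)
        assert np.all(prof.P2[ok] >= -0.5 - 1e-12) and np.all(prof.P2[ok] <= 1 + 1e-12)
        assert np.all(np.isnan(prof.P1[~ok]))

    def test_empty_profile_warns(self):
        traj, cdef = make_scripted_channel(np.full((2, 1), 50.0))
        # no real waters with hydrogens here: triples are empty
        with pytest.raises(ValueError, match="triples"):
            order_parameters(traj, cdef)
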