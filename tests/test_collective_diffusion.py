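"""Collective coordinate, multi-origin MSD, D_n fitting and p_f."""

import numpy as np
import pytest

from aquaperm.collective_diffusion import (
    CollectiveCoordinateSeries,
    collective_coordinate,
    fit_Dn,
    msd_multi_origin,
    osmotic_permeability,
    pf_pd_ratio,
    single_channel_from_membrane_permeability,
)
from conftest import make_scripted_channel


def series(n, dt=2.0):
    n = np.asarray(n, dtype=float)
    return CollectiveCoordinateSeries(
        monomer_id="A",
        times=np.arange(len(n)) * dt,
        n_values=n,
        channel_length_used=20.0,
    )


class TestCollectiveCoordinate:
    def test_single_water_translating_inside(self):
        # water moves 18 A along +z while staying inside the 20-A CR
        traj, cdef = make_scripted_channel(np.linspace(-9.0, 9.0, 10)[:, None])
        L = 20.0
        s = collective_coordinate(traj, cdef, L, mode="both_inside")
        assert s.n_values[0] == 0.0
        assert s.n_values[-1] == pytest.approx(18.0 / L)

    def test_static_frames_give_zero(self):
        traj, cdef = make_scripted_channel(np.zeros((6, 3)))
        s = collective_coordinate(traj, cdef, 20.0)
        assert np.all(s.n_values == 0.0)

    def test_matches_cumsum_oracle(self):
        rng = np.random.default_rng(5)
        z = np.cumsum(rng.normal(0, 0.8, size=(200, 6)), axis=0)
        traj, cdef = make_scripted_channel(z)
        L = 20.0
        s = collective_coordinate(traj, cdef, L, mode="both_inside")
        # independent oracle: literal loop over frame pairs
        n = [0.0]
        for f in range(199):
            dn = 0.0
            for w in range(6):
                if -10 <= z[f, w] < 10 and -10 <= z[f + 1, w] < 10:
                    dn += (z[f + 1, w] - z[f, w]) / L
            n.append(n[-1] + dn)
        np.testing.assert_allclose(s.n_values, n, atol=1e-12)

    def test_clipped_mode_counts_boundary_half_steps(self):
        # one water steps from just below the CR to just inside: the clipped
        # rule credits the inside part of the displacement, the strict rule
        # credits nothing
        z = np.array([[-10.5], [-9.5]])
        traj, cdef = make_scripted_channel(z)
        strict = collective_coordinate(traj, cdef, 20.0, mode="both_inside")
        clipped = collective_coordinate(traj, cdef, 20.0, mode="either_clipped")
        assert strict.n_values[-1] == 0.0
        assert clipped.n_values[-1] == pytest.approx(0.5 / 20.0)

    def test_requires_positive_length(self):
        traj, cdef = make_scripted_channel(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            collective_coordinate(traj, cdef, 0.0)


class TestMsdMultiOrigin:
    def test_pure_drift_is_quadratic(self):
        c = 0.03
        t = np.arange(501) * 2.0
        msd = msd_multi_origin(series(c * t), window_length=100.0)
        np.testing.assert_allclose(msd.msd, (c * msd.lags) ** 2, atol=1e-12)

    def test_constant_series_is_zero(self):
        # n(0) = 0 by definition, so a constant series is identically zero
        msd = msd_multi_origin(series(np.zeros(501)), window_length=100.0)
        assert np.all(msd.msd == 0.0)
        assert msd.msd[0] == 0.0

    def test_20ns_100ps_nonoverlapping_gives_200_origins(self):
        n = np.zeros(10001)  # 20 ns at 2 ps
        msd = msd_multi_origin(series(n), window_length=100.0, origin_stride=100.0)
        assert msd.n_origins == 200

    def test_single_origin_definition(self):
        rng = np.random.default_rng(2)
        n = np.cumsum(rng.normal(size=301))
        n[0] = 0
        msd = msd_multi_origin(series(n), window_length=500.0, origin_stride=50.0)
        # first origin's own contribution: average includes it
        assert msd.msd[1] >= 0

    def test_time_reversal_leaves_diffusion_unchanged(self):
        # reversing the trajectory's time order reshuffles which segments
        # fall into which window, but the diffusion constant (hence p_f)
        # must come out the same up to estimator noise
        rng = np.random.default_rng(8)
        dn = rng.normal(0, 0.1, 10_000)
        n = np.concatenate([[0], np.cumsum(dn)])
        rev = np.concatenate([[0], np.cumsum(-dn[::-1])])
        d1 = fit_Dn(msd_multi_origin(series(n), 100.0)).D_n
        d2 = fit_Dn(msd_multi_origin(series(rev), 100.0)).D_n
        assert d2 == pytest.approx(d1, rel=0.05)

    def test_too_few_origins(self):
        with pytest.raises(ValueError, match="origins"):
            msd_multi_origin(series(np.zeros(60)), window_length=100.0)


class TestFitDn:
    def test_exact_linear_input(self):
        lags = np.arange(51) * 2.0
        from aquaperm.collective_diffusion import MsdResult

        msd = MsdResult(lags=lags, msd=2 * 3.0 * lags / 1e3, n_origins=10, window_length=100.0)
        fit = fit_Dn(msd)
        assert fit.D_n == pytest.approx(3.0)

    def test_zero_msd(self):
        from aquaperm.collective_diffusion import MsdResult

        msd = MsdResult(
            lags=np.arange(51) * 2.0, msd=np.zeros(51), n_origins=10, window_length=100.0
        )
        assert fit_Dn(msd).D_n == 0.0

    def test_negative_slope_clamps_with_warning(self):
        from aquaperm.collective_diffusion import MsdResult

        msd = MsdResult(
            lags=np.arange(51) * 2.0,
            msd=-np.arange(51) * 0.01,
            n_origins=10,
            window_length=100.0,
        )
        with pytest.warns(UserWarning, match="clamping"):
            assert fit_Dn(msd).D_n == 0.0

    def test_recovers_random_walk_within_20_percent(self):
        d_true = 2.0  # ns^-1
        dt = 2.0  # ps
        rng = np.random.default_rng(12)
        dn = rng.normal(0.0, np.sqrt(2 * d_true * dt / 1e3), size=10000)
        n = np.concatenate([[0.0], np.cumsum(dn)])
        msd = msd_multi_origin(series(n, dt), window_length=100.0, origin_stride=100.0)
        assert msd.n_origins == 200
        fit = fit_Dn(msd)
        assert fit.D_n == pytest.approx(d_true, rel=0.20)


class TestPermeabilityConversions:
    def test_pf_from_unit_Dn(self):
        assert osmotic_permeability(1.0) == pytest.approx(2.99e-14)

    def test_pf_zero(self):
        assert osmotic_permeability(0.0) == 0.0

    def test_inversion_of_printed_value(self):
        # D_n chosen so that p_f reproduces 6.4e-14 by construction
        d_n = 6.4e-14 / 2.99e-23 / 1e9
        assert osmotic_permeability(d_n) == pytest.approx(6.4e-14)

    @pytest.mark.parametrize(
        "pf, pd, printed",
        [(6.4, 0.7, 9.1), (8.3, 2.8, 3.0), (5.1, 1.2, 4.2), (5.6, 0.7, 8.0)],
    )
    def test_single_fileness_ratios(self, pf, pd, printed):
        assert round(pf_pd_ratio(pf, pd), 1) == printed

    def test_ratio_of_equal_permeabilities(self):
        assert pf_pd_ratio(3.3, 3.3) == 1.0

    def test_zero_pd_reported_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pf_pd_ratio(1.0, 0.0))

    def test_membrane_identity_density(self):
        assert single_channel_from_membrane_permeability(1e4, 1.0) == pytest.approx(1.0)

    def test_doubling_density_halves_pf(self):
        a = single_channel_from_membrane_permeability(57.0, 1e10)
        b = single_channel_from_membrane_permeability(57.0, 2e10)
        assert a == pytest.approx(2 * b)

    def test_experimental_estimate_inversion(self):
        # density chosen so the conversion lands on the published estimate
        density = 57e-4 / 0.7e-14
        assert single_channel_from_membrane_permeability(57.0, density) == pytest.approx(
            0.7e-14
        )
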