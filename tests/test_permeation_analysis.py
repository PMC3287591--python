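"""Permeation events, the rate constant k0 and the diffusive permeability."""

import numpy as np
import pytest

from aquaperm.permeation_analysis import (
    AVOGADRO,
    PhysicalConstants,
    cumulative_counts,
    detect_events,
    diffusive_permeability,
    rate_constant,
    summarize_events,
    water_volume,
)
from conftest import make_scripted_channel


def brute_force_events(z: np.ndarray, z_bottom: float, z_top: float):
    """Independent oracle: per-water scan of boundary-crossing sequences."""
    out = []
    for w in range(z.shape[1]):
        # categorize each frame: 'B', 'I', 'A'
        cats = "".join(
            "I" if z_bottom <= v < z_top else ("B" if v < z_bottom else "A")
            for v in z[:, w]
        )
        side = None
        for i, c in enumerate(cats):
            if c == "I":
                if side is None and i > 0:
                    side = cats[i - 1]
            else:
                if side == "B" and c == "A":
                    out.append((w, "+z"))
                elif side == "A" and c == "B":
                    out.append((w, "-z"))
                side = None
        # waters starting inside have side=None and never complete an event
    return out


class TestDetectEvents:
    def test_monotonic_crossing_is_one_plus_event(self):
        z = np.linspace(-12.0, 12.0, 9)[:, None]
        traj, cdef = make_scripted_channel(z)
        events = detect_events(traj, [cdef])
        assert len(events) == 1
        assert events[0].direction == "+z"
        assert events[0].exit_time > events[0].entry_time

    def test_enter_and_leave_same_side_is_no_event(self):
        z = np.array([12.0, 5.0, 0.0, 5.0, 12.0])[:, None]
        traj, cdef = make_scripted_channel(z)
        assert detect_events(traj, [cdef]) == []

    def test_water_starting_inside_never_completes(self):
        z = np.array([0.0, 5.0, 12.0])[:, None]
        traj, cdef = make_scripted_channel(z)
        assert detect_events(traj, [cdef]) == []

    def test_lateral_vacation_resets_state(self):
        # enters from below, wanders out sideways, re-enters from above side
        z = np.array([[-12.0], [0.0], [0.0], [-12.0]])
        xy = np.zeros((4, 1, 2))
        xy[2, 0, 0] = 9.0  # outside the lateral cutoff at z ~ midpoint
        traj, cdef = make_scripted_channel(z, water_xy=xy)
        assert detect_events(traj, [cdef]) == []

    def test_matches_brute_force_oracle_on_random_scripts(self):
        rng = np.random.default_rng(17)
        n_w, n_f = 50, 400
        # random walks with steps small enough not to jump the whole CR
        z = np.cumsum(rng.uniform(-4, 4, size=(n_f, n_w)), axis=0)
        z += rng.uniform(-15, 15, size=(1, n_w))
        traj, cdef = make_scripted_channel(z)
        got = sorted(
            (e.water_index, e.direction) for e in detect_events(traj, [cdef])
        )
        expected = sorted(brute_force_events(z, -10.0, 10.0))
        assert got == expected
        assert len(got) > 10  # the script actually exercises crossings

    def test_subsampling_invariance(self):
        rng = np.random.default_rng(23)
        z = np.cumsum(rng.uniform(-2.5, 2.5, size=(600, 10)), axis=0)
        traj, cdef = make_scripted_channel(z)
        full = sorted((e.water_index, e.direction) for e in detect_events(traj, [cdef]))
        sub_frames = traj.frames[::2]
        sub = type(traj)(traj.topology, sub_frames, traj.frame_interval * 2)
        subbed = sorted((e.water_index, e.direction) for e in detect_events(sub, [cdef]))
        assert subbed == full

    def test_equals_simulator_log(self, small_sim):
        _, traj, _, sim_events, cdefs = small_sim
        det = detect_events(traj, cdefs)
        assert sorted((e.water_index, e.direction) for e in det) == sorted(
            (e.water_index, e.direction) for e in sim_events
        )

    def test_needs_two_frames(self):
        traj, cdef = make_scripted_channel(np.array([[0.0]]))
        with pytest.raises(ValueError):
            detect_events(traj, [cdef])


class TestRateConstant:
    def test_printed_worked_example(self):
        # 69 events over 4 channels and 19 ns -> 0.45... ~ 0.5 /ns
        assert rate_constant(69, 4, 19.0) == pytest.approx(69 / 152)
        assert round(rate_constant(69, 4, 19.0), 1) == 0.5

    def test_zero_events(self):
        assert rate_constant(0, 4, 19.0) == 0.0

    def test_hand_arithmetic(self):
        assert rate_constant(152, 4, 19.0) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rate_constant(1, 4, 0.0)
        with pytest.raises(ValueError):
            rate_constant(1, 0, 1.0)


class TestDiffusivePermeability:
    def test_tetramer_worked_example(self):
        p_d = diffusive_permeability(rate_constant(69, 4, 19.0))
        assert p_d == pytest.approx(1.36e-14, rel=0.01)

    def test_unit_rate(self):
        assert diffusive_permeability(1.0) == pytest.approx(2.99e-14)

    def test_zero(self):
        assert diffusive_permeability(0.0) == 0.0

    def test_linear_in_k0(self):
        assert diffusive_permeability(3.0) == pytest.approx(
            3 * diffusive_permeability(1.0)
        )


class TestWaterVolume:
    def test_liquid_water(self):
        assert water_volume(18.0, AVOGADRO) == pytest.approx(2.99e-23, rel=2e-3)

    def test_identity(self):
        assert water_volume(AVOGADRO, AVOGADRO) == 1.0

    def test_ideal_gas_sanity(self):
        assert water_volume(22.4e3, AVOGADRO) == pytest.approx(3.72e-20, rel=1e-2)


class TestSummaries:
    def test_counts_are_consistent(self, small_sim):
        _, traj, truth, _, cdefs = small_sim
        events = detect_events(traj, cdefs)
        summ = summarize_events(events, ["A"], truth.t_sim_ns)
        assert summ.n_pm == summ.n_plus + summ.n_minus
        assert summ.p_d == pytest.approx(
            PhysicalConstants().v_w * summ.k0 * 1e9
        )

    def test_cumulative_counts_monotone(self, small_sim):
        _, traj, _, _, cdefs = small_sim
        events = detect_events(traj, cdefs)
        cum = cumulative_counts(events, traj.times)
        assert (np.diff(cum["N_pm"]) >= 0).all()
        assert cum["N_pm"].iloc[-1] == len(events)
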