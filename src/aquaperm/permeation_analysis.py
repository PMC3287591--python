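"""Permeation-event counting and the diffusive permeability p_d.

A complete permeation event is a water molecule that enters the constriction
region through one axial boundary and leaves through the opposite one.  The
per-water state machine distinguishes "above", "below" and "inside (entered
from ...)"; waters that back out through their entry boundary, or that leave
the CR sideways (past the lateral cutoff), produce no event.  Waters already
inside at the first analyzed frame have an unknown entry side and can never
complete an event: only full lumen traversals count.

From the bidirectional event count N+- the unidirectional rate constant is

    k0 = N+- / (2 * n_monomers * t_sim)        [per channel, per direction]

and the diffusive permeability is p_d = v_w * k0, with v_w the average
volume of one water molecule (V_w / N_A ~= 2.99e-23 cm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import summarize
from .channel_model import ChannelDefinition, axial_coordinates
from .trajectory_io import Trajectory

__all__ = [
    "PhysicalConstants",
    "PermeationEvent",
    "PermeationSummary",
    "detect_events",
    "rate_constant",
    "diffusive_permeability",
    "water_volume",
    "cumulative_counts",
    "summarize_events",
    "events_to_dataframe",
]

AVOGADRO = 6.02214076e23  # mol^-1
WATER_MOLAR_VOLUME = 18.0  # cm^3 mol^-1 (liquid water, ambient)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the permeability conversions."""

    v_w: float = 2.99e-23  # cm^3, average volume of one water molecule
    N_A: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.v_w <= 0 or self.N_A <= 0:
            raise ValueError("constants must be positive")


@dataclass(frozen=True)
class PermeationEvent:
    """One complete crossing of the CR by one water molecule."""

    water_index: int
    monomer_id: str
    entry_time: float  # ps
    exit_time: float  # ps
    direction: str  # "+z" or "-z"

    def __post_init__(self) -> None:
        if self.exit_time <= self.entry_time:
            raise ValueError("exit_time must be later than entry_time")
        if self.direction not in {"+z", "-z"}:
            raise ValueError("direction must be '+z' or '-z'")


# state-machine categories: axially below / inside / axially above, plus
# "beside the channel" (within the axial interval but past the lateral
# cutoff), split by which half it is in.  A water that vacates the CR
# laterally resets to an outside state without completing an event; only
# exits through the axial boundaries can complete one.
_BELOW, _INSIDE, _ABOVE, _LATERAL_LOW, _LATERAL_HIGH = 0, 1, 2, 3, 4
_SIDE_BELOW = {_BELOW, _LATERAL_LOW}


def _categorize(
    z: np.ndarray, r: np.ndarray, z_bottom: np.ndarray, z_top: np.ndarray, cutoff: float
) -> np.ndarray:
    """Per-frame/per-water category relative to the CR."""
    cat = np.full(z.shape, _BELOW, dtype=np.int8)
    mid = 0.5 * (z_bottom + z_top)
    in_axial = (z >= z_bottom[:, None]) & (z < z_top[:, None])
    lateral_ok = r <= cutoff
    cat[~in_axial & (z >= mid[:, None])] = _ABOVE
    cat[in_axial & lateral_ok] = _INSIDE
    cat[in_axial & ~lateral_ok & (z < mid[:, None])] = _LATERAL_LOW
    cat[in_axial & ~lateral_ok & (z >= mid[:, None])] = _LATERAL_HIGH
    return cat


def detect_events(
    trajectory: Trajectory,
    channel_defs: list[ChannelDefinition],
    water_indices: np.ndarray | None = None,
    max_gap: float | None = None,
) -> list[PermeationEvent]:
    """Detect complete permeation events for every monomer.

    Detection requires that no water crosses the full boundary-to-boundary
    span within one frame stride; with ``max_gap`` set (ps), larger frame
    gaps raise a warning (events may be missed) but not an error.
    """
    if trajectory.n_frames < 2:
        raise ValueError("event detection needs at least two frames")
    times = trajectory.times
    if max_gap is not None and np.any(np.diff(times) > max_gap):
        warnings.warn(
            "frame gap exceeds max_gap; permeation events may be missed",
            stacklevel=2,
        )
    if water_indices is None:
        water_indices = trajectory.water_oxygen_indices()
    water_indices = np.asarray(water_indices, dtype=int)

    events: list[PermeationEvent] = []
    for cdef in channel_defs:
        z, r, zb, zt = axial_coordinates(trajectory, cdef, water_indices)
        cat = _categorize(z, r, zb, zt, cdef.lateral_cutoff)
        for w in range(len(water_indices)):
            cw = cat[:, w]
            change = np.flatnonzero(np.diff(cw)) + 1  # frames where state changes
            state = int(cw[0])
            entered_from: str | None = "unknown" if state == _INSIDE else None
            entry_time = times[0] if state == _INSIDE else None
            for f in change:
                new = int(cw[f])
                if new == _INSIDE:
                    entered_from = "below" if state in _SIDE_BELOW else "above"
                    entry_time = times[f]
                elif state == _INSIDE:
                    if new == _ABOVE and entered_from == "below":
                        events.append(
                            PermeationEvent(
                                water_index=int(water_indices[w]),
                                monomer_id=cdef.monomer_id,
                                entry_time=float(entry_time),
                                exit_time=float(times[f]),
                                direction="+z",
                            )
                        )
                    elif new == _BELOW and entered_from == "above":
                        events.append(
                            PermeationEvent(
                                water_index=int(water_indices[w]),
                                monomer_id=cdef.monomer_id,
                                entry_time=float(entry_time),
                                exit_time=float(times[f]),
                                direction="-z",
                            )
                        )
                    entered_from = None
                    entry_time = None
                state = new
    events.sort(key=lambda e: (e.exit_time, e.monomer_id, e.water_index))
    return events


def rate_constant(n_pm: int, n_monomers: int, t_sim: float) -> float:
    """Unidirectional permeation rate constant k0 = N+- / (2 nm t_sim).

    ``t_sim`` is the analyzed simulation span in ns (after any burn-in);
    the result is in ns^-1 per channel.
    """
    if t_sim <= 0:
        raise ValueError("t_sim must be > 0")
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if n_pm < 0:
        raise ValueError("event count cannot be negative")
    return n_pm / (2.0 * n_monomers * t_sim)


def diffusive_permeability(
    k0: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """p_d = v_w * k0, converted from ns^-1 to cm^3 s^-1."""
    if k0 < 0:
        raise ValueError("k0 must be >= 0")
    return constants.v_w * k0 * 1e9


def water_volume(v_w_molar: float = WATER_MOLAR_VOLUME, n_a: float = AVOGADRO) -> float:
    """Average volume of a single water molecule, V_w / N_A (cm^3)."""
    if v_w_molar <= 0 or n_a <= 0:
        raise ValueError("inputs must be positive")
    return v_w_molar / n_a


def cumulative_counts(
    events: list[PermeationEvent], times: np.ndarray
) -> pd.DataFrame:
    """Cumulative N+, N- and N+- versus time (events dated by exit time)."""
    times = np.asarray(times, dtype=float)
    plus_t = np.sort([e.exit_time for e in events if e.direction == "+z"])
    minus_t = np.sort([e.exit_time for e in events if e.direction == "-z"])
    n_plus = np.searchsorted(plus_t, times, side="right")
    n_minus = np.searchsorted(minus_t, times, side="right")
    return pd.DataFrame(
        {
            "time_ps": times,
            "N_plus": n_plus,
            "N_minus": n_minus,
            "N_pm": n_plus + n_minus,
        }
    )


@dataclass
class PermeationSummary:
    """Event counts, k0 and p_d, per monomer and pooled over the tetramer."""

    per_monomer: dict[str, dict[str, float]]
    n_plus: int
    n_minus: int
    n_pm: int
    k0: float  # ns^-1, pooled
    p_d: float  # cm^3 s^-1, pooled
    t_sim: float  # ns
    p_d_monomer_mean: float = 0.0
    p_d_monomer_sd: float | None = None
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)


def summarize_events(
    events: list[PermeationEvent],
    monomer_ids: list[str],
    t_sim: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> PermeationSummary:
    """Build the per-monomer and pooled k0 / p_d summary.

    The pooled (tetramer) k0 divides the total event count by all monomers;
    per-monomer values use that monomer's events alone (n_monomers = 1).
    """
    per: dict[str, dict[str, float]] = {}
    for m in monomer_ids:
        ev = [e for e in events if e.monomer_id == m]
        np_ = sum(1 for e in ev if e.direction == "+z")
        nm_ = sum(1 for e in ev if e.direction == "-z")
        k0_m = rate_constant(np_ + nm_, 1, t_sim)
        per[m] = {
            "N_plus": np_,
            "N_minus": nm_,
            "N_pm": np_ + nm_,
            "k0": k0_m,
            "p_d": diffusive_permeability(k0_m, constants),
        }
    n_plus = sum(int(v["N_plus"]) for v in per.values())
    n_minus = sum(int(v["N_minus"]) for v in per.values())
    n_pm = n_plus + n_minus
    k0 = rate_constant(n_pm, len(monomer_ids), t_sim)
    mean, sd = summarize([v["p_d"] for v in per.values()])
    return PermeationSummary(
        per_monomer=per,
        n_plus=n_plus,
        n_minus=n_minus,
        n_pm=n_pm,
        k0=k0,
        p_d=diffusive_permeability(k0, constants),
        t_sim=t_sim,
        p_d_monomer_mean=mean,
        p_d_monomer_sd=sd,
        constants=constants,
    )


def events_to_dataframe(events: list[PermeationEvent]) -> pd.DataFrame:
    """Event table (water, monomer, t_entry, t_exit, direction) for TSV export."""
    return pd.DataFrame(
        {
            "water_index": [e.water_index for e in events],
            "monomer_id": [e.monomer_id for e in events],
            "entry_time_ps": [e.entry_time for e in events],
            "exit_time_ps": [e.exit_time for e in events],
            "direction": [e.direction for e in events],
        }
    )
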