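"""Channel geometry: axis, constriction region (CR) and water membership.

Each monomer's channel is described by a unit axis vector (the membrane
normal by default), two boundary atoms whose axial positions delimit the
constriction region, and a lateral cutoff.  The CR length L-bar is the
time-averaged Euclidean distance between the two boundary atoms; a water is
"inside" a monomer when its axial coordinate lies in the half-open interval
[z_bottom, z_top) and its radial distance from the axis is at most the
lateral cutoff.  Axial coordinates are measured relative to the midpoint of
the two boundary atoms, which makes them invariant under rigid translation
of the whole frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import (
    Frame,
    Trajectory,
    select_single_atom,
)
from ._stats import summarize

__all__ = [
    "ChannelDefinition",
    "ChannelFrameState",
    "ChannelLengthResult",
    "channel_length",
    "waters_in_channel",
    "axial_coordinates",
    "inside_series",
]


@dataclass
class ChannelDefinition:
    """Geometry of one monomer's channel.

    ``top_selector`` / ``bottom_selector`` are selection expressions that must
    each resolve to exactly one atom (the CR boundary carbonyl oxygens).
    ``fixed_z_window`` switches from instantaneous boundary-atom z positions
    to a fixed axial interval (used to reproduce published profile axes, e.g.
    a -9..12 A window); ``flip_z`` mirrors the axial coordinate for sign
    conventions that put the extracellular side at negative z.
    """

    monomer_id: str
    top_selector: str
    bottom_selector: str
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    lateral_cutoff: float = 8.0  # A
    fixed_z_window: tuple[float, float] | None = None
    flip_z: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("channel axis must be a nonzero vector")
        self.axis = v / norm
        if self.flip_z:
            self.axis = -self.axis
        if self.lateral_cutoff <= 0:
            raise ValueError("lateral_cutoff must be > 0")

    def boundary_indices(self, trajectory: Trajectory) -> tuple[int, int]:
        """(top_index, bottom_index) of the boundary atoms."""
        return (
            select_single_atom(trajectory, self.top_selector),
            select_single_atom(trajectory, self.bottom_selector),
        )


@dataclass
class ChannelFrameState:
    """Per-frame CR interval and water membership for one monomer."""

    monomer_id: str
    time: float
    z_bottom: float
    z_top: float
    water_indices: np.ndarray

    def __post_init__(self) -> None:
        if not self.z_bottom < self.z_top:
            raise ValueError("z_bottom must be < z_top")


@dataclass
class ChannelLengthResult:
    """Time-averaged CR length per monomer and its tetramer aggregate."""

    per_monomer_mean: dict[str, float]
    per_monomer_sd: dict[str, float]
    mean: float
    sd: float | None


def channel_length(
    trajectory: Trajectory, channel_defs: list[ChannelDefinition]
) -> ChannelLengthResult:
    """Average distance between the two CR boundary atoms, per monomer.

    The aggregate is the arithmetic mean and sample SD of the per-monomer
    means.
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    coords = trajectory.coordinate_array()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for cdef in channel_defs:
        ti, bi = cdef.boundary_indices(trajectory)
        d = np.linalg.norm(coords[:, ti] - coords[:, bi], axis=1)
        means[cdef.monomer_id] = float(d.mean())
        sds[cdef.monomer_id] = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    mean, sd = summarize(list(means.values()))
    return ChannelLengthResult(
        per_monomer_mean=means, per_monomer_sd=sds, mean=mean, sd=sd
    )


def axial_coordinates(
    trajectory: Trajectory,
    channel_def: ChannelDefinition,
    atom_indices: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Axial and radial coordinates of selected atoms in every frame.

    Returns ``(z, r, z_bottom, z_top)`` where ``z``/``r`` have shape
    ``(n_frames, n_atoms_selected)`` and the bounds have shape
    ``(n_frames,)``.  The axial origin is the midpoint of the two boundary
    atoms of each frame.
    """
    coords = trajectory.coordinate_array()
    ti, bi = channel_def.boundary_indices(trajectory)
    n_z = channel_def.axis
    anchor = 0.5 * (coords[:, ti] + coords[:, bi])  # (F, 3)
    rel = coords[:, atom_indices] - anchor[:, None, :]  # (F, W, 3)
    z = rel @ n_z
    perp = rel - z[..., None] * n_z
    r = np.linalg.norm(perp, axis=-1)
    zt = np.einsum("ij,j->i", coords[:, ti] - anchor, n_z)
    zb = np.einsum("ij,j->i", coords[:, bi] - anchor, n_z)
    z_bottom = np.minimum(zb, zt)
    z_top = np.maximum(zb, zt)
    if channel_def.fixed_z_window is not None:
        lo, hi = channel_def.fixed_z_window
        z_bottom = np.full(trajectory.n_frames, float(min(lo, hi)))
        z_top = np.full(trajectory.n_frames, float(max(lo, hi)))
    return z, r, z_bottom, z_top


def inside_series(
    trajectory: Trajectory,
    channel_def: ChannelDefinition,
    water_indices: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean CR membership of each water in each frame.

    Returns ``(inside, z, z_bottom, z_top)``; ``inside`` has shape
    ``(n_frames, n_waters)`` and uses the half-open axial interval
    ``z_bottom <= z < z_top`` plus the lateral cutoff (half-open so that an
    atom exactly on a boundary belongs to one side only).
    """
    z, r, z_bottom, z_top = axial_coordinates(trajectory, channel_def, water_indices)
    inside = (
        (z >= z_bottom[:, None])
        & (z < z_top[:, None])
        & (r <= channel_def.lateral_cutoff)
    )
    return inside, z, z_bottom, z_top


def waters_in_channel(
    trajectory: Trajectory,
    channel_defs: list[ChannelDefinition],
    water_indices: np.ndarray | None = None,
    frame_index: int | None = None,
) -> list[dict[str, ChannelFrameState]] | dict[str, ChannelFrameState]:
    """Assign waters to monomer CRs, frame by frame.

    A water belongs to a monomer when it satisfies that monomer's axial and
    lateral criteria; a water satisfying several monomers is given to the one
    whose axis it is radially closest to, so the per-monomer sets are always
    disjoint.  With ``frame_index`` set, returns the mapping for that single
    frame; otherwise a list over all frames.
    """
    if water_indices is None:
        water_indices = trajectory.water_oxygen_indices()
    water_indices = np.asarray(water_indices, dtype=int)
    n_frames = trajectory.n_frames
    n_w = len(water_indices)
    times = trajectory.times

    per_def = []
    for cdef in channel_defs:
        z, r, zb, zt = axial_coordinates(trajectory, cdef, water_indices)
        inside = (z >= zb[:, None]) & (z < zt[:, None]) & (r <= cdef.lateral_cutoff)
        per_def.append((cdef, inside, r, zb, zt))

    # nearest-axis tie-break: radial distance where inside, +inf elsewhere
    radial_stack = np.full((len(channel_defs), n_frames, n_w), np.inf)
    for k, (_, inside, r, _, _) in enumerate(per_def):
        radial_stack[k][inside] = r[inside]
    winner = np.argmin(radial_stack, axis=0)  # (F, W)
    any_inside = np.isfinite(np.min(radial_stack, axis=0))

    def _frame_states(f: int) -> dict[str, ChannelFrameState]:
        out = {}
        for k, (cdef, _, _, zb, zt) in enumerate(per_def):
            mask = any_inside[f] & (winner[f] == k)
            out[cdef.monomer_id] = ChannelFrameState(
                monomer_id=cdef.monomer_id,
                time=float(times[f]),
                z_bottom=float(zb[f]),
                z_top=float(zt[f]),
                water_indices=water_indices[mask],
            )
        return out

    if frame_index is not None:
        return _frame_states(frame_index)
    return [_frame_states(f) for f in range(n_frames)]


def waters_in_frame(
    frame: Frame,
    trajectory: Trajectory,
    channel_defs: list[ChannelDefinition],
    water_indices: np.ndarray | None = None,
) -> dict[str, ChannelFrameState]:
    """Single-frame convenience wrapper around :func:`waters_in_channel`."""
    sub = Trajectory(
        topology=trajectory.topology,
        frames=[frame],
        frame_interval=trajectory.frame_interval,
    )
    return waters_in_channel(sub, channel_defs, water_indices, frame_index=0)
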