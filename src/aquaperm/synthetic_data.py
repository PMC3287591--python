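"""Synthetic trajectories with known transport ground truth.

The analysis pipeline is validated against data whose statistical structure
is known exactly, because real channel-protein MD trajectories are neither
redistributable nor desk-reproducible.  Three generators are provided:

``simulate_single_file``
    A continuous-time (Gillespie) model of a single-file water channel:
    N lattice sites spanning the constriction region, fed by reservoir
    pools at both ends.  Transport mixes the two mechanisms of the
    continuous-time-random-walk picture of single-file channels:

    * *concerted column shifts* (rate (1-q) k per direction, q the
      interchange probability): the whole file advances one site, the
      leading water leaves into one reservoir and a new water enters from
      the other.  This is single-file motion with perfect exclusion: a
      water can only advance when the entire column does.
    * *interchange (bypass) hops* (rate q k per water per direction, plus
      matching entry propensities at the mouths): a water slips past its
      neighbors independently of the rest of the file, the microscopic
      event behind water-water interchange.

    Both limits are exact.  At q = 0 the tagged-water traversal rate is
    k0 = k/(N+1) (a new entrant must win an (N+1)-step gambler's ruin)
    while the collective coordinate steps by +-1 per shift, so
    D_n = k and p_f/p_d = N + 1, the single-file CTRW relation.  At q = 1
    waters are independent walkers and the ratio falls to (N+1)/N ~ 1.
    In general k0 = k/(N+1) for every q and D_n = (1-q) k + q k / N.

    Events are exact in continuous time and only *sampled* onto the fixed
    frame grid, so the dynamics are independent of the frame interval and
    frame aliasing becomes a test dimension.  The simulator keeps an exact
    log of completed traversals: the ground-truth oracle for event
    detection and the permeability estimators.

``make_cylinder_pore``
    Stacked rings of spheres with an analytically known pore radius
    (ring_radius - vdw), optionally tapered: the geometry oracle for the
    pore-radius profiler.

``make_oriented_waters``
    Waters with prescribed dipole fields (aligned, perpendicular,
    isotropic, bipolar): the oracle for the order-parameter limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channel_model import ChannelDefinition
from .permeation_analysis import PhysicalConstants
from .trajectory_io import AtomRecord, BONDI_RADII, Frame, Trajectory

__all__ = [
    "SfChannelConfig",
    "GroundTruth",
    "SimEvent",
    "simulate_single_file",
    "single_file_channel_defs",
    "make_cylinder_pore",
    "cylinder_channel_def",
    "make_oriented_waters",
    "oriented_waters_channel_def",
]

# rigid three-point water geometry (A, degrees)
_R_OH = 0.9572
_HALF_HOH = math.radians(104.52 / 2.0)


@dataclass
class SfChannelConfig:
    """Parameters of the single-file channel simulator.

    Defaults emulate the conditions of a tetrameric aquaporin simulation:
    a file of ~8 waters spaced by a water-water hydrogen-bond distance,
    sampled every 2 ps.  ``hop_rate`` is the elementary file-advance
    attempt rate per direction (and, scaled by ``interchange_prob``, the
    per-water bypass rate); the default 2.5 ns^-1 reproduces
    aquaporin-scale transport: k0 = k/(N+1) ~ 0.3 ns^-1 and
    p_f = v_w k ~ 7e-14 cm^3 s^-1.
    """

    n_sites: int = 8
    site_spacing: float = 2.8  # A
    hop_rate: float = 2.5  # ns^-1
    interchange_prob: float = 0.0
    reservoir_depth: float = 8.4  # A of stacked reservoir waters per side
    n_monomers: int = 1
    frame_interval: float = 2.0  # ps
    n_frames: int = 5000
    rng_seed: int = 0
    transverse_jitter: float = 0.3  # A, SD of in-plane water scatter
    monomer_spacing: float = 25.0  # A between channel axes

    def __post_init__(self) -> None:
        if not 0.0 <= self.interchange_prob <= 1.0:
            raise ValueError("interchange_prob must be in [0, 1]")
        if self.hop_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_sites < 1 or self.n_frames < 1 or self.n_monomers < 1:
            raise ValueError("counts must be >= 1")
        if self.site_spacing <= 0 or self.frame_interval <= 0:
            raise ValueError("spacings and intervals must be > 0")
        if not isinstance(self.rng_seed, (int, np.integer)):
            raise ValueError("rng_seed must be an integer")

    @property
    def channel_length(self) -> float:
        return self.n_sites * self.site_spacing

    @property
    def t_total_ps(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class SimEvent:
    """One completed channel traversal, logged exactly by the simulator."""

    water_index: int  # topology index of the water oxygen
    monomer_id: str
    entry_time: float  # ps
    exit_time: float  # ps
    direction: str  # "+z" / "-z"


@dataclass
class GroundTruth:
    """Model-expected values for the emitted trajectory.

    All values are closed forms of the configuration: occupancy N (the file
    is always full at zero interchange, and entry/exit propensities balance
    at one water per site otherwise); k0 = k/(N+1) (entry rate k times the
    1/(N+1) gambler's-ruin traversal probability, for every interchange
    probability q); D_n = (1-q) k + q k / N (shifts carry unit collective
    steps, bypass hops 1/N steps); hence p_f/p_d = (N+1)(1-q+q/N): the
    single-file CTRW relation N+1 at q = 0, ~1 at q = 1.  ``n_events``
    counts the exact traversal log of this run.
    """

    expected_occupancy: float
    expected_k0: float  # ns^-1
    expected_p_d: float  # cm^3 s^-1
    expected_D_n: float  # ns^-1
    expected_p_f: float  # cm^3 s^-1
    expected_pf_over_pd: float
    n_events: int
    t_sim_ns: float
    seed: int
    config: SfChannelConfig = field(repr=False, default=None)


def _monomer_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


class _SingleFileChannel:
    """Gillespie dynamics of one channel plus its two reservoir pools.

    State: ``site_of`` maps each in-channel particle to its site (1..N;
    several particles may transiently share a site during bypass episodes),
    and two FIFO reservoir queues.  Moves: concerted column shifts at rate
    (1-q) k per direction, and bypass hops / entries at rate q k per water
    (or mouth) per direction.
    """

    def __init__(self, cfg: SfChannelConfig, rng: np.random.Generator, id_offset: int):
        self.cfg = cfg
        self.rng = rng
        n_pool = max(3, int(math.ceil(cfg.reservoir_depth / cfg.site_spacing)))
        self.n_pool = n_pool
        n_particles = cfg.n_sites + 2 * n_pool
        self.site_of: dict[int, int] = {
            id_offset + i: i + 1 for i in range(cfg.n_sites)
        }
        self.bottom = list(
            range(id_offset + cfg.n_sites, id_offset + cfg.n_sites + n_pool)
        )
        self.top = list(range(id_offset + cfg.n_sites + n_pool, id_offset + n_particles))
        self.n_particles = n_particles
        self.id_offset = id_offset
        self.entry_side: dict[int, str] = {p: "unknown" for p in self.site_of}
        self.entry_time: dict[int, float] = {p: 0.0 for p in self.site_of}
        self.k_shift = cfg.hop_rate * (1.0 - cfg.interchange_prob) / 1e3  # per ps
        self.k_free = cfg.hop_rate * cfg.interchange_prob / 1e3
        self.t = 0.0
        self.events: list[tuple[int, float, float, str]] = []

    def rebalance_pools(self) -> None:
        """Equalize the reservoir queues (called between frames only).

        Net transport drains one reservoir into the other; recirculating
        waters to the far queue emulates bulk mixing around the membrane, so
        the finite pools never reflect the collective walk.  Only the
        longest-rested water of the surplus queue (its FIFO front) is moved,
        and it joins the *back* of the far queue -- so every recirculated
        water was visible on its old side for many frames and stays several
        insertions from the mouth on its new side, keeping the frame-level
        picture consistent with the exact event log.
        """
        while len(self.bottom) - len(self.top) >= 2:
            self.top.append(self.bottom.pop(0))
        while len(self.top) - len(self.bottom) >= 2:
            self.bottom.append(self.top.pop(0))

    # --- elementary moves -------------------------------------------------
    def _exit(self, p: int, side: str) -> None:
        del self.site_of[p]
        entered = self.entry_side.pop(p, None)
        t_in = self.entry_time.pop(p, None)
        if side == "top":
            if entered == "below":
                self.events.append((p, t_in, self.t, "+z"))
            self.top.append(p)
        else:
            if entered == "above":
                self.events.append((p, t_in, self.t, "-z"))
            self.bottom.append(p)

    def _enter(self, side: str) -> None:
        n = self.cfg.n_sites
        if side == "bottom":
            p = self.bottom.pop(0)  # FIFO: most-rested reservoir water enters
            self.site_of[p] = 1
            self.entry_side[p] = "below"
        else:
            p = self.top.pop(0)
            self.site_of[p] = n
            self.entry_side[p] = "above"
        self.entry_time[p] = self.t

    def _shift(self, direction: int) -> None:
        n = self.cfg.n_sites
        leavers = []
        for p in list(self.site_of):
            s = self.site_of[p] + direction
            if s > n:
                leavers.append((p, "top"))
            elif s < 1:
                leavers.append((p, "bottom"))
            else:
                self.site_of[p] = s
        for p, side in sorted(leavers):
            self._exit(p, side)
        self._enter("bottom" if direction > 0 else "top")

    def _apply(self, act) -> None:
        kind = act[0]
        if kind == "shift":
            self._shift(act[1])
        elif kind == "free":
            p, direction = act[1], act[2]
            s = self.site_of[p] + direction
            if s > self.cfg.n_sites:
                self._exit(p, "top")
            elif s < 1:
                self._exit(p, "bottom")
            else:
                self.site_of[p] = s
        elif kind == "free_enter":
            self._enter(act[1])

    def _actions(self):
        acts = []
        if self.k_shift > 0:
            if self.bottom:
                acts.append((self.k_shift, ("shift", +1)))
            if self.top:
                acts.append((self.k_shift, ("shift", -1)))
        if self.k_free > 0:
            for p in self.site_of:
                acts.append((self.k_free, ("free", p, +1)))
                acts.append((self.k_free, ("free", p, -1)))
            if self.bottom:
                acts.append((self.k_free, ("free_enter", "bottom")))
            if self.top:
                acts.append((self.k_free, ("free_enter", "top")))
        return acts

    def advance_to(self, t_target: float) -> None:
        while True:
            acts = self._actions()
            total = sum(a[0] for a in acts)
            if total <= 0:
                self.t = t_target
                return
            dt = self.rng.exponential(1.0 / total)
            if self.t + dt > t_target:
                self.t = t_target
                return
            self.t += dt
            u = self.rng.uniform(0.0, total)
            acc = 0.0
            for rate, action in acts:
                acc += rate
                if u <= acc:
                    self._apply(action)
                    break

    # --- geometry ---------------------------------------------------------
    def particle_z(self) -> np.ndarray:
        """Axial position of every particle of this channel (A)."""
        cfg = self.cfg
        half = cfg.channel_length / 2.0
        z = np.empty(self.n_particles)
        for p, s in self.site_of.items():
            z[p - self.id_offset] = -half + (s - 0.5) * cfg.site_spacing
        # queue front (next to enter) sits closest to the channel mouth
        for slot, p in enumerate(self.bottom):
            z[p - self.id_offset] = -half - (slot + 1) * cfg.site_spacing
        for slot, p in enumerate(self.top):
            z[p - self.id_offset] = half + (slot + 1) * cfg.site_spacing
        return z


def _water_h_offsets(dipole: np.ndarray, perp_hint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """H positions (relative to O) whose bisector is the unit ``dipole``."""
    d = dipole / np.linalg.norm(dipole)
    p = perp_hint - (perp_hint @ d) * d
    n = np.linalg.norm(p)
    if n < 1e-8:
        p = np.array([1.0, 0.0, 0.0]) - d[0] * d
        n = np.linalg.norm(p)
    p /= n
    along = _R_OH * math.cos(_HALF_HOH)
    across = _R_OH * math.sin(_HALF_HOH)
    return along * d + across * p, along * d - across * p


def simulate_single_file(
    config: SfChannelConfig,
) -> tuple[Trajectory, GroundTruth, list[SimEvent]]:
    """Run the single-file hopping simulator and emit a trajectory.

    Returns the trajectory (waters plus two static boundary-marker atoms per
    monomer), the model ground truth, and the exact traversal log.  Channel
    waters carry a bipolar dipole field (dipoles pointing toward the channel
    midplane from both sides); reservoir waters are oriented in-plane.
    The same seed reproduces the trajectory bit for bit.
    """
    cfg = config
    ids = _monomer_ids(cfg.n_monomers)
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_monomers + 1)
    jitter_rng = np.random.default_rng(seeds[-1])

    channels = []
    id_offset = 0
    for m in range(cfg.n_monomers):
        ch = _SingleFileChannel(cfg, np.random.default_rng(seeds[m]), id_offset)
        channels.append(ch)
        id_offset += ch.n_particles
    n_waters = id_offset

    # topology: waters first (O,H,H per residue), then 2 boundary markers/monomer
    topology: list[AtomRecord] = []
    atom_i = 0
    water_oxygen_atom: list[int] = []  # particle id -> topology index of its O
    for m, ch in enumerate(channels):
        for p in range(ch.n_particles):
            resnum = p + 1
            water_oxygen_atom.append(atom_i)
            for name, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
                topology.append(
                    AtomRecord(
                        index=atom_i,
                        name=name,
                        element=el,
                        residue_name="SOL",
                        residue_number=resnum,
                        chain_id=ids[m],
                        vdw_radius=BONDI_RADII[el],
                    )
                )
                atom_i += 1
    boundary_atoms: list[tuple[int, int]] = []
    half = cfg.channel_length / 2.0
    for m in range(cfg.n_monomers):
        bot_i, top_i = atom_i, atom_i + 1
        for name, z in (("OB", -half), ("OT", half)):
            topology.append(
                AtomRecord(
                    index=atom_i,
                    name=name,
                    element="O",
                    residue_name="BND",
                    residue_number=1 if name == "OB" else 2,
                    chain_id=ids[m],
                    vdw_radius=BONDI_RADII["O"],
                )
            )
            atom_i += 1
        boundary_atoms.append((bot_i, top_i))

    n_atoms = atom_i
    x_offsets = np.arange(cfg.n_monomers) * cfg.monomer_spacing
    frames: list[Frame] = []
    xhat = np.array([1.0, 0.0, 0.0])

    for f in range(cfg.n_frames):
        t = f * cfg.frame_interval
        for ch in channels:
            ch.advance_to(t)
            ch.rebalance_pools()
        coords = np.zeros((n_atoms, 3))
        for m, ch in enumerate(channels):
            z = ch.particle_z()
            jit = jitter_rng.normal(0.0, cfg.transverse_jitter, size=(ch.n_particles, 2))
            in_channel = np.zeros(ch.n_particles, dtype=bool)
            for p in ch.site_of:
                in_channel[p - ch.id_offset] = True
            for p_local in range(ch.n_particles):
                o = np.array(
                    [x_offsets[m] + jit[p_local, 0], jit[p_local, 1], z[p_local]]
                )
                if in_channel[p_local]:
                    # bipolar field: dipole points toward the channel midplane
                    sign = 1.0 if z[p_local] <= 0 else -1.0
                    d = np.array([0.0, 0.0, sign])
                else:
                    d = np.array([1.0, 0.0, 0.0])  # reservoir: in-plane
                h1, h2 = _water_h_offsets(d, xhat if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0]))
                oi = water_oxygen_atom[ch.id_offset + p_local]
                coords[oi] = o
                coords[oi + 1] = o + h1
                coords[oi + 2] = o + h2
            bot_i, top_i = boundary_atoms[m]
            coords[bot_i] = [x_offsets[m], 0.0, -half]
            coords[top_i] = [x_offsets[m], 0.0, half]
        frames.append(Frame(time=t, coords=coords))

    trajectory = Trajectory(
        topology=topology, frames=frames, frame_interval=cfg.frame_interval
    )

    events: list[SimEvent] = []
    for m, ch in enumerate(channels):
        for p, t_in, t_out, direction in ch.events:
            events.append(
                SimEvent(
                    water_index=water_oxygen_atom[p],
                    monomer_id=ids[m],
                    entry_time=t_in,
                    exit_time=t_out,
                    direction=direction,
                )
            )
    events.sort(key=lambda e: e.exit_time)

    t_sim_ns = cfg.t_total_ps / 1e3
    n_events = len(events)
    consts = PhysicalConstants()
    n, q, k = cfg.n_sites, cfg.interchange_prob, cfg.hop_rate
    k0 = k / (n + 1.0)  # exact for every q: entry rate k, ruin probability 1/(N+1)
    d_n = (1.0 - q) * k + q * k / n
    ratio = d_n / k0 if k0 > 0 else float("nan")
    truth = GroundTruth(
        expected_occupancy=float(n),
        expected_k0=k0,
        expected_p_d=consts.v_w * k0 * 1e9,
        expected_D_n=d_n,
        expected_p_f=consts.v_w * d_n * 1e9,
        expected_pf_over_pd=ratio,
        n_events=n_events,
        t_sim_ns=t_sim_ns,
        seed=cfg.rng_seed,
        config=cfg,
    )
    return trajectory, truth, events


def single_file_channel_defs(config: SfChannelConfig) -> list[ChannelDefinition]:
    """Channel definitions matching :func:`simulate_single_file` output."""
    return [
        ChannelDefinition(
            monomer_id=m,
            top_selector=f"name=OT and chain={m}",
            bottom_selector=f"name=OB and chain={m}",
            lateral_cutoff=8.0,
        )
        for m in _monomer_ids(config.n_monomers)
    ]


# ---------------------------------------------------------------------------
# Geometric fixtures
# ---------------------------------------------------------------------------


def make_cylinder_pore(
    ring_radius: float = 5.0,
    vdw: float = 1.5,
    length: float = 20.0,
    n_rings: int = 41,
    atoms_per_ring: int = 12,
    taper: float = 0.0,
    frame_ring_radii: list[float] | None = None,
) -> Trajectory:
    """Stacked-ring pore with analytic radius ``ring_radius - vdw``.

    With ``taper`` != 0 the ring radius varies linearly with z
    (``ring_radius + taper * z``).  ``frame_ring_radii`` emits one frame per
    listed base radius (for multi-frame averaging tests).  Two boundary
    markers (resname BND) at z = +/- length/2 define the CR.
    """
    if ring_radius <= vdw:
        raise ValueError("ring_radius must exceed the vdW radius")
    zs = (
        np.linspace(-length / 2.0, length / 2.0, n_rings)
        if n_rings > 1
        else np.array([0.0])
    )
    angles = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
    base_radii = [ring_radius] if frame_ring_radii is None else list(frame_ring_radii)

    topology: list[AtomRecord] = []
    atom_i = 0
    for ri, z in enumerate(zs):
        for _ in angles:
            topology.append(
                AtomRecord(
                    index=atom_i,
                    name="C",
                    element="C",
                    residue_name="RNG",
                    residue_number=ri + 1,
                    chain_id="A",
                    vdw_radius=vdw,
                )
            )
            atom_i += 1
    for name, rn in (("OB", 9998), ("OT", 9999)):
        topology.append(
            AtomRecord(
                index=atom_i,
                name=name,
                element="O",
                residue_name="BND",
                residue_number=rn,
                chain_id="A",
                vdw_radius=1.52,
            )
        )
        atom_i += 1

    frames = []
    for f, r0 in enumerate(base_radii):
        coords = np.zeros((atom_i, 3))
        k = 0
        for z in zs:
            rr = r0 + taper * z
            for a in angles:
                coords[k] = [rr * np.cos(a), rr * np.sin(a), z]
                k += 1
        # markers sit on the pore axis; they are excluded from radius searches
        coords[k] = [0.0, 0.0, -length / 2.0]
        coords[k + 1] = [0.0, 0.0, length / 2.0]
        frames.append(Frame(time=float(f), coords=coords))
    return Trajectory(topology=topology, frames=frames, frame_interval=1.0)


def cylinder_channel_def(lateral_cutoff: float = 8.0) -> ChannelDefinition:
    return ChannelDefinition(
        monomer_id="A",
        top_selector="name=OT and resname=BND",
        bottom_selector="name=OB and resname=BND",
        lateral_cutoff=lateral_cutoff,
    )


def make_oriented_waters(
    n: int,
    orientation: str,
    z_range: tuple[float, float] = (-10.0, 10.0),
    midplane: float = 0.0,
    seed: int = 0,
    lateral_scatter: float = 1.0,
) -> Trajectory:
    """One frame of ``n`` waters with a prescribed dipole field.

    ``orientation`` is one of ``aligned+z``, ``aligned-z``, ``perpendicular``,
    ``isotropic`` or ``bipolar`` (dipoles pointing toward ``midplane`` from
    both sides).  O positions are spread uniformly over ``z_range`` with a
    small lateral scatter; two boundary markers delimit the CR.
    """
    rng = np.random.default_rng(seed)
    lo, hi = min(z_range), max(z_range)
    z = lo + (np.arange(n) + 0.5) * (hi - lo) / n
    xy = rng.normal(0.0, lateral_scatter, size=(n, 2))

    if orientation == "aligned+z":
        dips = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif orientation == "aligned-z":
        dips = np.tile([0.0, 0.0, -1.0], (n, 1))
    elif orientation == "perpendicular":
        phi = rng.uniform(0, 2 * np.pi, n)
        dips = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    elif orientation == "isotropic":
        v = rng.normal(size=(n, 3))
        dips = v / np.linalg.norm(v, axis=1, keepdims=True)
    elif orientation == "bipolar":
        # smooth dipole inversion: dipoles point toward the midplane from
        # both sides, rotating through perpendicular at the midplane itself
        # (P1 changes sign there and P2 dips to its minimum)
        cos_t = np.clip(-np.tanh((z - midplane) / 3.0), -1.0, 1.0)
        sin_t = np.sqrt(1.0 - cos_t**2)
        phi = rng.uniform(0, 2 * np.pi, n)
        dips = np.stack(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1
        )
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    topology: list[AtomRecord] = []
    coords = np.zeros((3 * n + 2, 3))
    atom_i = 0
    for i in range(n):
        o = np.array([xy[i, 0], xy[i, 1], z[i]])
        h1, h2 = _water_h_offsets(
            dips[i],
            np.array([1.0, 0.0, 0.0])
            if abs(dips[i, 0]) < 0.9
            else np.array([0.0, 1.0, 0.0]),
        )
        for name, el, pos in (
            ("OW", "O", o),
            ("HW1", "H", o + h1),
            ("HW2", "H", o + h2),
        ):
            topology.append(
                AtomRecord(
                    index=atom_i,
                    name=name,
                    element=el,
                    residue_name="SOL",
                    residue_number=i + 1,
                    chain_id="A",
                    vdw_radius=BONDI_RADII[el],
                )
            )
            coords[atom_i] = pos
            atom_i += 1
    for name, rn, zb in (("OB", 1, lo), ("OT", 2, hi)):
        topology.append(
            AtomRecord(
                index=atom_i,
                name=name,
                element="O",
                residue_name="BND",
                residue_number=rn,
                chain_id="Z",
                vdw_radius=1.52,
            )
        )
        coords[atom_i] = [0.0, 0.0, zb]
        atom_i += 1
    return Trajectory(
        topology=topology,
        frames=[Frame(time=0.0, coords=coords)],
        frame_interval=1.0,
    )


def oriented_waters_channel_def(lateral_cutoff: float = 50.0) -> ChannelDefinition:
    """Channel definition spanning the oriented-water fixture.

    The generous lateral cutoff keeps every generated water inside.
    """
    return ChannelDefinition(
        monomer_id="A",
        top_selector="name=OT and chain=Z",
        bottom_selector="name=OB and chain=Z",
        lateral_cutoff=lateral_cutoff,
    )
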