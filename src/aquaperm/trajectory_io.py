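"""Topology and trajectory input/output.

Everything downstream operates on a single in-memory representation: a
:class:`Trajectory` holding an atom table (:class:`AtomRecord`) and an ordered
list of coordinate :class:`Frame` objects.  Coordinates are in Angstrom and
times in picoseconds throughout the package; permeabilities are converted to
cm^3 s^-1 only at the reporting stage.

PDB (multi-MODEL), multi-frame XYZ and optionally CHARMM/NAMD DCD files are
read through MDAnalysis; writing uses plain fixed-width formatting so that
round trips are exact to format precision (1e-3 A for PDB).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "ParseError",
    "StructureError",
    "SelectionError",
    "BONDI_RADII",
    "read_pdb",
    "write_pdb",
    "read_xyz_multiframe",
    "write_xyz",
    "read_dcd",
    "select_atoms",
    "select_single_atom",
]


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class StructureError(ValueError):
    """File contents are inconsistent with the supplied topology."""


class SelectionError(ValueError):
    """An atom-selection expression is malformed or unsatisfiable."""


#: Bondi van der Waals radii (A).  HOLE ships a slightly different table; an
#: alternative set lives in :mod:`aquaperm.pore_radius`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.50

#: Residue names treated as water when auto-detecting solvent.
WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One row of the topology table.

    ``index`` is 0-based and contiguous; ``residue_number`` keeps the 1-based
    PDB convention.  ``chain_id`` doubles as the monomer label for tetrameric
    channels (the chain-to-monomer mapping is user configuration).
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass
class Frame:
    """Coordinates of every atom at one instant (A, ps)."""

    time: float
    coords: np.ndarray  # (n_atoms, 3) float64, A
    box: np.ndarray | None = None  # optional orthorhombic cell lengths (3,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")


@dataclass
class Trajectory:
    """An ordered sequence of frames bound to a fixed topology."""

    topology: list[AtomRecord]
    frames: list[Frame]
    frame_interval: float = 1.0  # ps

    _coord_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        n = len(self.topology)
        for i, a in enumerate(self.topology):
            if a.index != i:
                raise ValueError("topology indices must be contiguous from 0")
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise StructureError(
                    f"frame has {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as a ``(n_frames, n_atoms, 3)`` array."""
        if self._coord_cache is None or len(self._coord_cache) != self.n_frames:
            self._coord_cache = np.stack([f.coords for f in self.frames])
        return self._coord_cache

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygens, by residue name and element."""
        idx = [
            a.index
            for a in self.topology
            if a.residue_name.upper() in WATER_RESNAMES and a.element.upper() == "O"
        ]
        return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# Readers (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _element_of(name: str, element: str | None) -> str:
    if element:
        return element.strip().upper()
    # PDB files without an element column: strip digits from the atom name and
    # take the leading alphabetic part ("OW" -> O, "HW1" -> H, "CA" -> C).
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in BONDI_RADII and two not in {"CA", "CO", "CS", "NI"}:
        # avoid mis-reading calcium-like names in protein context
        return two
    return stripped[0].upper()


def _radius_for(element: str, radii: dict[str, float] | None, default: float) -> float:
    table = BONDI_RADII if radii is None else radii
    key = element.upper()
    if key in table:
        return table[key]
    warnings.warn(
        f"unknown element {element!r}: using default vdW radius {default} A",
        stacklevel=3,
    )
    return default


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in {"ATOM", "HETATM"}:
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparsable coordinates in {rec} record"
                ) from exc


def _universe(path: str, *args, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(path, *args, **kwargs)


def _topology_from_universe(u, radii, default_radius) -> list[AtomRecord]:
    atoms = u.atoms
    names = atoms.names
    try:
        elements = atoms.elements
    except Exception:
        elements = [None] * len(atoms)
    try:
        chains = atoms.chainIDs
    except Exception:
        try:
            chains = atoms.segids
        except Exception:
            chains = [""] * len(atoms)
    try:
        resnames = atoms.resnames
        resnums = atoms.resids
    except Exception:
        resnames = ["UNK"] * len(atoms)
        resnums = [1] * len(atoms)
    records = []
    for i in range(len(atoms)):
        el = _element_of(str(names[i]), elements[i] if elements[i] else None)
        records.append(
            AtomRecord(
                index=i,
                name=str(names[i]),
                element=el,
                residue_name=str(resnames[i]),
                residue_number=int(resnums[i]),
                chain_id=str(chains[i]).strip() or "A",
                vdw_radius=_radius_for(el, radii, default_radius),
            )
        )
    return records


def read_pdb(
    path: str,
    frame_interval: float = 1.0,
    radii: dict[str, float] | None = None,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file.

    Each MODEL becomes one frame; a file without MODEL records yields a single
    frame.  Frame times are assigned as ``frame_index * frame_interval`` since
    PDB carries no time information.  van der Waals radii are assigned from
    the Bondi table (or ``radii``) by element; unknown elements get
    ``default_radius`` with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    u = _universe(path)
    topology = _topology_from_universe(u, radii, default_radius)
    frames = [
        Frame(time=i * frame_interval, coords=ts.positions.astype(float).copy())
        for i, ts in enumerate(u.trajectory)
    ]
    if not frames:
        raise ParseError(f"{path}: no coordinate records found")
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def read_xyz_multiframe(
    path: str,
    topology: list[AtomRecord] | None = None,
    frame_interval: float = 1.0,
    radii: dict[str, float] | None = None,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> Trajectory:
    """Read a multi-frame XYZ file, optionally binding it to ``topology``.

    Without a topology the element column becomes a minimal one-residue
    topology.  With one, the per-frame atom count must match it.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        u = _universe(path, format="XYZ", topology_format="XYZ")
    except Exception as exc:  # noqa: BLE001 - normalize backend errors
        raise ParseError(f"{path}: not a readable XYZ file ({exc})") from exc
    if topology is not None:
        if len(u.atoms) != len(topology):
            raise StructureError(
                f"{path}: XYZ frames have {len(u.atoms)} atoms, "
                f"topology has {len(topology)}"
            )
    else:
        names = u.atoms.names
        topology = [
            AtomRecord(
                index=i,
                name=str(names[i]),
                element=_element_of(str(names[i]), None),
                residue_name="UNK",
                residue_number=1,
                chain_id="A",
                vdw_radius=_radius_for(
                    _element_of(str(names[i]), None), radii, default_radius
                ),
            )
            for i in range(len(u.atoms))
        ]
    frames = [
        Frame(time=i * frame_interval, coords=ts.positions.astype(float).copy())
        for i, ts in enumerate(u.trajectory)
    ]
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def read_dcd(
    dcd_path: str,
    topology_pdb: str,
    frame_interval: float | None = None,
    radii: dict[str, float] | None = None,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> Trajectory:
    """Read a CHARMM/NAMD DCD trajectory with a PDB topology (optional path)."""
    u = _universe(topology_pdb, dcd_path)
    topology = _topology_from_universe(u, radii, default_radius)
    dt = frame_interval if frame_interval is not None else float(u.trajectory.dt) or 1.0
    frames = [
        Frame(time=i * dt, coords=ts.positions.astype(float).copy())
        for i, ts in enumerate(u.trajectory)
    ]
    return Trajectory(topology=topology, frames=frames, frame_interval=dt)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_pdb(trajectory: Trajectory, path: str) -> None:
    """Write a Trajectory as a PDB file, one MODEL per frame if multi-frame."""
    multi = trajectory.n_frames > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(trajectory.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for a, xyz in zip(trajectory.topology, frame.coords):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {(a.index % 99999) + 1:5d} {name:<4.4s} "
                    f"{a.residue_name:<3.3s} {a.chain_id[:1]:1s}"
                    f"{a.residue_number % 10000:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(trajectory: Trajectory, path: str, label: str = "name") -> None:
    """Write a multi-frame XYZ file (count line, comment, ``sym x y z``).

    ``label`` selects the symbol column: atom ``name`` (default, keeps water
    O/H distinguishable on re-read) or ``element``.
    """
    n = trajectory.n_atoms
    syms = [
        (a.name if label == "name" else a.element) or "X" for a in trajectory.topology
    ]
    with open(path, "w") as fh:
        for i, frame in enumerate(trajectory.frames):
            fh.write(f"{n}\n")
            fh.write(f"frame {i} time_ps {frame.time:.6f}\n")
            for sym, xyz in zip(syms, frame.coords):
                fh.write(f"{sym:<5s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_SELECTION_KEYS = {"name", "element", "resname", "resnum", "chain"}


def _match_clause(atom: AtomRecord, key: str, values: list[str]) -> bool:
    if key == "name":
        return atom.name in values
    if key == "element":
        return atom.element.upper() in {v.upper() for v in values}
    if key == "resname":
        return atom.residue_name in values
    if key == "chain":
        return atom.chain_id in values
    if key == "resnum":
        for v in values:
            lo, dash, hi = v.partition("-")
            if dash and lo.isdigit() and hi.isdigit():  # "60-70" range
                if int(lo) <= atom.residue_number <= int(hi):
                    return True
            else:
                try:
                    num = int(v)
                except ValueError as exc:
                    raise SelectionError(f"bad resnum value {v!r}") from exc
                if atom.residue_number == num:
                    return True
        return False
    raise SelectionError(f"unknown selection key {key!r}")


def select_atoms(trajectory: Trajectory, query: str) -> np.ndarray:
    """Evaluate a selection expression against the topology.

    Grammar: clauses joined by ``and``; each clause is ``key=value`` or
    ``key=v1,v2``; keys are ``name``, ``element``, ``resname``, ``resnum``
    (integers or ``lo-hi`` ranges) and ``chain``.  Example:
    ``"name=O and resnum=195 and chain=A"``.  Selection depends only on the
    topology, never on coordinates; the result preserves atom order.
    """
    clauses = []
    for raw in query.split(" and "):
        raw = raw.strip()
        if not raw:
            raise SelectionError(f"empty clause in query {query!r}")
        if "=" not in raw:
            raise SelectionError(f"clause {raw!r} is not of the form key=value")
        key, _, val = raw.partition("=")
        key = key.strip().lower()
        if key not in _SELECTION_KEYS:
            raise SelectionError(
                f"unknown selection key {key!r}; expected one of {sorted(_SELECTION_KEYS)}"
            )
        values = [v.strip() for v in val.split(",") if v.strip()]
        if not values:
            raise SelectionError(f"clause {raw!r} has no value")
        clauses.append((key, values))
    out = [
        a.index
        for a in trajectory.topology
        if all(_match_clause(a, k, v) for k, v in clauses)
    ]
    return np.array(out, dtype=int)


def select_single_atom(trajectory: Trajectory, query: str) -> int:
    """Like :func:`select_atoms` but requires exactly one match."""
    idx = select_atoms(trajectory, query)
    if len(idx) != 1:
        raise SelectionError(
            f"query {query!r} matched {len(idx)} atoms; exactly one required"
        )
    return int(idx[0])
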