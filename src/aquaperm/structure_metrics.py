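"""Structural stability metrics: C-alpha RMSD, RMSF and average structures.

RMSD is computed per frame against a reference conformation after optimal
rigid-body (Kabsch) superposition by default; RMSF is the per-atom RMS
deviation from the time-mean position, after superposing every frame onto
the mean structure (the mean is recomputed once after superposition).
Superposition is the standard choice: without it, per-monomer deviations are
confounded by drift of the whole assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory, select_atoms

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "average_structure",
]


@dataclass
class RmsdSeries:
    times: np.ndarray  # ps
    rmsd: np.ndarray  # A
    reference: str
    superposed: bool


@dataclass
class RmsfProfile:
    residue_numbers: np.ndarray
    atom_indices: np.ndarray
    rmsf: np.ndarray  # A


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense, with a proper rotation (det = +1).  Requires at
    least three non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(P - pc), 1.0)
    if S[1] / scale**2 < 1e-12:
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _resolve_selection(
    trajectory: Trajectory, selection: str | np.ndarray | None
) -> np.ndarray:
    if selection is None:
        return np.arange(trajectory.n_atoms)
    if isinstance(selection, str):
        idx = select_atoms(trajectory, selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise ValueError("selection matched no atoms")
    return idx


def rmsd_series(
    trajectory: Trajectory,
    selection: str | np.ndarray | None = None,
    reference: int | np.ndarray = 0,
    superpose: bool = True,
) -> RmsdSeries:
    """Per-frame RMSD of the selected atoms versus a reference conformation.

    ``reference`` is a frame index or an explicit coordinate array of the
    selected atoms.
    """
    idx = _resolve_selection(trajectory, selection)
    coords = trajectory.coordinate_array()[:, idx]
    if isinstance(reference, (int, np.integer)):
        ref = coords[int(reference)]
        ref_desc = f"frame {int(reference)}"
    else:
        ref = np.asarray(reference, dtype=float)
        ref_desc = "external coordinates"
        if ref.shape != coords.shape[1:]:
            raise ValueError("reference shape does not match the selection")
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        if superpose:
            _, _, out[f] = kabsch_superpose(coords[f], ref)
        else:
            out[f] = np.sqrt(np.mean(np.sum((coords[f] - ref) ** 2, axis=1)))
    return RmsdSeries(
        times=trajectory.times, rmsd=out, reference=ref_desc, superposed=superpose
    )


def rmsf_profile(
    trajectory: Trajectory,
    selection: str | np.ndarray | None = None,
    superpose: bool = True,
) -> RmsfProfile:
    """Per-atom RMS fluctuation around the time-mean position.

    With superposition on, every frame is first fitted onto the mean
    structure and the mean is then recomputed once from the fitted frames.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = _resolve_selection(trajectory, selection)
    coords = trajectory.coordinate_array()[:, idx].copy()
    if superpose:
        mean = coords.mean(axis=0)
        for f in range(len(coords)):
            R, t, _ = kabsch_superpose(coords[f], mean)
            coords[f] = coords[f] @ R.T + t
        mean = coords.mean(axis=0)
    else:
        mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    resnums = np.array([trajectory.topology[i].residue_number for i in idx])
    return RmsfProfile(residue_numbers=resnums, atom_indices=idx, rmsf=rmsf)


def average_structure(
    trajectory: Trajectory,
    selection: str | np.ndarray | None = None,
    window: tuple[int, int] | None = None,
    stride: int = 1,
    superpose: bool = False,
) -> np.ndarray:
    """Arithmetic per-atom mean of the coordinates over a frame window.

    ``window`` is a half-open frame-index interval ``(start, stop)``
    defaulting to the whole trajectory; ``stride`` subsamples it.  With
    ``superpose`` on, frames are first fitted onto the window's first frame.
    """
    idx = _resolve_selection(trajectory, selection)
    start, stop = window if window is not None else (0, trajectory.n_frames)
    if not (0 <= start < stop <= trajectory.n_frames):
        raise ValueError("window outside the trajectory")
    frames = range(start, stop, max(1, int(stride)))
    if len(frames) == 0:
        raise ValueError("empty frame window")
    coords = trajectory.coordinate_array()[list(frames)][:, idx]
    if superpose:
        ref = coords[0]
        fitted = np.empty_like(coords)
        for f in range(len(coords)):
            R, t, _ = kabsch_superpose(coords[f], ref)
            fitted[f] = coords[f] @ R.T + t
        coords = fitted
    return coords.mean(axis=0)
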