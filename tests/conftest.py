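"""Shared fixtures: scripted toy channels and small simulator runs."""

from __future__ import annotations

import numpy as np
import pytest

from aquaperm.channel_model import ChannelDefinition
from aquaperm.synthetic_data import (
    SfChannelConfig,
    simulate_single_file,
    single_file_channel_defs,
)
from aquaperm.trajectory_io import AtomRecord, Frame, Trajectory


def make_scripted_channel(
    water_z: np.ndarray,
    z_bottom: float = -10.0,
    z_top: float = 10.0,
    water_xy: np.ndarray | None = None,
    frame_interval: float = 1.0,
) -> tuple[Trajectory, ChannelDefinition]:
    """Build a toy trajectory from scripted water z-paths.

    ``water_z`` has shape (n_frames, n_waters); two static boundary atoms at
    ``z_bottom``/``z_top`` define the CR.  Waters sit on the axis unless
    ``water_xy`` (same leading shape, trailing 2) is given.
    """
    water_z = np.atleast_2d(np.asarray(water_z, dtype=float))
    n_frames, n_w = water_z.shape
    topology = []
    for i in range(n_w):
        topology.append(
            AtomRecord(
                index=i,
                name="OW",
                element="O",
                residue_name="SOL",
                residue_number=i + 1,
                chain_id="A",
                vdw_radius=1.52,
            )
        )
    for j, (name, rn) in enumerate([("OB", 9001), ("OT", 9002)]):
        topology.append(
            AtomRecord(
                index=n_w + j,
                name=name,
                element="O",
                residue_name="BND",
                residue_number=rn,
                chain_id="A",
                vdw_radius=1.52,
            )
        )
    frames = []
    for f in range(n_frames):
        coords = np.zeros((n_w + 2, 3))
        coords[:n_w, 2] = water_z[f]
        if water_xy is not None:
            coords[:n_w, :2] = water_xy[f]
        coords[n_w] = [0.0, 0.0, z_bottom]
        coords[n_w + 1] = [0.0, 0.0, z_top]
        frames.append(Frame(time=f * frame_interval, coords=coords))
    cdef = ChannelDefinition(
        monomer_id="A",
        top_selector="name=OT",
        bottom_selector="name=OB",
        lateral_cutoff=8.0,
    )
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval), cdef


@pytest.fixture(scope="session")
def small_sim():
    """A short default-parameter single-file run with its exact event log."""
    cfg = SfChannelConfig(n_sites=5, n_frames=5001, rng_seed=7)
    traj, truth, events = simulate_single_file(cfg)
    return cfg, traj, truth, events, single_file_channel_defs(cfg)
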