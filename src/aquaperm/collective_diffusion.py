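"""Collective-diffusion estimate of the osmotic permeability p_f.

The collective coordinate n(t) accumulates, frame by frame, the net axial
displacement of all waters inside the constriction region, in units of the
average channel length L-bar:

    dn = sum_i dz_i / L_bar ,      n(0) = 0 .

At equilibrium n(t) is an unbiased one-dimensional random walk; its
mean-square displacement over many time origins gives the collective
diffusion constant through <n^2(t)> = 2 D_n t, and the single-channel
osmotic permeability is p_f = v_w * D_n.  The p_f/p_d ratio measures the
"single-fileness" of transport: for a perfect single file of N waters the
continuous-time-random-walk model predicts p_f/p_d = N + 1, while
water-water interchange drives the ratio toward 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import summarize
from .channel_model import ChannelDefinition, axial_coordinates
from .permeation_analysis import PhysicalConstants
from .trajectory_io import Trajectory

__all__ = [
    "CollectiveCoordinateSeries",
    "MsdResult",
    "DnFit",
    "collective_coordinate",
    "msd_multi_origin",
    "fit_Dn",
    "osmotic_permeability",
    "pf_pd_ratio",
    "single_channel_from_membrane_permeability",
]


@dataclass
class CollectiveCoordinateSeries:
    """n(t) for one monomer (dimensionless; times in ps)."""

    monomer_id: str
    times: np.ndarray
    n_values: np.ndarray
    channel_length_used: float  # A

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_values = np.asarray(self.n_values, dtype=float)
        if self.n_values[0] != 0.0:
            raise ValueError("n(0) must be 0")
        if not np.all(np.isfinite(self.n_values)):
            raise ValueError("n(t) must be finite")


@dataclass
class MsdResult:
    """Multi-origin mean-square displacement of n."""

    lags: np.ndarray  # ps
    msd: np.ndarray  # dimensionless
    n_origins: int
    window_length: float  # ps


@dataclass
class DnFit:
    """Fitted collective diffusion constant with diagnostics."""

    D_n: float  # ns^-1
    slope: float  # per ps (of the msd-vs-lag line)
    intercept: float
    fit_range: tuple[float, float]
    n_points: int


def collective_coordinate(
    trajectory: Trajectory,
    channel_def: ChannelDefinition,
    channel_length: float,
    water_indices: np.ndarray | None = None,
    mode: str = "either_clipped",
) -> CollectiveCoordinateSeries:
    """Accumulate the collective coordinate n(t) for one monomer.

    ``mode`` selects which waters contribute their axial displacement for a
    frame pair:

    - ``"either_clipped"`` (default): waters inside at either endpoint
      contribute, with z clipped to the CR interval at both endpoints.
      Entering/leaving waters thus contribute exactly the part of their
      displacement that lies inside the CR; a concerted advance of a file
      of N waters yields dn = 1 exactly.
    - ``"both_inside"``: only waters inside the CR in both frames.  Simpler,
      but the dropped boundary half-steps bias D_n low by ~(1-1/N)^2 for
      single-file hopping.
    """
    if channel_length <= 0:
        raise ValueError("channel_length must be > 0")
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames")
    if water_indices is None:
        water_indices = trajectory.water_oxygen_indices()
    water_indices = np.asarray(water_indices, dtype=int)

    z, r, zb, zt = axial_coordinates(trajectory, channel_def, water_indices)
    inside = (
        (z >= zb[:, None]) & (z < zt[:, None]) & (r <= channel_def.lateral_cutoff)
    )
    if mode == "both_inside":
        contrib = inside[:-1] & inside[1:]
        dz = (z[1:] - z[:-1]) * contrib
    elif mode == "either_clipped":
        zc = np.clip(z, zb[:, None], zt[:, None])
        contrib = inside[:-1] | inside[1:]
        dz = (zc[1:] - zc[:-1]) * contrib
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dn = dz.sum(axis=1) / channel_length
    n = np.concatenate([[0.0], np.cumsum(dn)])
    return CollectiveCoordinateSeries(
        monomer_id=channel_def.monomer_id,
        times=trajectory.times,
        n_values=n,
        channel_length_used=channel_length,
    )


def msd_multi_origin(
    series: CollectiveCoordinateSeries,
    window_length: float,
    origin_stride: float | None = None,
) -> MsdResult:
    """<n^2(tau)> averaged over multiple time origins.

    Each origin t' restarts the walk (n(t') := 0) and contributes
    (n(t'+tau) - n(t'))^2 for tau in [0, window_length].  The default stride
    equals the window length, i.e. non-overlapping windows (a 20 ns series
    with 100 ps windows gives exactly 200 origins); a smaller stride yields
    overlapping windows.
    """
    t = series.times
    dt = float(t[1] - t[0])
    span = float(t[-1] - t[0])
    if window_length > span:
        raise ValueError("window_length exceeds the series span")
    if origin_stride is None:
        origin_stride = window_length
    if origin_stride <= 0:
        raise ValueError("origin_stride must be > 0")
    w = int(round(window_length / dt))
    s = max(1, int(round(origin_stride / dt)))
    origins = np.arange(0, len(t) - w, s)
    if len(origins) < 2:
        raise ValueError("fewer than 2 time origins; shorten the window or stride")
    seg = series.n_values[origins[:, None] + np.arange(w + 1)[None, :]]
    disp = seg - seg[:, :1]
    msd = np.mean(disp**2, axis=0)
    return MsdResult(
        lags=np.arange(w + 1) * dt,
        msd=msd,
        n_origins=len(origins),
        window_length=w * dt,
    )


def fit_Dn(msd: MsdResult, fit_range: tuple[float, float] = (10.0, 100.0)) -> DnFit:
    """Least-squares slope of <n^2> versus lag; D_n = slope / 2 (ns^-1).

    The default fit range skips the earliest lags, where successive collective
    displacements are still correlated (ballistic/onset regime).  A negative
    fitted slope is clamped to zero with a warning.
    """
    lo, hi = fit_range
    mask = (msd.lags >= lo) & (msd.lags <= hi)
    if mask.sum() < 2:
        raise ValueError("fit range contains fewer than 2 MSD points")
    slope, intercept = np.polyfit(msd.lags[mask], msd.msd[mask], 1)
    d_n = slope / 2.0 * 1e3  # per ps -> per ns
    if d_n < 0:
        warnings.warn("negative fitted MSD slope; clamping D_n to 0", stacklevel=2)
        d_n = 0.0
    return DnFit(
        D_n=float(d_n),
        slope=float(slope),
        intercept=float(intercept),
        fit_range=(float(lo), float(hi)),
        n_points=int(mask.sum()),
    )


def osmotic_permeability(
    d_n: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """p_f = v_w * D_n, converted from ns^-1 to cm^3 s^-1."""
    if d_n < 0:
        raise ValueError("D_n must be >= 0")
    return constants.v_w * d_n * 1e9


def pf_pd_ratio(p_f: float, p_d: float) -> float:
    """Single-fileness ratio p_f / p_d; NaN (missing) when p_d is zero."""
    if p_d == 0:
        warnings.warn("p_d is zero; p_f/p_d is undefined", stacklevel=2)
        return float("nan")
    return p_f / p_d


def single_channel_from_membrane_permeability(
    P_f_um_per_s: float, channel_density_per_cm2: float
) -> float:
    """Single-channel p_f from a membrane-level P_f and channel density.

    ``P_f`` in um s^-1 is converted to cm s^-1 and divided by the number of
    channels per cm^2 of membrane, giving cm^3 s^-1 per channel.
    """
    if channel_density_per_cm2 <= 0:
        raise ValueError("channel density must be > 0")
    return (P_f_um_per_s * 1e-4) / channel_density_per_cm2


def aggregate_pf(per_monomer_pf: dict[str, float]) -> tuple[float, float | None]:
    """Mean and sample SD of per-monomer p_f values (Table-style aggregate)."""
    return summarize(list(per_monomer_pf.values()))
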