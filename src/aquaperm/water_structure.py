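"""Channel-water occupancy and z-resolved dipole order parameters.

Occupancy is the number of waters inside the constriction region per frame.
Orientation is characterized by the first two Legendre order parameters of
the angle theta between the water dipole and the channel axis n_z:

    P1(z) = <cos theta> ,    P2(z) = <(3 cos^2 theta - 1) / 2> ,

binned by the axial position z of the water oxygen.  P1 ranges over [-1, 1]
(sign = direction of the mean dipole along the axis), P2 over [-0.5, 1]
(+1 parallel alignment, -0.5 perpendicular).  A bipolar water file, with
dipoles pointing toward a central plane from both sides, shows a P1 sign
change and a P2 minimum at that plane.

The dipole direction is geometric by default (the HOH bisector); for
three-point waters with symmetric hydrogen charges this coincides with the
charge-weighted dipole.  Charge weighting is available via ``charges``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import summarize
from .channel_model import ChannelDefinition, inside_series
from .trajectory_io import Trajectory

__all__ = [
    "OccupancyHistogram",
    "OrientationProfile",
    "occupancy_histogram",
    "water_dipole",
    "order_parameters",
    "water_triples",
    "combine_profiles",
]


@dataclass
class OccupancyHistogram:
    """Distribution of the per-frame CR water count for one monomer."""

    monomer_id: str
    values: np.ndarray  # occupancy values (0..max)
    frame_counts: np.ndarray  # frames observed at each value
    mean: float
    sd: float
    n_frames: int

    def __post_init__(self) -> None:
        if int(self.frame_counts.sum()) != self.n_frames:
            raise ValueError("histogram counts must sum to n_frames")
        check = (
            float(np.dot(self.values, self.frame_counts)) / self.n_frames
            if self.n_frames
            else 0.0
        )
        if abs(check - self.mean) > 1e-9:
            raise ValueError("mean inconsistent with histogram")


@dataclass
class OrientationProfile:
    """P1(z), P2(z) with per-bin sampling statistics.

    Bins never visited by a water are NaN (missing), not zero.  The SDs are
    standard deviations across frames of the per-frame bin means (the error
    bars of the usual profile plots).
    """

    monomer_id: str
    z_centers: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P1_sd: np.ndarray
    P2_sd: np.ndarray
    n_samples: np.ndarray


def occupancy_histogram(
    trajectory: Trajectory,
    channel_def: ChannelDefinition,
    water_indices: np.ndarray | None = None,
) -> OccupancyHistogram:
    """Count CR waters per frame and histogram the counts."""
    if water_indices is None:
        water_indices = trajectory.water_oxygen_indices()
    inside, _, _, _ = inside_series(trajectory, channel_def, water_indices)
    counts = inside.sum(axis=1)
    hist = np.bincount(counts)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return OccupancyHistogram(
        monomer_id=channel_def.monomer_id,
        values=np.arange(len(hist)),
        frame_counts=hist,
        mean=mean,
        sd=sd,
        n_frames=len(counts),
    )


def water_dipole(
    o: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
    charges: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Unit dipole direction of one water molecule.

    Geometric form: the normalized HOH bisector (r_H1 - r_O) + (r_H2 - r_O).
    With ``charges`` (q_O, q_H1, q_H2), the classical point-charge dipole
    sum(q_i * r_i) is used instead.
    """
    o, h1, h2 = (np.asarray(x, dtype=float) for x in (o, h1, h2))
    if charges is None:
        d = (h1 - o) + (h2 - o)
    else:
        q_o, q_h1, q_h2 = charges
        d = q_o * o + q_h1 * h1 + q_h2 * h2
    norm = np.linalg.norm(d)
    if norm < 1e-10:
        raise ValueError("degenerate water geometry: zero dipole")
    return d / norm


def water_triples(trajectory: Trajectory) -> np.ndarray:
    """(O, H1, H2) index triples for every water residue in the topology."""
    by_res: dict[tuple[str, int, str], dict[str, list[int]]] = {}
    for a in trajectory.topology:
        if a.residue_name.upper() not in {
            "HOH",
            "WAT",
            "SOL",
            "TIP3",
            "TIP",
            "SPC",
            "H2O",
        }:
            continue
        key = (a.chain_id, a.residue_number, a.residue_name)
        slot = by_res.setdefault(key, {"O": [], "H": []})
        el = a.element.upper()
        if el in ("O", "H"):
            slot[el].append(a.index)
    triples = []
    for key in sorted(by_res):
        slot = by_res[key]
        if len(slot["O"]) == 1 and len(slot["H"]) == 2:
            triples.append([slot["O"][0], slot["H"][0], slot["H"][1]])
    return np.array(triples, dtype=int).reshape(-1, 3)


def order_parameters(
    trajectory: Trajectory,
    channel_def: ChannelDefinition,
    triples: np.ndarray | None = None,
    bin_width: float = 1.0,
    z_range: tuple[float, float] | None = None,
    charges: tuple[float, float, float] | None = None,
) -> OrientationProfile:
    """z-binned dipole order parameters P1 and P2 for one monomer.

    Each CR water contributes cos(theta) = dipole . n_z to the bin of its
    oxygen's axial coordinate.  ``z_range`` defaults to the time-averaged CR
    interval.  All frames and waters are pooled for the bin means; the SD
    across per-frame bin means provides the error bars.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if triples is None:
        triples = water_triples(trajectory)
    if len(triples) == 0:
        raise ValueError("no water (O, H, H) triples found")
    o_idx = triples[:, 0]
    inside, z, zb, zt = inside_series(trajectory, channel_def, o_idx)
    if z_range is None:
        z_range = (float(zb.mean()), float(zt.mean()))
    lo, hi = min(z_range), max(z_range)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    coords = trajectory.coordinate_array()
    n_z = channel_def.axis

    sum_c = np.zeros(n_bins)
    sum_p2 = np.zeros(n_bins)
    n_samp = np.zeros(n_bins, dtype=int)
    # per-frame bin means, accumulated for the across-frame SD
    fm_count = np.zeros(n_bins, dtype=int)
    fm1_sum = np.zeros(n_bins)
    fm1_sq = np.zeros(n_bins)
    fm2_sum = np.zeros(n_bins)
    fm2_sq = np.zeros(n_bins)

    for f in range(trajectory.n_frames):
        sel = inside[f]
        if not sel.any():
            continue
        tw = triples[sel]
        o = coords[f, tw[:, 0]]
        h1 = coords[f, tw[:, 1]]
        h2 = coords[f, tw[:, 2]]
        if charges is None:
            d = (h1 - o) + (h2 - o)
        else:
            q_o, q_h1, q_h2 = charges
            d = q_o * o + q_h1 * h1 + q_h2 * h2
        norm = np.linalg.norm(d, axis=1)
        ok = norm > 1e-10
        if not ok.all():
            raise ValueError("degenerate water geometry: zero dipole")
        cos = (d @ n_z) / norm
        p2 = 0.5 * (3.0 * cos**2 - 1.0)
        bins = np.clip(((z[f, sel] - lo) / bin_width).astype(int), 0, n_bins - 1)
        np.add.at(sum_c, bins, cos)
        np.add.at(sum_p2, bins, p2)
        np.add.at(n_samp, bins, 1)
        cnt = np.bincount(bins, minlength=n_bins)
        occ = cnt > 0
        m1 = np.zeros(n_bins)
        m2 = np.zeros(n_bins)
        np.add.at(m1, bins, cos)
        np.add.at(m2, bins, p2)
        m1[occ] /= cnt[occ]
        m2[occ] /= cnt[occ]
        fm_count[occ] += 1
        fm1_sum[occ] += m1[occ]
        fm1_sq[occ] += m1[occ] ** 2
        fm2_sum[occ] += m2[occ]
        fm2_sq[occ] += m2[occ] ** 2

    if n_samp.sum() == 0:
        warnings.warn("no waters found in any bin; profile is all-missing")

    with np.errstate(invalid="ignore", divide="ignore"):
        P1 = np.where(n_samp > 0, sum_c / np.maximum(n_samp, 1), np.nan)
        P2 = np.where(n_samp > 0, sum_p2 / np.maximum(n_samp, 1), np.nan)
        mean1 = fm1_sum / np.maximum(fm_count, 1)
        mean2 = fm2_sum / np.maximum(fm_count, 1)
        var1 = fm1_sq / np.maximum(fm_count, 1) - mean1**2
        var2 = fm2_sq / np.maximum(fm_count, 1) - mean2**2
        P1_sd = np.where(fm_count > 1, np.sqrt(np.maximum(var1, 0.0)), np.nan)
        P2_sd = np.where(fm_count > 1, np.sqrt(np.maximum(var2, 0.0)), np.nan)
        P1_sd = np.where(n_samp > 0, P1_sd, np.nan)
        P2_sd = np.where(n_samp > 0, P2_sd, np.nan)

    return OrientationProfile(
        monomer_id=channel_def.monomer_id,
        z_centers=centers,
        P1=P1,
        P2=P2,
        P1_sd=P1_sd,
        P2_sd=P2_sd,
        n_samples=n_samp,
    )


def combine_profiles(profiles: list[OrientationProfile]) -> OrientationProfile:
    """Cross-monomer average profile with SD-across-monomers error bars.

    Profiles must share a binning (same z centers).
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    z = profiles[0].z_centers
    for p in profiles[1:]:
        if len(p.z_centers) != len(z) or not np.allclose(p.z_centers, z):
            raise ValueError("profiles have different binnings")
    p1 = np.vstack([p.P1 for p in profiles])
    p2 = np.vstack([p.P2 for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        P1 = np.nanmean(p1, axis=0)
        P2 = np.nanmean(p2, axis=0)
        P1_sd = np.nanstd(p1, axis=0, ddof=1) if len(profiles) > 1 else np.full_like(P1, np.nan)
        P2_sd = np.nanstd(p2, axis=0, ddof=1) if len(profiles) > 1 else np.full_like(P2, np.nan)
    return OrientationProfile(
        monomer_id="mean",
        z_centers=z,
        P1=P1,
        P2=P2,
        P1_sd=P1_sd,
        P2_sd=P2_sd,
        n_samples=np.sum([p.n_samples for p in profiles], axis=0),
    )
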