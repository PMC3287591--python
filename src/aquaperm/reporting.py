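"""Config-driven orchestration and the summary-table report.

``run_pipeline`` executes the enabled analysis stages on a trajectory (read
from files or generated by the synthetic simulator) and assembles a
:class:`PermeabilityReport` mirroring the usual per-monomer summary table:
p_d, p_f (reported in 1e-14 cm^3 s^-1), channel occupancy <N>, the p_f/p_d
single-fileness ratio, and the CR length L-bar, each with its
mean +/- sample SD aggregate over monomers.  Rounding happens only at the
presentation (TSV) layer; the JSON report carries full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._stats import summarize
from . import channel_model, collective_diffusion, permeation_analysis, water_structure
from .channel_model import ChannelDefinition
from .permeation_analysis import PhysicalConstants
from .trajectory_io import Trajectory, read_pdb, read_xyz_multiframe

__all__ = ["PermeabilityReport", "run_pipeline", "summarize", "load_config"]

logger = logging.getLogger("aquaperm")

__version__ = "0.1.0"


@dataclass
class PermeabilityReport:
    """Per-monomer and aggregate transport summary with provenance."""

    per_monomer: dict[str, dict[str, float]]
    aggregate: dict[str, dict[str, float | None]]
    counts: dict[str, int]
    t_sim_ns: float
    provenance: dict[str, object] = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "per_monomer": self.per_monomer,
            "aggregate": self.aggregate,
            "counts": self.counts,
            "t_sim_ns": self.t_sim_ns,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "PermeabilityReport":
        d = json.loads(text)
        return cls(
            per_monomer=d["per_monomer"],
            aggregate=d["aggregate"],
            counts=d["counts"],
            t_sim_ns=d["t_sim_ns"],
            provenance=d.get("provenance", {}),
        )

    def table_tsv(self, path: str | None = None) -> str:
        """Summary-table text: permeabilities in 1e-14 cm^3 s^-1, one decimal."""
        monomers = sorted(self.per_monomer)
        rows = []
        scale = {"p_d": 1e14, "p_f": 1e14, "occupancy": 1.0, "pf_over_pd": 1.0, "L": 1.0}
        label = {
            "p_d": "p_d (1e-14 cm3/s)",
            "p_f": "p_f (1e-14 cm3/s)",
            "occupancy": "<N>",
            "pf_over_pd": "p_f/p_d",
            "L": "L (A)",
        }
        for key in ["p_d", "p_f", "occupancy", "pf_over_pd", "L"]:
            agg = self.aggregate.get(key)
            if agg is None:
                continue
            s = scale[key]
            mean = agg["mean"] * s
            sd = agg["sd"] * s if agg["sd"] is not None else float("nan")
            row = {"quantity": label[key], "mean_sd": f"{mean:.1f} +/- {sd:.1f}"}
            for m in monomers:
                v = self.per_monomer[m].get(key)
                row[m] = f"{v * s:.1f}" if v is not None else ""
            rows.append(row)
        df = pd.DataFrame(rows)
        text = df.to_csv(sep="\t", index=False)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


DEFAULT_ANALYSIS = {
    "burn_in_ns": 0.0,
    "window_ps": 100.0,
    "stride_ps": None,  # None -> non-overlapping (stride = window)
    "fit_range_ps": [10.0, 100.0],
    "bin_width": 1.0,
    "z_grid_step": 0.5,
    "frame_stride": 1,
    "coordinate_mode": "either_clipped",
}

ALL_STAGES = ["permeability", "occupancy", "orientation"]


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _channel_defs_from_config(config: dict) -> list[ChannelDefinition]:
    defs = []
    for c in config["channels"]:
        defs.append(
            ChannelDefinition(
                monomer_id=str(c["monomer_id"]),
                top_selector=c["top"],
                bottom_selector=c["bottom"],
                axis=np.asarray(c.get("axis", [0.0, 0.0, 1.0]), dtype=float),
                lateral_cutoff=float(c.get("lateral_cutoff", 8.0)),
                fixed_z_window=tuple(c["fixed_z_window"])
                if c.get("fixed_z_window")
                else None,
                flip_z=bool(c.get("flip_z", False)),
            )
        )
    return defs


def _load_trajectory(config: dict) -> tuple[Trajectory, list[ChannelDefinition], dict]:
    prov: dict[str, object] = {}
    if "synthetic" in config:
        from .synthetic_data import (
            SfChannelConfig,
            simulate_single_file,
            single_file_channel_defs,
        )

        syn = dict(config["synthetic"])
        syn.setdefault("rng_seed", int(config.get("seed", 0)))
        cfg = SfChannelConfig(**syn)
        traj, truth, _events = simulate_single_file(cfg)
        cdefs = (
            _channel_defs_from_config(config)
            if "channels" in config
            else single_file_channel_defs(cfg)
        )
        prov["source"] = "synthetic"
        prov["synthetic_seed"] = cfg.rng_seed
        prov["ground_truth_pf_over_pd"] = truth.expected_pf_over_pd
        return traj, cdefs, prov
    tr = config["trajectory"]
    dt = float(tr.get("frame_interval", 1.0))
    if "xyz" in tr:
        topo = read_pdb(tr["pdb"], frame_interval=dt).topology if "pdb" in tr else None
        traj = read_xyz_multiframe(tr["xyz"], topology=topo, frame_interval=dt)
        prov["source"] = tr["xyz"]
    else:
        traj = read_pdb(tr["pdb"], frame_interval=dt)
        prov["source"] = tr["pdb"]
    return traj, _channel_defs_from_config(config), prov


def _burned(traj: Trajectory, burn_in_ns: float) -> Trajectory:
    if burn_in_ns <= 0:
        return traj
    t0 = traj.frames[0].time + burn_in_ns * 1e3
    keep = [f for f in traj.frames if f.time >= t0]
    if len(keep) < 2:
        raise ValueError("burn-in removes the whole trajectory")
    shifted = [f for f in keep]
    return Trajectory(
        topology=traj.topology, frames=shifted, frame_interval=traj.frame_interval
    )


def run_pipeline(
    config: dict | str,
    out_dir: str | None = None,
) -> PermeabilityReport:
    """Run the enabled stages and build the summary report.

    ``config`` is a YAML path or an equivalent dict; see the package README
    for the schema.  With ``out_dir`` set, the report (JSON + TSV) and the
    per-stage series (events, cumulative counts, n(t), MSD, occupancy,
    orientation profiles) are written there.  Output is deterministic given
    the config and seed.
    """
    if isinstance(config, str):
        config = load_config(config)
    analysis = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    stages = config.get("stages", ALL_STAGES)
    constants = PhysicalConstants()
    t_start = time.time()

    traj, cdefs, prov = _load_trajectory(config)
    traj = _burned(traj, float(analysis["burn_in_ns"]))
    monomers = [c.monomer_id for c in cdefs]
    water_idx = traj.water_oxygen_indices()
    times = traj.times
    t_sim_ns = float(times[-1] - times[0]) / 1e3
    logger.info(
        "pipeline: %d frames, %d waters, %d monomers, %.3f ns",
        traj.n_frames,
        len(water_idx),
        len(monomers),
        t_sim_ns,
    )

    per: dict[str, dict[str, float]] = {m: {} for m in monomers}
    aggregate: dict[str, dict[str, float | None]] = {}
    counts: dict[str, int] = {}
    artifacts: dict[str, pd.DataFrame] = {}

    length_result = channel_model.channel_length(traj, cdefs)
    for m in monomers:
        per[m]["L"] = length_result.per_monomer_mean[m]
    aggregate["L"] = {"mean": length_result.mean, "sd": length_result.sd}

    if "permeability" in stages:
        try:
            events = permeation_analysis.detect_events(traj, cdefs, water_idx)
            ev_summary = permeation_analysis.summarize_events(
                events, monomers, t_sim_ns, constants
            )
            counts.update(
                N_plus=ev_summary.n_plus,
                N_minus=ev_summary.n_minus,
                N_pm=ev_summary.n_pm,
            )
            pf_per: dict[str, float] = {}
            for m, cdef in zip(monomers, cdefs):
                series = collective_diffusion.collective_coordinate(
                    traj,
                    cdef,
                    length_result.per_monomer_mean[m],
                    water_idx,
                    mode=analysis["coordinate_mode"],
                )
                msd = collective_diffusion.msd_multi_origin(
                    series,
                    window_length=float(analysis["window_ps"]),
                    origin_stride=analysis["stride_ps"]
                    and float(analysis["stride_ps"]),
                )
                fit = collective_diffusion.fit_Dn(
                    msd, tuple(analysis["fit_range_ps"])
                )
                p_f = collective_diffusion.osmotic_permeability(fit.D_n, constants)
                pf_per[m] = p_f
                per[m].update(
                    N_pm=ev_summary.per_monomer[m]["N_pm"],
                    k0=ev_summary.per_monomer[m]["k0"],
                    p_d=ev_summary.per_monomer[m]["p_d"],
                    D_n=fit.D_n,
                    p_f=p_f,
                    pf_over_pd=collective_diffusion.pf_pd_ratio(
                        p_f, ev_summary.per_monomer[m]["p_d"]
                    ),
                )
            aggregate["k0_pooled"] = {"mean": ev_summary.k0, "sd": None}
            aggregate["p_d_pooled"] = {"mean": ev_summary.p_d, "sd": None}
            for key in ["p_d", "p_f", "pf_over_pd", "D_n"]:
                vals = [per[m][key] for m in monomers if key in per[m]]
                vals = [v for v in vals if np.isfinite(v)]
                if vals:
                    mean, sd = summarize(vals)
                    aggregate[key] = {"mean": mean, "sd": sd}
            artifacts["events"] = permeation_analysis.events_to_dataframe(events)
            artifacts["cumulative_events"] = permeation_analysis.cumulative_counts(
                events, times
            )
        except Exception as exc:
            raise RuntimeError(f"[permeability] stage failed: {exc}") from exc

    if "occupancy" in stages:
        try:
            occ_means = {}
            hist_frames = []
            for cdef in cdefs:
                occ = water_structure.occupancy_histogram(traj, cdef, water_idx)
                per[cdef.monomer_id]["occupancy"] = occ.mean
                occ_means[cdef.monomer_id] = occ.mean
                hist_frames.append(
                    pd.DataFrame(
                        {
                            "monomer": cdef.monomer_id,
                            "occupancy": occ.values,
                            "frames": occ.frame_counts,
                        }
                    )
                )
            mean, sd = summarize(list(occ_means.values()))
            aggregate["occupancy"] = {"mean": mean, "sd": sd}
            artifacts["occupancy"] = pd.concat(hist_frames, ignore_index=True)
        except Exception as exc:
            raise RuntimeError(f"[occupancy] stage failed: {exc}") from exc

    if "orientation" in stages:
        try:
            triples = water_structure.water_triples(traj)
            profiles = [
                water_structure.order_parameters(
                    traj, cdef, triples, bin_width=float(analysis["bin_width"])
                )
                for cdef in cdefs
            ]
            combined = (
                water_structure.combine_profiles(profiles)
                if len(profiles) > 1
                else profiles[0]
            )
            artifacts["orientation"] = pd.DataFrame(
                {
                    "z": combined.z_centers,
                    "P1": combined.P1,
                    "P1_sd": combined.P1_sd,
                    "P2": combined.P2,
                    "P2_sd": combined.P2_sd,
                    "n_samples": combined.n_samples,
                }
            )
        except Exception as exc:
            raise RuntimeError(f"[orientation] stage failed: {exc}") from exc

    logger.info("pipeline finished in %.2f s", time.time() - t_start)
    prov.update(
        config_hash=_config_hash(config),
        seed=int(config.get("seed", 0)),
        version=__version__,
        stages=list(stages),
    )
    report = PermeabilityReport(
        per_monomer=per,
        aggregate=aggregate,
        counts=counts,
        t_sim_ns=t_sim_ns,
        provenance=prov,
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        report.to_json(os.path.join(out_dir, "report.json"))
        report.table_tsv(os.path.join(out_dir, "table1.tsv"))
        for name, df in artifacts.items():
            df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    return report
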