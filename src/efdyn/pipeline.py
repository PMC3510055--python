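"""Orchestration: run the full per-system analysis and compare systems.

One :func:`run_analysis` call takes a trajectory (plus optional holo ion
and receptor charges) and produces a :class:`Report` holding the tables
the mutant-comparison study is built from: order-parameter profile,
DCCM with region-pair signs, HA/HB angle series, HC helical content,
site II chelation metrics, conformational clusters and the weighted BD
association rate.  Stages fail independently: an apo system without a
bound ion records the chelation stage as not-applicable and the rest
completes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bdrates import BDConfig, estimate_rate, weighted_rate
from .calcium_site import chelation_distances, dentation, pair_distance
from .clustering import gromos_cluster, pairwise_rmsd, representatives
from .correlations import block_summary, dccm, superpose
from .helixgeom import helix_content, interhelical_angle_series
from .model_io import RegionMap, Structure, Trajectory, read_pdb, read_trajectory
from .orderparams import nh_vectors, windowed_s2

logger = logging.getLogger("efdyn")

__all__ = ["AnalysisConfig", "Report", "run_analysis", "compare_systems", "load_config"]


@dataclass
class AnalysisConfig:
    """Declarative description of one system analysis."""

    label: str
    trajectory: Trajectory | None = None
    topology_path: str | None = None
    trajectory_path: str | None = None
    region_map: RegionMap = field(default_factory=RegionMap)
    window_ps: float = 500.0
    cluster_cutoff: float = 1.5
    cluster_stride: int = 1
    cluster_selection: str = "name CA"
    ion_spec: str = "resname CAL"
    run_bd: bool = False
    bd_config: BDConfig = field(default_factory=BDConfig)
    dccm_threshold: float = 0.2
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cluster_cutoff <= 0 or self.window_ps <= 0:
            raise ValueError("cutoffs and windows must be positive")

    def resolve_trajectory(self) -> Trajectory:
        if self.trajectory is not None:
            return self.trajectory
        if not self.topology_path or not self.trajectory_path:
            raise ValueError("either a Trajectory or topology+trajectory paths required")
        topo = read_pdb(self.topology_path)
        assert isinstance(topo, Structure)
        return read_trajectory(topo, self.trajectory_path)


@dataclass
class Report:
    """All per-system results, each traceable to its producing stage."""

    label: str
    tables: dict[str, Any]
    series: dict[str, Any]
    errors: dict[str, str]
    provenance: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        """Write numeric tables as tab-separated text plus a provenance log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            path = out / f"{self.label}_{name}.tsv"
            if isinstance(tab, pd.DataFrame):
                tab.to_csv(path, sep="\t")
            elif hasattr(tab, "to_table"):
                path.write_text(tab.to_table())
            else:
                path.write_text(json.dumps(tab, indent=2, default=str))
        (out / f"{self.label}_provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )


def _traj_hash(traj: Trajectory) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(traj.frames).tobytes())
    return h.hexdigest()[:16]


def run_analysis(config: AnalysisConfig) -> Report:
    """Run every analysis stage on one system; partial failures recorded."""
    traj = config.resolve_trajectory()
    rm = config.region_map
    tables: dict[str, Any] = {}
    series: dict[str, Any] = {}
    errors: dict[str, str] = {}

    def stage(name, fn):
        try:
            fn()
            logger.info("stage %s complete", name)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            errors[name] = f"{type(exc).__name__}: {exc}"
            logger.warning("stage %s failed: %s", name, errors[name])

    def _orderparams():
        vs = nh_vectors(traj)
        profile = windowed_s2(vs, window_ps=config.window_ps)
        tables["order_parameters"] = pd.DataFrame(
            {"residue": profile.residue_ids, "S2": profile.s2, "stderr": profile.stderr}
        ).set_index("residue")
        series["s2_profile"] = profile

    def _correlations():
        aligned = superpose(traj)
        corr = dccm(aligned)
        summary = block_summary(corr, rm, threshold=config.dccm_threshold)
        series["dccm"] = corr
        tables["correlation_signs"] = pd.DataFrame(
            [
                {"region_a": a, "region_b": b, "mean": v["mean"], "sign": v["sign"]}
                for (a, b), v in summary.blocks.items()
            ]
        )

    def _angles():
        ha = rm.regions["HA"]
        hb = rm.regions["HB"]
        ang = interhelical_angle_series(traj, ha, hb)
        series["ha_hb_angle"] = ang
        tables["interhelical_angle"] = pd.DataFrame(
            [{"pair": "HA/HB", "mean_deg": ang.mean}]
        )

    def _content():
        hc = helix_content(traj, (54, 68))
        series["helix_content"] = hc
        tables["helix_content"] = pd.DataFrame(
            [{"range": "54-68", "mean_residues": hc.mean}]
        )

    def _calcium():
        chel = chelation_distances(traj, config.ion_spec, rm)
        tables["chelation"] = chel.table
        dent_rows = []
        for resnum, (resname, _) in sorted(rm.chelators.items()):
            if resname in ("ASP", "GLU"):
                ds = dentation(traj, resnum, config.ion_spec)
                dent_rows.append({"residue": resnum, **ds.fractions})
        tables["dentation"] = pd.DataFrame(dent_rows).set_index("residue")

    def _pairing():
        try:
            s, counts, edges = pair_distance(traj)
        except Exception:
            return  # toy topologies may lack D67/E76; not a failure
        series["d67_e76_distance"] = s
        tables["d67_e76"] = pd.DataFrame(
            [{"mean_A": float(s.mean()), "sd_A": float(s.std())}]
        )

    cluster_state: dict[str, Any] = {}

    def _cluster():
        m = pairwise_rmsd(
            traj, selection=config.cluster_selection, stride=config.cluster_stride
        )
        cs = gromos_cluster(m, config.cluster_cutoff)
        cluster_state["set"] = cs
        tables["clusters"] = pd.DataFrame(
            [
                {
                    "cluster": i,
                    "size": len(c.members),
                    "weight": c.weight,
                    "representative_frame": c.representative * config.cluster_stride,
                }
                for i, c in enumerate(cs.clusters)
            ]
        ).set_index("cluster")

    def _bd():
        if not config.run_bd:
            return
        cs = cluster_state.get("set")
        if cs is None:
            raise RuntimeError("clustering stage required before BD rates")
        reps = representatives(cs, traj, stride=config.cluster_stride)
        ests, weights = [], []
        for i, (struct, w) in enumerate(reps):
            cfg = BDConfig(
                **{**config.bd_config.__dict__, "seed": config.bd_config.seed + i}
            )
            ests.append(estimate_rate(struct, cfg, provenance=f"cluster-{i}"))
            weights.append(w)
        overall = weighted_rate(ests, weights)
        tables["rates"] = pd.DataFrame(
            [
                {
                    "provenance": e.provenance,
                    "k_Ms": e.k,
                    "beta": e.beta,
                    "k_b": e.k_b,
                    "weight": w,
                }
                for e, w in zip(ests, weights)
            ]
            + [
                {
                    "provenance": overall.provenance,
                    "k_Ms": overall.k,
                    "beta": overall.beta,
                    "k_b": overall.k_b,
                    "weight": 1.0,
                }
            ]
        )
        series["weighted_rate"] = overall

    stage("order_parameters", _orderparams)
    stage("correlations", _correlations)
    stage("interhelical_angle", _angles)
    stage("helix_content", _content)
    stage("calcium_site", _calcium)
    stage("carboxyl_pairing", _pairing)
    stage("clustering", _cluster)
    stage("bd_rates", _bd)

    if "calcium_site" in errors and "no bound ion" in errors["calcium_site"].lower():
        errors["calcium_site"] = "not applicable (apo system, no bound ion)"

    provenance = {
        "label": config.label,
        "efdyn_version": __version__,
        "n_frames": traj.n_frames,
        "dt_ps": traj.dt,
        "trajectory_sha256_16": _traj_hash(traj),
        "window_ps": config.window_ps,
        "cluster_cutoff_A": config.cluster_cutoff,
        "bd_seed": config.bd_config.seed if config.run_bd else None,
    }
    report = Report(config.label, tables, series, errors, provenance)
    if config.output_dir:
        report.write(config.output_dir)
    return report


def compare_systems(reports: list[Report]) -> dict[str, pd.DataFrame]:
    """Pairwise per-metric deltas between system reports (descriptive only)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    out: dict[str, pd.DataFrame] = {}

    rows = []
    for i, a in enumerate(reports):
        for b in reports[i + 1 :]:
            row: dict[str, Any] = {"system_a": a.label, "system_b": b.label}
            for key, col in [
                ("helix_content", "mean_residues"),
                ("interhelical_angle", "mean_deg"),
            ]:
                if key in a.tables and key in b.tables:
                    row[f"delta_{key}"] = float(
                        a.tables[key][col].iloc[0] - b.tables[key][col].iloc[0]
                    )
            rows.append(row)
    out["scalar_deltas"] = pd.DataFrame(rows)

    base = reports[0]
    if "order_parameters" in base.tables:
        s2 = base.tables["order_parameters"]["S2"].rename(base.label).to_frame()
        for r in reports[1:]:
            if "order_parameters" in r.tables:
                s2[r.label] = r.tables["order_parameters"]["S2"]
                s2[f"delta_{r.label}"] = s2[r.label] - s2[base.label]
        out["s2_deltas"] = s2
    return out


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a declarative YAML text file.

    Recognised keys mirror the dataclass fields; a ``bd`` section maps
    onto :class:`BDConfig`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bd_raw = raw.pop("bd", {})
    bd = BDConfig(**bd_raw) if bd_raw else BDConfig()
    return AnalysisConfig(bd_config=bd, **raw)
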