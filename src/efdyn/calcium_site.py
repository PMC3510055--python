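"""Site II Ca²⁺ coordination metrics.

Per-oxygen chelation distances to the bound ion (mean ± s.d. over
frames), mono-/bi-dentate classification of carboxylate coordination,
and arbitrary atom-pair distance series with histograms (the default
pair, D67 carboxyl carbon to E76 carboxyl carbon, tracks whether the
site II loop is pre-organised for binding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import RegionMap, Trajectory, select

__all__ = [
    "ChelationTable",
    "DentationSeries",
    "chelation_distances",
    "dentation",
    "pair_distance",
]

_CARBOXYL_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class ChelationTable:
    """Mean ion–oxygen distances, one row per chelating oxygen."""

    table: pd.DataFrame  # index (residue_number, atom); columns mean_A, sd_A

    def to_table(self) -> str:
        lines = ["residue\tatom\tmean_A\tsd_A"]
        for (res, atom), row in self.table.iterrows():
            lines.append(f"{res}\t{atom}\t{row.mean_A:.3f}\t{row.sd_A:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class DentationSeries:
    """Per-frame coordination class of one carboxylate residue."""

    residue_number: int
    labels: list[str]  # 'bidentate' | 'monodentate' | 'unbound'
    cutoff: float

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {
            k: self.labels.count(k) / n
            for k in ("bidentate", "monodentate", "unbound")
        }


def _resolve_ion(traj: Trajectory, ion_spec: str) -> int:
    idx = select(traj, ion_spec)
    if len(idx) != 1:
        raise ValueError(
            f"ion selection {ion_spec!r} resolved to {len(idx)} atoms "
            "(need exactly 1); an apo trajectory has no bound ion"
        )
    return idx[0]


def chelation_distances(
    traj: Trajectory,
    ion_spec: str = "resname CAL",
    region_map: RegionMap | None = None,
) -> ChelationTable:
    """Mean distance from the ion to every chelating oxygen of site II.

    The chelator set comes from the region map (default: D65 OD1/OD2,
    D67 OD1/OD2, S69 OG, T71 OG1, E76 OE1/OE2).  Missing oxygens raise,
    naming the atom.
    """
    region_map = region_map or RegionMap()
    ion = _resolve_ion(traj, ion_spec)
    rows = []
    index = []
    for resnum in sorted(region_map.chelators):
        resname, oxygens = region_map.chelators[resnum]
        for aname in oxygens:
            hits = [
                i
                for i, a in enumerate(traj.topology.atoms)
                if a.residue_number == resnum and a.name == aname
            ]
            if len(hits) != 1:
                raise ValueError(
                    f"chelator atom {resnum} {resname} {aname}: "
                    f"found {len(hits)} matches (need exactly 1)"
                )
            d = np.linalg.norm(traj.frames[:, hits[0]] - traj.frames[:, ion], axis=1)
            rows.append({"mean_A": float(d.mean()), "sd_A": float(d.std(ddof=0))})
            index.append((resnum, aname))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["residue", "atom"]))
    return ChelationTable(table)


def dentation(
    traj: Trajectory,
    residue_number: int,
    ion_spec: str = "resname CAL",
    cutoff: float = 3.0,
) -> DentationSeries:
    """Mono-/bi-dentate classification of an Asp/Glu residue per frame.

    bidentate: both carboxylate oxygens within ``cutoff`` of the ion;
    monodentate: exactly one; unbound: none.  The 3.0 Å default is a
    typical Ca–O coordination bound.
    """
    ion = _resolve_ion(traj, ion_spec)
    resnames = {
        a.residue_number: a.residue_name for a in traj.topology.atoms
    }
    resname = resnames.get(residue_number)
    if resname not in _CARBOXYL_OXYGENS:
        raise ValueError(
            f"residue {residue_number} ({resname}) is not a carboxylate (Asp/Glu)"
        )
    o_idx = []
    for aname in _CARBOXYL_OXYGENS[resname]:
        hits = [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.residue_number == residue_number and a.name == aname
        ]
        if len(hits) != 1:
            raise ValueError(f"carboxylate oxygen {aname} of residue {residue_number} missing")
        o_idx.append(hits[0])
    d = np.linalg.norm(
        traj.frames[:, o_idx, :] - traj.frames[:, [ion], :], axis=2
    )  # (F, 2)
    within = (d <= cutoff).sum(axis=1)
    labels = ["unbound", "monodentate", "bidentate"]
    return DentationSeries(
        residue_number, [labels[int(k)] for k in within], cutoff
    )


def pair_distance(
    traj: Trajectory,
    spec1: str = "resid 67 and name CG",
    spec2: str = "resid 76 and name CD",
    bins: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame distance between two single-atom selections, plus histogram.

    Defaults measure the D67–E76 carboxyl-carbon pairing.  Returns
    (series, counts, bin_edges); default bins are 0.25 Å wide over 2–16 Å.
    """
    i1 = select(traj, spec1)
    i2 = select(traj, spec2)
    if len(i1) != 1 or len(i2) != 1:
        raise ValueError(
            f"pair specs must each resolve to one atom "
            f"({spec1!r} -> {len(i1)}, {spec2!r} -> {len(i2)})"
        )
    series = np.linalg.norm(
        traj.frames[:, i1[0]] - traj.frames[:, i2[0]], axis=1
    )
    if bins is None:
        bins = np.arange(2.0, 16.0 + 0.25, 0.25)
    counts, edges = np.histogram(series, bins=bins)
    return series, counts, edges
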