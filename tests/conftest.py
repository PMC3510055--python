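"""Shared fixtures: synthetic troponin-C-like systems built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from efdyn.model_io import Atom, Structure, Trajectory
from efdyn.synthetic import ideal_helix_backbone


def _add_sidechain_atoms(structure: Structure) -> Structure:
    """Graft site II chelator side-chain oxygens onto an all-ALA backbone.

    Residues 65/67 become ASP (OD1, OD2, CG), 69 SER (OG), 71 THR (OG1),
    76 GLU (OE1, OE2, CD); oxygens sit at fixed offsets from the Cα so a
    Ca²⁺ ion placed at their centroid is chelated at realistic ~2.3 Å
    distances.
    """
    plan = {
        65: ("ASP", [("OD1", 1.0), ("OD2", 1.2), ("CG", 0.6)]),
        67: ("ASP", [("OD1", 1.0), ("OD2", 1.4), ("CG", 0.6)]),
        69: ("SER", [("OG", 1.1)]),
        71: ("THR", [("OG1", 1.2)]),
        76: ("GLU", [("OE1", 1.0), ("OE2", 1.1), ("CD", 0.6)]),
    }
    ca_pos = {
        a.residue_number: a.coords for a in structure.atoms if a.name == "CA"
    }
    centroid = np.mean([ca_pos[r] for r in plan], axis=0)
    atoms = []
    serial = 1
    for a in structure.atoms:
        resname = plan.get(a.residue_number, (a.residue_name, []))[0]
        atoms.append(
            Atom(serial, a.name, a.residue_number, resname, a.chain, a.coords.copy())
        )
        serial += 1
    for res, (resname, sidechain) in sorted(plan.items()):
        ca = ca_pos[res]
        toward = centroid - ca
        toward /= np.linalg.norm(toward)
        for k, (name, frac) in enumerate(sidechain):
            jitter = 0.3 * np.array([np.sin(k * 2.1), np.cos(k * 1.3), 0.2 * k])
            pos = ca + toward * (np.linalg.norm(centroid - ca) - 2.0 - frac) + jitter
            atoms.append(Atom(serial, name, res, resname, "A", pos))
            serial += 1
    return Structure(atoms, title="tnc-like")


def make_tnc_like_trajectory(
    n_frames: int = 30,
    noise: float = 0.15,
    seed: int = 11,
    with_ion: bool = True,
    dt: float = 6.0,
) -> Trajectory:
    """Synthetic regulatory-domain stand-in covering residues 4–86.

    An ideal α-helical backbone (so helix regions and N–H vectors resolve)
    with grafted site II chelator side chains and, optionally, a Ca²⁺ ion
    at the chelator-oxygen centroid; frames add small Gaussian noise.
    Purely synthetic plumbing for pipeline-level tests.
    """
    backbone = ideal_helix_backbone(83, resnum_start=4)
    struct = _add_sidechain_atoms(backbone)
    if with_ion:
        oxy = [
            a.coords
            for a in struct.atoms
            if a.name in ("OD1", "OD2", "OG", "OG1", "OE1", "OE2")
        ]
        ion_pos = np.mean(oxy, axis=0)
        atoms = struct.atoms + [
            Atom(len(struct.atoms) + 1, "CA", 999, "CAL", "X", ion_pos)
        ]
        struct = Structure(atoms, title=struct.title)
    rng = np.random.default_rng(seed)
    base = struct.coords
    frames = base[None] + rng.normal(0.0, noise, size=(n_frames, *base.shape))
    return Trajectory(struct, frames, dt=dt)


@pytest.fixture(scope="session")
def tnc_like_holo() -> Trajectory:
    return make_tnc_like_trajectory(n_frames=30, with_ion=True)


@pytest.fixture(scope="session")
def tnc_like_apo() -> Trajectory:
    return make_tnc_like_trajectory(n_frames=30, with_ion=False)
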