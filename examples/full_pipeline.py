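"""Full per-system analysis and apo/holo comparison on a synthetic domain.

Builds a small troponin-C-like regulatory domain (ideal helical backbone
over residues 4-86 with grafted site II chelator oxygens and an optional
bound ion), runs every analysis stage through one call, and compares a
rigid 'holo-like' system with a floppier 'apo-like' one.
"""

import numpy as np

from efdyn.model_io import Atom, Structure, Trajectory
from efdyn.pipeline import AnalysisConfig, compare_systems, run_analysis
from efdyn.synthetic import ideal_helix_backbone


def build_domain(n_frames: int, noise: float, with_ion: bool, seed: int) -> Trajectory:
    backbone = ideal_helix_backbone(83, resnum_start=4)
    plan = {65: ("ASP", ["OD1", "OD2"]), 67: ("ASP", ["OD1", "OD2"]),
            69: ("SER", ["OG"]), 71: ("THR", ["OG1"]), 76: ("GLU", ["OE1", "OE2"])}
    ca = {a.residue_number: a.coords for a in backbone.atoms if a.name == "CA"}
    centre = np.mean([ca[r] for r in plan], axis=0)
    atoms, serial = [], 1
    for a in backbone.atoms:
        resname = plan.get(a.residue_number, (a.residue_name, []))[0]
        atoms.append(Atom(serial, a.name, a.residue_number, resname, "A", a.coords.copy()))
        serial += 1
    for res, (resname, names) in sorted(plan.items()):
        u = centre - ca[res]
        u /= np.linalg.norm(u)
        for k, name in enumerate(names):
            pos = centre - u * (2.3 + 0.2 * k)
            atoms.append(Atom(serial, name, res, resname, "A", pos))
            serial += 1
    if with_ion:
        atoms.append(Atom(serial, "CA", 999, "CAL", "X", centre))
    struct = Structure(atoms, title="synthetic-domain")
    rng = np.random.default_rng(seed)
    frames = struct.coords[None] + rng.normal(0, noise, (n_frames, len(struct), 3))
    return Trajectory(struct, frames, dt=6.0)


holo = run_analysis(AnalysisConfig(
    label="holo-like", trajectory=build_domain(24, 0.08, True, 1),
    window_ps=72.0, cluster_cutoff=1.0,
))
apo = run_analysis(AnalysisConfig(
    label="apo-like", trajectory=build_domain(24, 0.30, False, 1),
    window_ps=72.0, cluster_cutoff=1.0,
))

for rep in (holo, apo):
    print(f"== {rep.label}: tables {sorted(rep.tables)}")
    for stage, msg in rep.errors.items():
        print(f"   stage '{stage}': {msg}")
print()
print(holo.tables["chelation"].round(2))
cmp = compare_systems([holo, apo])
site_ii = [r for r in range(65, 77) if r in cmp["s2_deltas"].index]
delta = cmp["s2_deltas"].loc[site_ii, "delta_apo-like"].mean()
print(f"\nmean site II S2 change, apo-like minus holo-like: {delta:+.3f}")
print()
print("The apo-like system (larger thermal noise, no bound ion) reports")
print("its chelation stage as not applicable and shows depressed site II")
print("order parameters - the signature separating calcium-free from")
print("calcium-bound dynamics.")
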