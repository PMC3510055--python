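"""Conformational clustering feeding cluster-weighted BD association rates.

A two-conformer trajectory is clustered with the greedy neighbour-count
rule; each representative becomes a rigid receptor for Brownian dynamics
with the phantom-atom reaction criterion, and the rates are combined by
cluster population.  A synthetic PMF barrier then attenuates the
diffusion-limited rate by the Boltzmann (Kramers) factor.
"""

import numpy as np

from efdyn.bdrates import (
    BDConfig,
    PMFProfile,
    estimate_rate,
    kramers_attenuation,
    pmf_barrier,
    weighted_rate,
)
from efdyn.clustering import gromos_cluster, pairwise_rmsd, representatives
from efdyn.model_io import Atom, Structure, Trajectory
from efdyn.synthetic import make_toy_site_receptor

# --- cluster a toy two-conformer trajectory --------------------------
rng = np.random.default_rng(5)
site = make_toy_site_receptor(n_oxygens=4, seed=1)
open_form = site.coords.copy()
open_form[:2] *= 1.4  # two oxygens swing outward in the minor conformer
frames = []
for k in range(8):
    base = site.coords if k < 6 else open_form
    f = base + rng.normal(0, 0.05, base.shape)
    f[-1] = 0.0  # phantom marker stays at the expected ion position
    frames.append(f)
traj = Trajectory(site, np.array(frames), dt=6.0)

m = pairwise_rmsd(traj, selection="resname ASP")
clusters = gromos_cluster(m, cutoff=0.5)
print(f"clusters (cutoff 0.5 A): sizes {[len(c.members) for c in clusters.clusters]}, "
      f"weights {[round(c.weight, 2) for c in clusters.clusters]}")

# --- per-cluster BD rates, weighted ----------------------------------
cfg = BDConfig(n_trajectories=2000, seed=17)  # Ca2+ probe, 150 mM, 310 K
ests, weights = [], []
for i, (rep, w) in enumerate(representatives(clusters, traj)):
    est = estimate_rate(rep, cfg, provenance=f"cluster-{i}")
    ests.append(est)
    weights.append(w)
    print(f"cluster {i}: weight {w:.2f}  beta {est.beta:.3f}  k_D {est.k:.3e} 1/(M s)")
overall = weighted_rate(ests, weights)
print(f"population-weighted k_D: {overall.k:.3e} 1/(M s)")

# --- Kramers attenuation through a PMF barrier -----------------------
r = np.arange(2.0, 12.01, 0.1)
g = np.where(r < 4.0, -2.0 * (1 - (r - 2.0) / 2.0), 0.0) + 3.0 * np.exp(-((r - 4.0) ** 2) / 0.18)
bar = pmf_barrier(PMFProfile(r, g))
k_on = kramers_attenuation(overall.k, bar["barrier_kcal"])
print(f"PMF barrier: {bar['barrier_kcal']:.2f} kcal/mol at {bar['position_A']:.1f} A")
print(f"barrier-attenuated k_on: {k_on:.3e} 1/(M s)")
print()
print("k_D in the 1e9-1e10 range shows electrostatically steered diffusional")
print("encounter; a ~3 kcal/mol desolvation barrier knocks the overall")
print("association rate down ~130-fold into the experimentally observed")
print("1e7-1e8 window.")
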