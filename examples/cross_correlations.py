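"""Dynamic cross-correlation maps and region-pair sign summaries.

A trajectory is generated with a known displacement correlation matrix;
the DCCM must recover it, and the block summary condenses region pairs
into the +/−/0 classes used to compare mutants.
"""

import numpy as np

from efdyn.correlations import block_summary, dccm
from efdyn.model_io import RegionMap
from efdyn.synthetic import CorrSpec, gen_correlated_trajectory, make_ca_reference

n_res, n_frames = 12, 5000
target = np.eye(n_res)
for i in range(4):          # residues 1-4 couple positively to 9-12
    for j in range(8, 12):  # 0.25 is the largest PSD-safe block value here
        target[i, j] = target[j, i] = 0.25

traj = gen_correlated_trajectory(
    make_ca_reference(n_res), CorrSpec(target, n_frames=n_frames, seed=11)
)
corr = dccm(traj)
err = np.abs(corr.matrix - target).max()

rm = RegionMap(regions={"head": (1, 4), "mid": (5, 8), "tail": (9, 12)})
summary = block_summary(corr, rm, pairs=[("head", "tail"), ("head", "mid")])

print("planted correlation 0.25 between head and tail residues")
print(f"max |recovered - target| over all pairs: {err:.4f} "
      f"(sampling bound {3/np.sqrt(n_frames)+0.02:.4f})")
for pair, blk in summary.blocks.items():
    print(f"block {pair[0]}-{pair[1]}: mean C = {blk['mean']:+.3f} -> class '{blk['sign']}'")
print()
print("A '+' class marks concerted motion of two regions (threshold 0.2);")
print("in the troponin-C study such signed blocks distinguish sensitized")
print("from desensitized mutants (e.g. HA-HB anticorrelation).")
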