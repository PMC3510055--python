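"""Backbone order parameters: iRED vs the direct model-free estimator.

Twenty residues wobble independently in 20-degree cones (closed-form
S² = [cosθ₀(1+cosθ₀)/2]² = 0.831); the iRED eigenmode route and the
direct estimator must both recover it.
"""

import numpy as np

from efdyn.orderparams import VectorSeries, ired_matrix, ired_s2, s2_direct, windowed_s2
from efdyn.synthetic import cone_s2_closed_form, gen_cone_series

ids, vecs = gen_cone_series(n_res=20, theta0=20.0, n_frames=20_000, seed=7)
series = VectorSeries(ids, vecs, dt=6.0)

s2_ired = ired_s2(ired_matrix(vecs))
s2_oracle = s2_direct(vecs)
profile = windowed_s2(series, window_ps=500.0)

print(f"closed-form cone S2 (20 deg):   {cone_s2_closed_form(20.0):.4f}")
print(f"direct model-free S2 (mean):    {s2_oracle.mean():.4f}")
print(f"iRED S2 (mean):                 {s2_ired.mean():.4f}")
print(f"max |iRED - direct| per residue: {np.abs(s2_ired - s2_oracle).max():.4f}")
print(f"windowed profile: {profile.n_windows} windows of 500 ps, "
      f"mean stderr {profile.stderr.mean():.4f}")
print()
print("S2 near 1 means a rigid N-H bond vector; the windowed profile is")
print("what gets compared across apo/holo states and mutants: a floppy")
print("binding site shows depressed S2 in the calcium-free state.")
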