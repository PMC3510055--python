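"""Interhelical angles and DSSP helical content.

Builds a helix pair at a prescribed angle (the open-state ~104 degrees
seen for TnI-exposing conformations) and a fraying-helix trajectory
whose per-frame helical residue count is tracked.
"""

from efdyn.helixgeom import helix_axis, helix_content, interhelical_angle
from efdyn.synthetic import gen_helix_content_trajectory, gen_helix_pair

# --- interhelical angle recovery -------------------------------------
for planted in (104.0, 140.0):
    pair = gen_helix_pair(planted, n_res_per_helix=11, seed=int(planted))
    a = helix_axis(pair, (1, 11))
    b = helix_axis(pair, (101, 111))
    got = interhelical_angle(a, b)
    print(f"planted angle {planted:5.1f} deg -> recovered {got:6.2f} deg")

# --- helical content of a fraying helix ------------------------------
traj = gen_helix_content_trajectory(15, helical_counts=[15, 12, 9, 6, 3])
hc = helix_content(traj, residue_range=(1, 15))
print(f"per-frame helical residue counts: {hc.counts.tolist()}")
print(f"trajectory mean helical length:   {hc.mean:.1f} residues")
print()
print("~140 deg means nearly antiparallel packed helices (the closed")
print("regulatory domain); angles near 100-120 deg mark the open,")
print("TnI-binding-competent arrangement.  Helical content in units of")
print("amino-acid length is how helix-C stability is compared between")
print("calcium-sensitized and desensitized variants.")
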