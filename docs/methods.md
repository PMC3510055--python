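# Methods

This note records the models implemented in efdyn, the assumptions and
tunable parameters that matter, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open. Units are fixed package-wide: Å, ps, kcal/mol, Kelvin,
degrees, elementary charge, and M⁻¹s⁻¹ for rates.

## Structures, trajectories and the region map

Structures are ordered atom lists read from PDB; PQR-style files reuse
the occupancy/B-factor columns as partial charge (e) and radius (Å).
Negative radii are legal only on *phantom* atoms — zero-charge markers
that define a spherically symmetric reaction criterion for Brownian
dynamics and take no part in forces or collisions. Trajectories are
frame stacks over a fixed topology, stored as multi-model PDB (three
coordinate decimals, hence round-trips are exact to ≤5×10⁻⁴ Å); the
inter-frame spacing defaults to 6 ps, the snapshot stride used
throughout the analyses. Multi-model NMR files default to model 1.

The troponin-C region map encodes the N-terminal regulatory domain:
helices HN 4–8, HA 14–24, HB 38–48, HC 54–64, HD 73–85; binding loops
25–35 (site I) and 65–70 (site II); β-strands 36–37 and 71–72; and the
site II chelation residues D65, D67, S69, T71, E76 with their
coordinating oxygens (OD1/OD2, OG, OG1, OE1/OE2). Residue numbering
follows the PDB records verbatim; nothing is renumbered. Amide
hydrogens absent from a topology are reconstructed geometrically: H sits
1.01 Å from N, opposed to the bisector of C(i−1)–N and CA–N. Prolines
and chain-leading residues are excluded from amide-based analyses.

## Order parameters (iRED)

The iRED matrix M_ij = ⟨P₂(û_i·û_j)⟩ is accumulated over raw
(unaligned) frames, the standard iRED practice, since the isotropic
average makes explicit superposition unnecessary. Eigenmodes are sorted
by descending eigenvalue with ascending-index tie-breaks — iRED assumes
a spectral gap after the five reorientational modes, and the tie rule
only matters in degenerate synthetic cases. S²_j = 1 − Σ_{m≥6}
λ_m⟨j|m⟩² is clipped to [0, 1] against round-off; completeness
(Σ_m λ_m⟨j|m⟩² = M_jj = 1) guarantees the bound analytically.

Windowed averaging uses non-overlapping windows (default 500 ps);
remainder frames past the last full window are dropped, and the
across-window standard error is reported. The direct model-free
estimator S² = (3Σ_{αβ}⟨u_α u_β⟩²−1)/2 shares no code with the
eigenmode route and is the oracle in the regression suite: on fixtures
with ≥20 residues moving about dispersed axes and no global tumbling
the two agree within 0.05 per residue. When there is genuine overall
tumbling, iRED's separation is the meaningful quantity and the direct
estimator decays with the tumbling — the comparison is only valid on
tumbling-free fixtures.

## Cross-correlation maps

Superposition is a two-pass least-squares fit: frames are first fitted
to the initial frame on the Cα selection, then refitted to the mean of
that pass (the usual convention when no external reference exists).
DCCM entries use full 3-D displacement dot products, Cα only, no mass
weighting. Zero-variance residues yield undefined (NaN) rows flagged to
the caller. Region-pair blocks are classed + / − / 0 against a
configurable threshold, default 0.2, with boundary values taking the
signed class; the threshold is a reporting convention, chosen so that
clearly concerted blocks in the synthetic fixtures classify as signed
while sampling noise classifies as 0.

A caveat the test design reflects: least-squares superposition treats
*all* deviation as noise, so on very small atom sets it can absorb part
of a genuine correlated displacement into the fitted rigid body. The
correlated-trajectory generator therefore emits frames already in a
common frame (displacements along one laboratory axis on a 3-D curved
reference chain), recovery is asserted on those frames directly, and
superposition is checked separately for exact invariance under added
rigid-body motion.

## Helix geometry and DSSP

Helix axes: Cα positions ordered by residue number are smoothed by
consecutive-quadruple averages (4 ≈ 3.6 residues per turn, cancelling
the helical wobble), then a principal line is fitted by SVD and
oriented N→C. At least 6 Cα are required. The interhelical angle is
the plain arccos of the two axis directions — under this convention the
closed regulatory domain reads ≈140° (apo) / ≈132° (holo) and open
TnI-bound arrangements ≈102–121°, which is what makes the angle a
useful open/closed order parameter.

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
model, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with
a bond below −0.5 kcal/mol, a 4-turn at *i* when residue i+4 donates to
the carbonyl of *i*, and the minimal-helix rule (two consecutive
4-turns) extended over the hydrogen-bonded span. Only the α-helix (H)
state is assigned; 3₁₀/π subclasses and bend/turn states are out of
scope. Agreement with an independent reference implementation (mdtraj's
DSSP) is ≥95% per residue on helix/coil fixtures — edge residues of a
helical stretch are where conventions differ. Helical content counts
H-flagged residues per frame in a window (default 54–68, helix C plus
the start of the site II loop) and reports the trajectory mean in
units of amino-acid length, which is why non-integer means are
expected.

## Site II chelation

Chelation tables report mean ± s.d. ion–oxygen distances over all
frames for the chelator oxygens. Dentation of an Asp/Glu is classified
per frame by how many carboxylate oxygens sit within a cutoff of the
ion: both → bidentate, one → monodentate, none → unbound. The default
cutoff of 3.0 Å is a typical Ca–O coordination bound and is
configurable; occupancy fractions sum to one exactly. The D67/E76
pairing is measured between carboxyl carbons (CG of Asp, CD of Glu), a
side-chain-rotation-insensitive proxy for carboxylate approach;
histograms default to 0.25 Å bins over 2–16 Å. The chelator list
implements S69 OG and T71 OG1 (the chemically valid threonine oxygen).

## Conformational clustering

Pairwise frame RMSD superposes every pair independently (Kabsch), so
the matrix is a dissimilarity, not a metric — mild triangle-inequality
violations are expected and documented. The greedy neighbour-count
(GROMOS/Daura) rule takes the frame with the most neighbours within the
cutoff as representative (the frame itself counts as a neighbour),
removes the cluster, and repeats; ties go to the lowest frame index,
making the partition deterministic and permutation-equivariant. Because
neighbour counts only shrink as frames are removed, cluster sizes are
non-increasing in extraction order, and the number of clusters is
non-increasing in the cutoff. Typical cutoffs for the regulatory-domain
systems lie between 1.2 and 1.9 Å, chosen per system so a handful of
clusters covers ≥90% of frames.

## Brownian-dynamics association rates

The NAM decomposition estimates k by combining an analytic steady-state
rate to an outer b-sphere with a simulated reaction probability β from
b, truncated at an escape q-sphere:

    k = k(b)·β / (1 − (1−β)·k(b)/k(q)),
    k(r) = 4πD [∫_r^∞ e^{U(s)/k_BT} s⁻² ds]⁻¹.

The surface integral is evaluated with the substitution x = 1/s, which
maps it onto a finite interval. Surface rates use the receptor's
monopole (total charge at the centroid) — the NAM construction requires
a centrosymmetric potential at b, and b is placed far enough out
(receptor extent + 3 Debye lengths by default; q = 4b) that the
monopole dominates. Both radii are overridable, and rate estimates are
verified to be insensitive to b within the binomial confidence width.

Electrostatics are pairwise Debye–Hückel screened Coulomb terms,
U = Σ 332.06·q_lig·q_i·e^(−κr_i)/(ε·r_i) with ε = 78 and κ from the
ionic strength (κ⁻¹ ≈ 8 Å at 150 mM, 310 K). This is a deliberate
simplification of grid Poisson–Boltzmann electrostatics: the far-field
monopole behaviour that dominates the diffusional encounter rate is
preserved, while short-range dielectric-boundary detail is not — rates
for receptors whose binding site relies on strong local field focusing
will be less accurate.

Propagation is Ermak–McCammon free diffusion,
Δx = (D/k_BT)FΔt + √(2DΔt)·g, with hard-sphere push-back to contact on
ligand–atom overlap. The defaults encode the Ca²⁺ study conditions:
charge +2 e, radius 1.14 Å, D = 0.079 Å²/ps (the standard aqueous
value), 310 K, 150 mM, reaction distance 3.5 Å around the phantom atom.
The phantom defaults to the bound-ion position when a holo frame is
supplied; for apo receptors the centroid of the site II chelating
oxygens is the natural stand-in.

Time step: dt = clamp((0.08·d)²/2D, dt_base, dt_base·dt_cap), where d
is the clearance to the nearest of (receptor surface, reaction surface,
q-sphere) and dt_base = 0.01 ps. This makes the r.m.s. step ≈8% of the
clearance — far-field diffusion is cheap while every boundary is
approached with sub-0.05 Å steps, which keeps the discretization bias
of the absorbing surfaces well under the statistical error at 10⁴
trajectories. Shrinking steps near *all* absorbing boundaries matters:
with coarse far-field steps, mid-step excursions through the q-sphere
go undetected, survival is overestimated, and β inherits a positive
bias of several percent. Validation against closed forms: NAM-combined
rates match Smoluchowski 4πDa for neutral absorbing spheres within 5%
and the Debye result for charged spheres within 10% at 10⁴
trajectories. Stragglers that neither react nor escape within the step
budget (500 000) are counted as escapes and reported.

Per-cluster rates are combined as k = Σ wᵢkᵢ with cluster population
weights; binomial 95% CIs on β propagate through the NAM formula and
the weighting. Receptors are rigid per representative — conformational
flexibility enters only through the cluster weights.

## PMF barriers and Kramers attenuation

A 1-D PMF (two-column text: coordinate Å, free energy kcal/mol,
min-shifted on load) is scanned from the global minimum outward: the
barrier is the highest maximum between the minimum and the outer end,
measured from the outer approach value. Monotone profiles yield ΔG‡ = 0
with a flag rather than an error. The attenuated association rate is
the Boltzmann (Kramers-type) factor k_on = k_D·e^(−ΔG‡/k_BT); a
3 kcal/mol barrier at 310 K (k_BT = 0.616 kcal/mol) attenuates a 10¹⁰
M⁻¹s⁻¹ encounter rate to ≈7.7×10⁷ M⁻¹s⁻¹ — two to three orders of
magnitude, which is exactly the gap between diffusional-encounter
predictions and measured Ca²⁺ association rates.

## Synthetic generators: what they emulate and what they do not

All generators take mandatory seeds, use one documented PRNG stream
each, and are bitwise reproducible.

- **Cone vectors**: a reflected Gaussian random walk in (cosθ, φ) has a
  uniform stationary density on the spherical cap, matching the
  diffusion-in-a-cone model behind S² = [cosθ₀(1+cosθ₀)/2]². The
  default per-frame step (15°) decorrelates frames within a few steps
  so 5×10⁴ frames pin the closed form to ±0.02. Emulated: bond-vector
  wobble amplitude. Not emulated: anisotropic motion, exchange between
  substates, global tumbling.
- **Correlated displacements**: Gaussian fields d = Lz along one
  laboratory axis on a curved 3-D Cα chain; Pearson structure exact by
  construction. Not emulated: 3-D anisotropic correlated motion,
  non-Gaussian dynamics.
- **Helix pairs / backbones**: ideal Cα helices (rise 1.5 Å,
  100°/residue, radius 2.3 Å) under a seeded random rigid placement;
  full backbones are built from internal coordinates (φ/ψ = −57°/−47°
  helical, −140°/135° extended) by natural-extension chain building.
  Not emulated: side chains, frayed-end heterogeneity beyond the
  prescribed torsion switches.
- **Coordination sites**: oxygens at prescribed mean distances with
  radial Gaussian jitter; carboxyl carbons placed beyond the oxygen
  midpoint. Not emulated: angular ligand rearrangement, water exchange.
- **Toy receptors**: single charged spheres whose collision surface
  coincides with the reaction surface (the textbook absorbing sphere),
  and a minimal acidic-site ring for desk-scale demonstrations.

Consequently, passing tests establish correctness of the estimators
and rate machinery against known ground truth; they do not establish
that any particular biological trajectory will show a given apo/holo or
mutant contrast — those contrasts (depressed site II S² in apo, tight
D67/E76 pairing in sensitized mutants, mean chelation distances in the
2.1–4.3 Å band, encounter rates of 10⁹–10¹⁰ M⁻¹s⁻¹ on real regulatory-
domain conformers) are expectations for user-supplied MD data,
documented here rather than asserted in CI. Experimental-structure
calibrations of the interhelical angle (≈140°/132° closed, ≤121°
TnI-bound) likewise require the corresponding PDB entries, which users
must supply.

## Problem sizes and determinism

The regression and acceptance suites run at desk scale on one CPU: cone
fixtures use 20 residues × 5×10⁴ frames; DCCM recovery 5×10³ frames;
clustering oracles exhaust instances of ≤8 frames; BD oracle suites use
10⁴ trajectories (analysis-level BD demonstrations use 2–4×10³). These
sizes put the statistical error comfortably inside each stated
tolerance; production analyses of real trajectories would typically use
the full 500 000-trajectory BD budget and whole-trajectory windows.
Fixed seeds make every pipeline run byte-identical; reports embed the
package version, a trajectory content hash and the configuration echo.

## Known limitations

- Debye–Hückel electrostatics (no dielectric boundary or field
  focusing); monopole surface rates.
- Rigid-receptor BD; flexibility only via cluster weighting.
- α-helix-only secondary structure; no 3₁₀/π or turn states.
- Pairwise-fit RMSD matrices are not metrics (documented).
- The iRED/direct-estimator equivalence holds on tumbling-free
  fixtures; with global tumbling only iRED separates internal motion.
- mmCIF, PSF/force-field topologies and solvent handling are out of
  scope; MD and ABF/PMF generation are upstream of this package.
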