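"""Synthetic structures and trajectories with known ground truth.

Every analysis stage in the package has a generator here whose output it
must recover: diffusion-in-a-cone bond vectors with a closed-form order
parameter, Cα displacement fields with a prescribed Pearson matrix, ideal
helix pairs at a prescribed interhelical angle, toy ion-coordination sites
with prescribed chelation distances, and charged-sphere receptors with
analytic association rates.  All generators take mandatory seeds and are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import Atom, Structure, Trajectory

__all__ = [
    "ConeSpec",
    "CorrSpec",
    "ToyReceptor",
    "cone_s2_closed_form",
    "gen_cone_vectors",
    "gen_cone_series",
    "gen_correlated_trajectory",
    "make_ca_reference",
    "gen_helix_pair",
    "ideal_helix_backbone",
    "gen_helix_content_trajectory",
    "gen_coordination_frames",
    "make_absorbing_sphere_receptor",
    "make_toy_site_receptor",
    "dispersed_axes",
]


# ---------------------------------------------------------------------------
# Diffusion in a cone: oracle for order parameters
# ---------------------------------------------------------------------------


@dataclass
class ConeSpec:
    """Wobble-in-a-cone random walk for one bond vector.

    theta0: cone semi-angle in degrees; step_sd: per-frame angular step
    (degrees) — large steps decorrelate frames quickly, which the order-
    parameter oracles rely on.
    """

    theta0: float
    n_frames: int
    step_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta0 <= 90.0:
            raise ValueError("theta0 must be in [0, 90] degrees")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def cone_s2_closed_form(theta0_deg: float) -> float:
    """Model-free S² for uniform diffusion in a cone of semi-angle θ₀:
    S² = [cosθ₀ (1 + cosθ₀) / 2]²."""
    c = np.cos(np.radians(theta0_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)


def _reflect_interval(x: np.ndarray | float, lo: float, hi: float):
    """Reflect values into [lo, hi] (billiard reflection, any overshoot)."""
    span = hi - lo
    if span <= 0:
        return np.clip(x, lo, hi)
    y = np.mod(np.asarray(x, dtype=float) - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def gen_cone_vectors(spec: ConeSpec, axis: np.ndarray | None = None) -> np.ndarray:
    """Unit vectors (n_frames, 3) wobbling uniformly in a cone about ``axis``.

    The walk runs in (cosθ, φ): a reflected Gaussian random walk on
    u = cosθ ∈ [cosθ₀, 1] has a uniform stationary density, which together
    with free diffusion in φ gives the uniform-on-cap distribution that the
    closed-form S² assumes.  θ₀ = 0 degenerates to a static vector.
    """
    rng = np.random.default_rng(spec.seed)
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    if spec.theta0 == 0.0:
        return np.tile(axis, (spec.n_frames, 1))

    u_lo = np.cos(np.radians(spec.theta0))
    step = np.radians(spec.step_sd)
    # scale the u-step so small angular steps near the axis map sensibly
    sigma_u = step * max(np.sin(np.radians(spec.theta0)), 1e-3)

    u = np.empty(spec.n_frames)
    phi = np.empty(spec.n_frames)
    u[0] = rng.uniform(u_lo, 1.0)
    phi[0] = rng.uniform(0.0, 2 * np.pi)
    du = rng.normal(0.0, sigma_u, size=spec.n_frames - 1)
    dphi = rng.normal(0.0, step / max(np.sin(np.radians(spec.theta0) / 2), 1e-3),
                      size=spec.n_frames - 1)
    for t in range(1, spec.n_frames):
        u[t] = _reflect_interval(u[t - 1] + du[t - 1], u_lo, 1.0)
        phi[t] = phi[t - 1] + dphi[t - 1]

    sin_t = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), u])
    # rotate local z onto the requested axis
    rot, _ = Rotation.align_vectors(axis[None, :], np.array([[0.0, 0.0, 1.0]]))
    return local @ rot.as_matrix().T


def dispersed_axes(n: int) -> np.ndarray:
    """n roughly evenly dispersed unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gen_cone_series(
    n_res: int, theta0: float, n_frames: int, seed: int, step_sd: float = 15.0
) -> tuple[list[int], np.ndarray]:
    """Independent cone walks for ``n_res`` residues about dispersed axes.

    Returns (residue ids, vectors of shape (n_frames, n_res, 3)); a fixture
    for the iRED / model-free order-parameter cross-validation.
    """
    axes = dispersed_axes(n_res)
    vecs = np.empty((n_frames, n_res, 3))
    for j in range(n_res):
        spec = ConeSpec(theta0, n_frames, step_sd=step_sd, seed=seed + 7919 * j)
        vecs[:, j, :] = gen_cone_vectors(spec, axis=axes[j])
    return list(range(1, n_res + 1)), vecs


# ---------------------------------------------------------------------------
# Correlated Cα displacements: oracle for DCCM
# ---------------------------------------------------------------------------


@dataclass
class CorrSpec:
    """Target Pearson matrix for Cα displacements along one lab axis."""

    target: np.ndarray
    scale: float = 0.3
    n_frames: int = 5000
    seed: int = 0
    axis: int = 0  # lab axis (0=x) carrying the correlated displacements

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        t = self.target
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("target must be square")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("target must be symmetric")
        if not np.allclose(np.diag(t), 1.0, atol=1e-12):
            raise ValueError("target must have unit diagonal")
        if np.linalg.eigvalsh(t).min() < -1e-10:
            raise ValueError("target matrix is not positive semi-definite")


def make_ca_reference(n_res: int, spacing: float = 3.8) -> Structure:
    """Coarse helical pseudo-chain of Cα atoms, one per residue.

    The chain winds through 3-D (a wide helix of ~3.8 Å Cα spacing) so
    rigid-body superposition is well-conditioned and cannot absorb the
    small per-residue displacements the correlated-trajectory generator
    plants on top of it.
    """
    radius = 6.0
    twist = np.radians(40.0)
    rise = np.sqrt(max(spacing**2 - (2 * radius * np.sin(twist / 2)) ** 2, 1.0))
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            residue_number=i + 1,
            residue_name="ALA",
            chain="A",
            coords=np.array(
                [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i]
            ),
        )
        for i in range(n_res)
    ]
    return Structure(atoms, title="ca-reference")


def gen_correlated_trajectory(reference: Structure, spec: CorrSpec) -> Trajectory:
    """Trajectory whose Cα displacements along one axis follow ``spec.target``.

    Gaussian displacements d = L z (L from an eigendecomposition of the
    target, robust to semi-definite targets) are applied along a single
    laboratory axis, so the sample Pearson matrix converges to the target
    as n_frames grows.  Every atom of residue i moves rigidly with its Cα.
    """
    resnums = reference.residue_numbers()
    n_res = len(resnums)
    if spec.target.shape[0] != n_res:
        raise ValueError(
            f"target dimension {spec.target.shape[0]} != {n_res} residues"
        )
    rng = np.random.default_rng(spec.seed)
    evals, evecs = np.linalg.eigh(spec.target)
    evals = np.clip(evals, 0.0, None)
    L = evecs * np.sqrt(evals)
    z = rng.standard_normal((spec.n_frames, n_res))
    disp = z @ L.T * spec.scale  # (n_frames, n_res)

    res_of_atom = np.array(
        [resnums.index(a.residue_number) for a in reference.atoms]
    )
    frames = np.tile(reference.coords, (spec.n_frames, 1, 1))
    frames[:, :, spec.axis] += disp[:, res_of_atom]
    return Trajectory(reference, frames, dt=6.0)


# ---------------------------------------------------------------------------
# Ideal helices: oracles for axis fitting and DSSP content
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å, Cα radius


def _helix_ca_coords(n_res: int, phase: float = 0.0) -> np.ndarray:
    """Cα positions of an ideal α-helix with its axis along +z."""
    i = np.arange(n_res)
    ang = np.radians(_HELIX_TWIST * i + phase)
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(ang), _HELIX_RADIUS * np.sin(ang), _HELIX_RISE * i]
    )


def gen_helix_pair(angle_deg: float, n_res_per_helix: int = 11, seed: int = 0) -> Structure:
    """Two ideal Cα helices whose N→C axes subtend ``angle_deg``.

    Helix A runs along +z; helix B is helix A rotated by the requested
    angle about x, displaced 15 Å along y to avoid overlap.  The whole
    assembly is then given a random rigid placement (seeded) so axis
    recovery cannot rely on lab-frame alignment.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle must be in [0, 180] degrees")
    if n_res_per_helix < 4:
        raise ValueError("need at least 4 residues per helix")
    rng = np.random.default_rng(seed)
    ca_a = _helix_ca_coords(n_res_per_helix)
    rot_b = Rotation.from_euler("x", angle_deg, degrees=True)
    ca_b = rot_b.apply(ca_a) + np.array([0.0, 15.0, 0.0])

    rigid = Rotation.random(rng=rng)
    shift = rng.uniform(-5, 5, size=3)
    ca_a = rigid.apply(ca_a) + shift
    ca_b = rigid.apply(ca_b) + shift

    atoms = []
    for i, c in enumerate(ca_a):
        atoms.append(Atom(i + 1, "CA", i + 1, "ALA", "A", c))
    for i, c in enumerate(ca_b):
        atoms.append(
            Atom(n_res_per_helix + i + 1, "CA", 100 + i + 1, "ALA", "B", c)
        )
    return Structure(atoms, title=f"helix-pair-{angle_deg:.0f}deg")


# NeRF internal-coordinate chain building for full-backbone fixtures
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_OMEGA = 180.0

_PHI_HELIX, _PSI_HELIX = -57.0, -47.0
_PHI_EXT, _PSI_EXT = -140.0, 135.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural extension reference frame placement of atom d bonded to c."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_helix_backbone(
    n_res: int,
    phi_psi: list[tuple[float, float]] | None = None,
    resnum_start: int = 1,
    chain: str = "A",
) -> Structure:
    """Full backbone (N, CA, C, O) chain built from φ/ψ internal coordinates.

    Default torsions are ideal α-helical (φ=−57°, ψ=−47°); pass per-residue
    (φ, ψ) pairs to fray or extend parts of the chain.  Used as the DSSP
    fixture generator.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    if phi_psi is None:
        phi_psi = [(_PHI_HELIX, _PSI_HELIX)] * n_res
    if len(phi_psi) != n_res:
        raise ValueError("phi_psi length must equal n_res")

    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi_i)
        backbone.append((n_i, ca_i, c_i))

    atoms: list[Atom] = []
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res = resnum_start + i
        # carbonyl O in the peptide plane, opposed to the next amide N
        if i + 1 < n_res:
            n_next = backbone[i + 1][0]
            d = -( (ca_i - c_i) / np.linalg.norm(ca_i - c_i)
                   + (n_next - c_i) / np.linalg.norm(n_next - c_i) )
        else:
            d = -(ca_i - c_i)
        o_i = c_i + _BOND_C_O * d / np.linalg.norm(d)
        for name, xyz in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)):
            atoms.append(Atom(serial, name, res, "ALA", chain, xyz))
            serial += 1
    return Structure(atoms, title="ideal-backbone")


def gen_helix_content_trajectory(
    n_res: int,
    helical_counts: list[int],
    seed: int = 0,
) -> Trajectory:
    """Frames with a prescribed number of leading helical residues each.

    Frame f keeps ``helical_counts[f]`` residues at α torsions and sets the
    remainder extended, so downstream helix-content bookkeeping has exact
    construction truth (up to DSSP's pattern-edge conventions).
    """
    frames = []
    topo = None
    for k in helical_counts:
        if not 0 <= k <= n_res:
            raise ValueError("helical count out of range")
        phi_psi = [(_PHI_HELIX, _PSI_HELIX)] * k + [(_PHI_EXT, _PSI_EXT)] * (n_res - k)
        s = ideal_helix_backbone(n_res, phi_psi)
        if topo is None:
            topo = s
        frames.append(s.coords)
    assert topo is not None
    return Trajectory(topo, np.array(frames), dt=6.0)


# ---------------------------------------------------------------------------
# Toy ion-coordination site: oracle for chelation metrics
# ---------------------------------------------------------------------------


def gen_coordination_frames(
    mean_dists: dict[tuple[int, str, str], float],
    jitter_sd: float,
    n_frames: int,
    seed: int,
    ion_name: str = "CAL",
) -> Trajectory:
    """Toy binding site: an ion at the origin plus oxygens at set distances.

    ``mean_dists`` maps (residue_number, residue_name, atom_name) to the
    mean ion–oxygen distance in Å; per-frame radial Gaussian jitter of
    ``jitter_sd`` is applied independently per atom.  Asp/Glu residues also
    get their carboxyl carbon (CG/CD) placed 1.3 Å beyond the oxygen
    midpoint so carboxyl-pairing distances are measurable.
    """
    for key, d in mean_dists.items():
        if d <= 0:
            raise ValueError(f"mean distance for {key} must be positive")
    rng = np.random.default_rng(seed)
    keys = sorted(mean_dists)
    dirs = dispersed_axes(max(len(keys), 2))[: len(keys)]

    atoms = [Atom(1, "CA", 999, ion_name, "X", np.zeros(3))]
    serial = 2
    oxy_rows = []
    for k, (key, u) in enumerate(zip(keys, dirs)):
        resnum, resname, aname = key
        pos = mean_dists[key] * u
        atoms.append(Atom(serial, aname, resnum, resname, "A", pos))
        oxy_rows.append((len(atoms) - 1, mean_dists[key], u))
        serial += 1
    # carboxyl carbons for Asp/Glu residues present
    carbox: dict[int, list[int]] = {}
    for idx, a in enumerate(atoms):
        if a.residue_name in ("ASP", "GLU") and a.name.startswith(("OD", "OE")):
            carbox.setdefault(a.residue_number, []).append(idx)
    for resnum, oidx in sorted(carbox.items()):
        resname = atoms[oidx[0]].residue_name
        cname = "CG" if resname == "ASP" else "CD"
        mid = np.mean([atoms[i].coords for i in oidx], axis=0)
        nrm = np.linalg.norm(mid)
        u = mid / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        atoms.append(Atom(serial, cname, resnum, resname, "A", mid + 1.3 * u))
        serial += 1

    topo = Structure(atoms, title="toy-coordination-site")
    base = topo.coords
    frames = np.tile(base, (n_frames, 1, 1))
    for atom_idx, mean_d, u in oxy_rows:
        radii = mean_d + rng.normal(0.0, jitter_sd, size=n_frames)
        frames[:, atom_idx, :] = radii[:, None] * u[None, :]
    return Trajectory(topo, frames, dt=6.0)


# ---------------------------------------------------------------------------
# Toy receptors: oracles for Brownian-dynamics rates
# ---------------------------------------------------------------------------


@dataclass
class ToyReceptor:
    """Charged-sphere receptor with analytic association-rate limits."""

    radius: float
    net_charge: float = 0.0
    diffusion: float = 0.079  # ligand D, Å²/ps (aqueous Ca²⁺)
    reaction_radius: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.reaction_radius is None:
            self.reaction_radius = self.radius


def make_absorbing_sphere_receptor(
    spec: ToyReceptor, ligand_radius: float = 1.14
) -> Structure:
    """Single-atom receptor whose collision surface coincides with the
    reaction surface, realising the textbook absorbing sphere.

    The atom's hard-sphere radius is set to reaction_radius − ligand_radius
    so the ligand reacts exactly when it would touch; a phantom atom at the
    centre carries the reaction criterion.
    """
    hard = max(spec.reaction_radius - ligand_radius, 0.0)
    atoms = [
        Atom(1, "SPH", 1, "TOY", "R", np.zeros(3), charge=spec.net_charge, radius=hard),
        Atom(2, "PHA", 2, "PHA", "R", np.zeros(3), charge=0.0, radius=-1.14, phantom=True),
    ]
    return Structure(atoms, title="toy-absorbing-sphere")


def make_toy_site_receptor(
    n_oxygens: int = 4,
    site_radius: float = 2.8,
    oxygen_charge: float = -1.0,
    seed: int = 0,
) -> Structure:
    """A minimal EF-hand-like site: a ring of carboxylate-oxygen charges.

    Oxygens of charge ``oxygen_charge`` sit on a ring of ``site_radius``
    around the expected ion position (the origin), where a phantom atom
    marks the reaction criterion.  Used for desk-scale demonstrations that
    an acidic site drives k_D into the diffusion-enhanced 1e9–1e10 1/(M s)
    range.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_oxygens):
        ang = 2 * np.pi * i / n_oxygens
        pos = site_radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        pos += rng.normal(0, 0.05, size=3)
        atoms.append(
            Atom(i + 1, "OD1", i + 1, "ASP", "A", pos, charge=oxygen_charge, radius=1.5)
        )
    atoms.append(
        Atom(
            n_oxygens + 1, "PHA", 900, "PHA", "X", np.zeros(3),
            charge=0.0, radius=-1.14, phantom=True,
        )
    )
    return Structure(atoms, title="toy-efhand-site")
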