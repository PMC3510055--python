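"""Dynamic cross-correlation maps of Cα displacements.

After rigid-body superposition onto the mean structure, the DCCM entry
for residues i, j is the Pearson correlation of their displacement
vectors,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),

with Δr the deviation from the mean position.  Region-pair blocks are
summarised with a signed three-way classification (+ / − / 0) against a
configurable threshold, mirroring how correlated helix motions are
tabulated for troponin-C mutants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import RegionMap, Structure, Trajectory, select

__all__ = [
    "CorrelationMatrix",
    "BlockSummary",
    "kabsch_fit",
    "superpose",
    "dccm",
    "block_summary",
    "DEFAULT_REGION_PAIRS",
]

# region pairs tracked in the mutant-comparison summary (helix-helix and
# loop/sheet couplings implicated in Ca2+ and TnI binding)
DEFAULT_REGION_PAIRS: list[tuple[str, str]] = [
    ("HA", "HB"),
    ("HA", "HD"),
    ("HB", "HC"),
    ("HB", "HD"),
    ("HN", "HD"),
    ("HC", "HD"),
    ("loop_I", "loop_II"),
    ("beta1", "beta2"),
]


@dataclass
class CorrelationMatrix:
    residue_ids: list[int]
    matrix: np.ndarray
    undefined: list[int] | None = None  # residues with zero displacement variance

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residue_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match residue count")

    def to_table(self) -> str:
        """Dense tab-separated text with residue-id headers."""
        header = "residue\t" + "\t".join(str(r) for r in self.residue_ids)
        lines = [header]
        for r, row in zip(self.residue_ids, self.matrix):
            lines.append(str(r) + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class BlockSummary:
    """Mean correlation and sign class per region pair."""

    blocks: dict[tuple[str, str], dict]
    threshold: float

    def sign(self, pair: tuple[str, str]) -> str:
        return self.blocks[pair]["sign"]


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the post-fit RMSD.  Collinear
    (degenerate) point sets are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need matching coordinate sets of at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m0 = mobile - mc
    sv = np.linalg.svd(m0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) selection; fit is ill-posed")
    rot, _ = Rotation.align_vectors(reference - rc, m0)
    fitted = rot.apply(m0) + rc
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return fitted, rmsd


def _fit_frames(
    frames: np.ndarray, sel: np.ndarray, ref_sel: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ref (selection-based fit, applied to all atoms)."""
    out = np.empty_like(frames)
    rc = ref_sel.mean(axis=0)
    for f in range(frames.shape[0]):
        mob = frames[f, sel]
        mc = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sel - rc, mob - mc)
        out[f] = rot.apply(frames[f] - mc) + rc
    return out


def superpose(traj: Trajectory, selection: str = "name CA") -> Trajectory:
    """Least-squares rigid superposition of every frame, two-pass.

    Frames are first fitted to the initial frame on the selection, the
    mean structure of that pass becomes the reference, and all frames are
    refitted to it — the standard convention when no external reference is
    given.
    """
    sel = np.array(select(traj, selection))
    if sel.size < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    ref = traj.frames[0, sel]
    sv = np.linalg.svd(ref - ref.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) alignment selection")
    pass1 = _fit_frames(traj.frames, sel, ref)
    mean_ref = pass1[:, sel].mean(axis=0)
    aligned = _fit_frames(traj.frames, sel, mean_ref)
    return Trajectory(traj.topology, aligned, dt=traj.dt)


def dccm(traj: Trajectory, ca_selection: str = "name CA") -> CorrelationMatrix:
    """Dynamic cross-correlation map over the Cα selection of an aligned
    trajectory.

    Residues whose displacement variance vanishes have undefined
    correlations; their rows/columns are NaN (diagonal kept at 1) and they
    are listed in ``undefined``.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for a meaningful DCCM")
    sel = np.array(select(traj, ca_selection))
    if sel.size == 0:
        raise ValueError("empty Cα selection")
    resids = [traj.topology.atoms[i].residue_number for i in sel]
    x = traj.frames[:, sel, :]  # (F, R, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", dx, dx) / traj.n_frames
    var = np.diag(cov).copy()
    zero = var <= 1e-24
    denom = np.sqrt(np.outer(np.where(zero, np.nan, var), np.where(zero, np.nan, var)))
    with np.errstate(invalid="ignore"):
        c = cov / denom
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    undefined = [resids[i] for i in np.nonzero(zero)[0]]
    if undefined:
        warnings.warn(
            f"zero-variance residues with undefined correlations: {undefined}",
            stacklevel=2,
        )
    return CorrelationMatrix(resids, c, undefined=undefined or None)


def block_summary(
    corr: CorrelationMatrix,
    region_map: RegionMap | None = None,
    threshold: float = 0.2,
    pairs: list[tuple[str, str]] | None = None,
) -> BlockSummary:
    """Mean correlation and sign class for each region pair.

    sign = '+' if the block mean is ≥ threshold, '−' if ≤ −threshold,
    otherwise '0' (boundary values take the signed class).
    """
    region_map = region_map or RegionMap()
    pairs = pairs if pairs is not None else list(DEFAULT_REGION_PAIRS)
    pos = {r: i for i, r in enumerate(corr.residue_ids)}
    blocks: dict[tuple[str, str], dict] = {}
    for a, b in pairs:
        ia = [pos[r] for r in region_map.residues(a) if r in pos]
        ib = [pos[r] for r in region_map.residues(b) if r in pos]
        if not ia or not ib:
            raise ValueError(f"region pair ({a}, {b}) unresolvable in matrix")
        sub = corr.matrix[np.ix_(ia, ib)]
        mean = float(np.nanmean(sub))
        if mean >= threshold:
            sign = "+"
        elif mean <= -threshold:
            sign = "-"
        else:
            sign = "0"
        blocks[(a, b)] = {"mean": mean, "sign": sign}
    return BlockSummary(blocks, threshold)
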