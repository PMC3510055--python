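"""Backbone amide order parameters via iRED eigenmode analysis.

The isotropic reorientational eigenmode dynamics (iRED) method builds the
matrix M of isotropically averaged second-Legendre inner products of the
N–H bond unit vectors, M_ij = <P2(u_i · u_j)>, and separates overall
reorientation (the five largest eigenmodes) from internal motion: the
generalized order parameter of residue j is the share of M_jj = 1 carried
by the five global modes,

    S²_j = 1 − Σ_{m≥6} λ_m |<j|m>|²  (eigenvalues sorted descending).

A direct model-free estimator (no eigenmodes) is provided as an
independent oracle.  Profiles are averaged over non-overlapping time
windows (0.5 ns by default, the standard choice that separates internal
motion from slow drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Structure, Trajectory, reconstruct_amide_hydrogens

__all__ = [
    "VectorSeries",
    "OrderParameterProfile",
    "nh_vectors",
    "ired_matrix",
    "ired_s2",
    "windowed_s2",
    "s2_direct",
]


@dataclass
class VectorSeries:
    """Per-frame unit vectors for a set of residues."""

    residue_ids: list[int]
    vectors: np.ndarray  # (n_frames, n_res, 3)
    dt: float = 6.0
    excluded: list[int] | None = None  # prolines / termini left out

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_frames, n_res, 3)")
        if self.vectors.shape[1] != len(self.residue_ids):
            raise ValueError("residue id count must match vector count")
        norms = np.linalg.norm(self.vectors, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("vectors must be unit norm (tolerance 1e-6)")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_res(self) -> int:
        return self.vectors.shape[1]


@dataclass
class OrderParameterProfile:
    """Windowed-average S² per residue with across-window standard error."""

    residue_ids: list[int]
    s2: np.ndarray
    stderr: np.ndarray
    window_ps: float
    n_windows: int

    def to_table(self) -> str:
        """Tab-separated text: residue, S², stderr."""
        lines = ["residue\tS2\tstderr"]
        for r, s, e in zip(self.residue_ids, self.s2, self.stderr):
            lines.append(f"{r}\t{s:.4f}\t{e:.4f}")
        return "\n".join(lines) + "\n"


def nh_vectors(traj: Trajectory) -> VectorSeries:
    """Backbone N–H unit-vector series from a trajectory.

    Amide hydrogens are taken from the topology when present (names H or
    HN) and otherwise reconstructed geometrically each frame.  Prolines
    and chain-leading residues (no preceding carbonyl) are excluded and
    listed in ``excluded``.
    """
    topo = traj.topology
    by_res: dict[int, dict[str, int]] = {}
    for i, a in enumerate(topo.atoms):
        by_res.setdefault(a.residue_number, {})[a.name] = i
    resname = {a.residue_number: a.residue_name for a in topo.atoms}
    all_res = sorted(by_res)
    if not any("N" in by_res[r] for r in all_res):
        raise ValueError("topology has no backbone N atoms")

    eligible: list[int] = []
    excluded: list[int] = []
    h_index: dict[int, int | None] = {}
    for r in all_res:
        names = by_res[r]
        if resname[r] == "PRO" or "N" not in names:
            excluded.append(r)
            continue
        if "H" in names or "HN" in names:
            h_index[r] = names.get("H", names.get("HN"))
            eligible.append(r)
        elif "CA" in names and "C" in by_res.get(r - 1, {}):
            h_index[r] = None  # reconstruct per frame
            eligible.append(r)
        else:
            excluded.append(r)
    if not eligible:
        raise ValueError("no residues with resolvable N–H vectors")

    n_idx = np.array([by_res[r]["N"] for r in eligible])
    vecs = np.empty((traj.n_frames, len(eligible), 3))
    needs_rebuild = [r for r in eligible if h_index[r] is None]
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        rebuilt = (
            reconstruct_amide_hydrogens(coords, topo) if needs_rebuild else {}
        )
        for j, r in enumerate(eligible):
            h = coords[h_index[r]] if h_index[r] is not None else rebuilt[r]
            v = h - coords[n_idx[j]]
            vecs[f, j] = v / np.linalg.norm(v)
    return VectorSeries(eligible, vecs, dt=traj.dt, excluded=excluded)


def ired_matrix(vectors: np.ndarray) -> np.ndarray:
    """iRED covariance matrix M_ij = <P2(u_i · u_j)> over frames.

    ``vectors`` is (n_frames, n_res, 3) of unit vectors; needs ≥ 2 frames.
    The diagonal is exactly 1 and M is symmetric by construction.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3 or vectors.shape[0] < 2:
        raise ValueError("need (n_frames, n_res, 3) with at least 2 frames")
    # per-frame Gram matrices, averaged: <(u_i·u_j)^2>
    dots_sq = np.einsum("fia,fja->fij", vectors, vectors) ** 2
    m = (3.0 * dots_sq.mean(axis=0) - 1.0) / 2.0
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def ired_s2(m: np.ndarray, n_global: int = 5) -> np.ndarray:
    """Per-residue S² from an iRED matrix.

    The ``n_global`` largest eigenmodes (ties broken by descending
    eigenvalue then ascending index) represent overall reorientation; the
    rest are internal and deplete S².  Requires more residues than global
    modes.  Completeness Σ_m λ_m <j|m>² = M_jj = 1 guarantees S² ∈ [0, 1]
    up to round-off, which is clipped.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if n <= n_global:
        raise ValueError(
            f"need more than {n_global} residues for iRED (got {n})"
        )
    evals, evecs = np.linalg.eigh(m)  # ascending
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    internal = np.arange(n_global, n)
    s2 = 1.0 - np.einsum("m,jm->j", evals[internal], evecs[:, internal] ** 2)
    return np.clip(s2, 0.0, 1.0)


def s2_direct(vectors: np.ndarray) -> np.ndarray:
    """Model-free generalized order parameter, no eigenmodes (oracle):

        S² = (3 Σ_{αβ} <u_α u_β>² − 1) / 2

    computed per residue from the time-averaged second-moment tensor.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3 or vectors.shape[0] < 2:
        raise ValueError("need (n_frames, n_res, 3) with at least 2 frames")
    second = np.einsum("fja,fjb->jab", vectors, vectors) / vectors.shape[0]
    s2 = (3.0 * np.einsum("jab,jab->j", second, second) - 1.0) / 2.0
    return np.clip(s2, 0.0, 1.0)


def windowed_s2(
    series: VectorSeries, window_ps: float = 500.0, n_global: int = 5
) -> OrderParameterProfile:
    """iRED S² averaged over non-overlapping windows of ``window_ps``.

    Frames beyond the last full window are dropped.  The across-window
    standard error is reported per residue (zero when only one window
    fits).
    """
    frames_per_window = int(window_ps / series.dt)
    if frames_per_window < 2:
        raise ValueError("window shorter than two frames")
    n_windows = series.n_frames // frames_per_window
    if n_windows < 1:
        raise ValueError(
            f"trajectory ({series.n_frames} frames) shorter than one "
            f"{window_ps} ps window ({frames_per_window} frames)"
        )
    per_window = np.empty((n_windows, series.n_res))
    for w in range(n_windows):
        chunk = series.vectors[w * frames_per_window : (w + 1) * frames_per_window]
        per_window[w] = ired_s2(ired_matrix(chunk), n_global=n_global)
    s2 = per_window.mean(axis=0)
    stderr = (
        per_window.std(axis=0, ddof=1) / np.sqrt(n_windows)
        if n_windows > 1
        else np.zeros(series.n_res)
    )
    return OrderParameterProfile(
        list(series.residue_ids), s2, stderr, window_ps, n_windows
    )
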