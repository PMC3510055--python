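"""Superposition, DCCM recovery and region-pair sign summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from efdyn.correlations import (
    DEFAULT_REGION_PAIRS,
    block_summary,
    dccm,
    kabsch_fit,
    superpose,
)
from efdyn.model_io import Atom, RegionMap, Structure, Trajectory
from efdyn.synthetic import CorrSpec, gen_correlated_trajectory, make_ca_reference


def rigid_copies(base: np.ndarray, n: int, seed: int, translate=True, rotate=True):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        f = base.copy()
        if rotate:
            f = Rotation.random(rng=rng).apply(f)
        if translate:
            f = f + rng.uniform(-10, 10, 3)
        frames.append(f)
    return np.array(frames)


class TestSuperpose:
    def make_traj(self, n_frames=12, translate=True, rotate=True, seed=0):
        ref = make_ca_reference(10)
        frames = rigid_copies(ref.coords, n_frames, seed, translate, rotate)
        return Trajectory(ref, frames, dt=6.0), ref

    def test_translated_copies_align_exactly(self):
        traj, ref = self.make_traj(rotate=False)
        aligned = superpose(traj)
        spread = aligned.frames - aligned.frames.mean(axis=0)
        assert np.abs(spread).max() <= 1e-6

    def test_rotated_copies_align_exactly(self):
        traj, ref = self.make_traj(translate=False)
        aligned = superpose(traj)
        spread = aligned.frames - aligned.frames.mean(axis=0)
        assert np.abs(spread).max() <= 1e-6

    def test_alignment_never_increases_rmsd(self):
        ref = make_ca_reference(8)
        rng = np.random.default_rng(4)
        frames = rigid_copies(ref.coords, 10, 5) + rng.normal(0, 0.3, (10, 8, 3))
        traj = Trajectory(ref, frames, dt=6.0)
        aligned = superpose(traj)
        mean_ref = aligned.frames.mean(axis=0)
        for f in range(traj.n_frames):
            before = np.sqrt(((traj.frames[f] - mean_ref) ** 2).sum(1).mean())
            after = np.sqrt(((aligned.frames[f] - mean_ref) ** 2).sum(1).mean())
            assert after <= before + 1e-9

    def test_collinear_selection_rejected(self):
        atoms = [
            Atom(i + 1, "CA", i + 1, "ALA", "A", np.array([0.0, 3.8 * i, 0.0]))
            for i in range(5)
        ]
        line = Structure(atoms)
        traj = Trajectory(line, np.tile(line.coords, (5, 1, 1)), dt=6.0)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(traj)

    def test_kabsch_single_atom_perturbation_closed_form(self):
        """4-atom tetrahedron, one atom displaced by d along its centroid ray:
        optimal-fit RMSD has the closed form d·sqrt(3)/(2·sqrt(n)) when the
        displacement is radial through the centroid (translation absorbs
        d/n, rotation nothing)."""
        base = np.array(
            [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
        )
        d = 1.0
        moved = base.copy()
        moved[0] += d * base[0] / np.linalg.norm(base[0])
        fitted, rmsd = kabsch_fit(moved, base)
        # oracle: brute-force optimisation over rigid transforms
        from scipy.optimize import minimize

        def loss(p):
            rot = Rotation.from_rotvec(p[:3])
            return ((rot.apply(moved) + p[3:] - base) ** 2).sum()

        best = min(
            minimize(loss, np.concatenate([rv, tv])).fun
            for rv in (np.zeros(3), np.array([0.1, 0, 0]))
            for tv in (np.zeros(3), np.array([0, 0.1, 0]))
        )
        assert rmsd == pytest.approx(np.sqrt(best / 4), abs=1e-6)


class TestDCCM:
    def test_self_correlation_is_one(self):
        traj = gen_correlated_trajectory(
            make_ca_reference(4), CorrSpec(np.eye(4), n_frames=200, seed=1)
        )
        c = dccm(traj)
        assert np.allclose(np.diag(c.matrix), 1.0)

    def test_mirrored_displacements_fully_anticorrelated(self):
        t = np.array([[1.0, -1.0], [-1.0, 1.0]])
        traj = gen_correlated_trajectory(
            make_ca_reference(2), CorrSpec(t, n_frames=500, seed=2)
        )
        c = dccm(traj)
        assert c.matrix[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_planted_half_correlation_recovered(self):
        t = np.eye(5)
        t[1, 3] = t[3, 1] = 0.5
        traj = gen_correlated_trajectory(
            make_ca_reference(5), CorrSpec(t, n_frames=5000, seed=3)
        )
        c = dccm(traj)
        assert c.matrix[1, 3] == pytest.approx(0.5, abs=0.05)

    def test_full_matrix_recovery_bound(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((8, 8))
        cov = a @ a.T + 8 * np.eye(8)
        d = np.sqrt(np.diag(cov))
        t = cov / np.outer(d, d)
        n = 5000
        traj = gen_correlated_trajectory(
            make_ca_reference(8), CorrSpec(t, n_frames=n, seed=5)
        )
        c = dccm(traj)
        assert np.abs(c.matrix - t).max() <= 3 / np.sqrt(n) + 0.02

    def test_rigid_body_motion_invariance_after_superpose(self):
        t = np.eye(6)
        t[0, 1] = t[1, 0] = 0.5
        traj = gen_correlated_trajectory(
            make_ca_reference(6), CorrSpec(t, n_frames=300, seed=6)
        )
        rng = np.random.default_rng(7)
        moved = np.array(
            [Rotation.random(rng=rng).apply(f) + rng.uniform(-20, 20, 3) for f in traj.frames]
        )
        c1 = dccm(superpose(traj)).matrix
        c2 = dccm(superpose(Trajectory(traj.topology, moved, dt=6.0))).matrix
        assert np.abs(c1 - c2).max() <= 1e-3

    def test_zero_variance_residue_flagged(self):
        ref = make_ca_reference(4)
        rng = np.random.default_rng(8)
        frames = np.tile(ref.coords, (50, 1, 1))
        frames[:, :2, 0] += rng.standard_normal((50, 2))  # residues 3,4 frozen
        traj = Trajectory(ref, frames, dt=6.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            c = dccm(traj)
        assert c.undefined == [3, 4]
        assert np.isnan(c.matrix[0, 2])

    def test_too_few_frames_rejected(self):
        traj = gen_correlated_trajectory(
            make_ca_reference(3), CorrSpec(np.eye(3), n_frames=5, seed=9)
        )
        with pytest.raises(ValueError, match="10 frames"):
            dccm(traj)


class TestBlockSummary:
    @staticmethod
    def region_map_small():
        return RegionMap(regions={"R1": (1, 3), "R2": (4, 6)})

    def build_corr(self, block_value: float):
        # block value must keep the 6x6 two-group matrix PSD (|v| ≤ 1/3)
        n = 6
        t = np.eye(n)
        for i in range(3):
            for j in range(3, 6):
                t[i, j] = t[j, i] = block_value
        traj = gen_correlated_trajectory(
            make_ca_reference(n), CorrSpec(t, n_frames=4000, seed=10)
        )
        return dccm(traj)

    def test_identity_fixture_all_zero_class(self):
        c = self.build_corr(0.0)
        s = block_summary(c, self.region_map_small(), pairs=[("R1", "R2")])
        assert s.sign(("R1", "R2")) == "0"

    def test_planted_positive_block_classed_positive(self):
        c = self.build_corr(0.3)
        s = block_summary(c, self.region_map_small(), pairs=[("R1", "R2")])
        assert s.sign(("R1", "R2")) == "+"
        assert s.blocks[("R1", "R2")]["mean"] == pytest.approx(0.3, abs=0.05)

    def test_boundary_value_takes_signed_class(self):
        from efdyn.correlations import BlockSummary, CorrelationMatrix

        c = CorrelationMatrix(
            list(range(1, 7)),
            np.where(np.eye(6, dtype=bool), 1.0, 0.2),
        )
        s = block_summary(c, self.region_map_small(), threshold=0.2, pairs=[("R1", "R2")])
        assert s.sign(("R1", "R2")) == "+"

    def test_unresolvable_region_errors(self):
        c = self.build_corr(0.0)
        with pytest.raises((KeyError, ValueError)):
            block_summary(c, RegionMap(), pairs=[("HA", "HB")])

    def test_default_pairs_cover_helix_couplings(self):
        assert ("HA", "HB") in DEFAULT_REGION_PAIRS
        assert ("beta1", "beta2") in DEFAULT_REGION_PAIRS
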