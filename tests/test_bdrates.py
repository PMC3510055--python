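"""Brownian-dynamics rate machinery: fields, surface rates, NAM, Kramers."""

from __future__ import annotations

import numpy as np
import pytest

from efdyn.bdrates import (
    BDConfig,
    COULOMB_KCAL,
    DebyeHuckelField,
    KB_KCAL,
    PMFProfile,
    RateEstimate,
    analytic_surface_rate,
    bd_propagate,
    debye_kappa,
    dh_potential,
    estimate_rate,
    kramers_attenuation,
    nam_rate,
    pmf_barrier,
    weighted_rate,
)
from efdyn.model_io import Atom, Structure
from efdyn.synthetic import ToyReceptor, make_absorbing_sphere_receptor

RATE_CONV = 6.02214076e8  # Å³/ps -> 1/(M s)


def point_receptor(charge: float) -> Structure:
    atoms = [
        Atom(1, "PT", 1, "TOY", "R", np.zeros(3), charge=charge, radius=1.0),
        Atom(2, "PHA", 2, "PHA", "R", np.zeros(3), charge=0.0, radius=-1.14, phantom=True),
    ]
    return Structure(atoms)


class TestDebyeHuckel:
    def test_unscreened_single_charge_is_coulomb(self):
        field = dh_potential(point_receptor(-1.0), ionic_strength=0.0, ligand_charge=2.0)
        u = field.potential(np.array([10.0, 0.0, 0.0]))
        assert u == pytest.approx(-1.0 * 2.0 * COULOMB_KCAL / (78.0 * 10.0))

    def test_screening_multiplies_exponential_factor(self):
        r = 10.0
        f0 = dh_potential(point_receptor(-1.0), ionic_strength=0.0)
        f1 = dh_potential(point_receptor(-1.0), ionic_strength=0.15)
        kappa = debye_kappa(0.15, 310.0)
        x = np.array([r, 0.0, 0.0])
        assert f1.potential(x) == pytest.approx(f0.potential(x) * np.exp(-kappa * r))

    def test_neutral_receptor_zero_potential(self):
        field = dh_potential(point_receptor(0.0))
        assert field.potential(np.array([5.0, 5.0, 5.0])) == pytest.approx(0.0)

    def test_missing_charges_rejected(self):
        s = Structure([Atom(1, "X", 1, "Y", "A", np.zeros(3))])
        with pytest.raises(ValueError, match="charges"):
            dh_potential(s)

    def test_force_is_negative_gradient(self):
        field = dh_potential(point_receptor(-2.0), ionic_strength=0.15)
        x = np.array([4.0, 3.0, 1.0])
        eps = 1e-5
        num = np.array(
            [
                (field.potential(x + eps * e) - field.potential(x - eps * e)) / (2 * eps)
                for e in np.eye(3)
            ]
        )
        assert np.allclose(field.force(x), -num, atol=1e-6)

    def test_debye_length_at_physiological_salt(self):
        # ~8 Å at 150 mM, 310 K, ε=78
        assert 1.0 / debye_kappa(0.15, 310.0) == pytest.approx(8.0, abs=0.4)


class TestAnalyticSurfaceRate:
    def test_zero_potential_is_smoluchowski(self):
        d, r = 0.079, 50.0
        k = analytic_surface_rate(d, r)
        assert k == pytest.approx(4 * np.pi * d * r * RATE_CONV, rel=1e-12)
        assert k == pytest.approx(3.0e10, rel=0.01)

    def test_attraction_exceeds_smoluchowski(self):
        u = lambda r: -50.0 / r
        k = analytic_surface_rate(0.079, 20.0, u)
        assert k > analytic_surface_rate(0.079, 20.0)

    def test_tall_repulsive_barrier_kills_rate(self):
        u = lambda r: 50.0 if r < 30 else 0.0
        k = analytic_surface_rate(0.079, 20.0, u)
        assert k < 1e-10 * analytic_surface_rate(0.079, 20.0)

    def test_coulomb_matches_debye_closed_form(self):
        a, kT = 10.0, KB_KCAL * 310.0
        pref = -8.0 * COULOMB_KCAL / 78.0  # q1 q2 = -4 * +2
        L = -pref / kT  # Onsager length, attraction
        r_eff = L / (1 - np.exp(-L / a))
        k = analytic_surface_rate(0.079, a, lambda r: pref / r)
        assert k == pytest.approx(4 * np.pi * 0.079 * r_eff * RATE_CONV, rel=1e-6)


class TestNamArithmetic:
    def test_beta_one_returns_kb(self):
        assert nam_rate(2e9, 4e9, 1.0) == pytest.approx(2e9)

    def test_beta_zero_returns_zero(self):
        assert nam_rate(2e9, 4e9, 0.0) == 0.0

    def test_reference_arithmetic(self):
        assert nam_rate(1e10, 2e10, 0.2) == pytest.approx(1e10 * 0.2 / (1 - 0.8 * 0.5))
        assert nam_rate(1e10, 2e10, 0.2) == pytest.approx(3.33e9, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nam_rate(1e10, 5e9, 0.5)  # k_q < k_b
        with pytest.raises(ValueError):
            nam_rate(1e10, 2e10, 1.5)


class TestBDPropagation:
    def test_reaction_distance_at_b_reacts_instantly(self):
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=5.0))
        cfg = BDConfig(
            ionic_strength=0.0, b_radius=20.0, q_radius=80.0,
            n_trajectories=100, seed=1, reaction_distance=20.0,
        )
        res = bd_propagate(rec, cfg)
        assert res.beta == 1.0

    def test_seed_reproducibility(self):
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=10.0))
        cfg = BDConfig(
            ionic_strength=0.0, b_radius=30.0, q_radius=120.0,
            n_trajectories=500, seed=11, reaction_distance=10.0,
        )
        assert bd_propagate(rec, cfg).beta == bd_propagate(rec, cfg).beta

    def test_neutral_sphere_beta_matches_free_diffusion_theory(self):
        """Hitting probability from b before q for free diffusion:
        β = (1/b − 1/q)/(1/a − 1/q)."""
        a, b, q = 10.0, 30.0, 120.0
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=a))
        cfg = BDConfig(
            ionic_strength=0.0, b_radius=b, q_radius=q,
            n_trajectories=3000, seed=2, reaction_distance=a,
        )
        res = bd_propagate(rec, cfg)
        beta_exact = (1 / b - 1 / q) / (1 / a - 1 / q)
        assert res.beta == pytest.approx(beta_exact, abs=0.025)
        assert res.beta_ci[0] <= beta_exact <= res.beta_ci[1] + 0.02

    def test_nam_combined_rate_matches_smoluchowski(self):
        a = 10.0
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=a))
        cfg = BDConfig(
            ionic_strength=0.0, b_radius=30.0, q_radius=120.0,
            n_trajectories=4000, seed=3, reaction_distance=a,
        )
        est = estimate_rate(rec, cfg)
        k_smol = analytic_surface_rate(cfg.diffusion, a)
        assert est.k == pytest.approx(k_smol, rel=0.08)

    def test_charged_sphere_exceeds_neutral_and_matches_debye(self):
        a, kT = 10.0, KB_KCAL * 310.0
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=a, net_charge=-4.0))
        cfg = BDConfig(
            ionic_strength=0.0, b_radius=30.0, q_radius=120.0,
            n_trajectories=3000, seed=4, reaction_distance=a,
        )
        est = estimate_rate(rec, cfg)
        pref = -4.0 * 2.0 * COULOMB_KCAL / 78.0
        L = -pref / kT
        k_debye = 4 * np.pi * 0.079 * L / (1 - np.exp(-L / a)) * RATE_CONV
        assert est.k > analytic_surface_rate(0.079, a)
        assert est.k == pytest.approx(k_debye, rel=0.10)

    def test_missing_phantom_rejected(self):
        s = Structure([Atom(1, "PT", 1, "TOY", "R", np.zeros(3), charge=0.0, radius=2.0)])
        with pytest.raises(ValueError, match="phantom"):
            bd_propagate(s, BDConfig(n_trajectories=10, seed=0))

    def test_b_inside_receptor_rejected(self):
        rec = make_absorbing_sphere_receptor(ToyReceptor(radius=10.0))
        cfg = BDConfig(b_radius=5.0, q_radius=40.0, n_trajectories=10, seed=0,
                       reaction_distance=2.0)
        with pytest.raises(ValueError, match="b-sphere"):
            bd_propagate(rec, cfg)


class TestWeightedRate:
    @staticmethod
    def est(k, beta=0.5, kb=1e11):
        return RateEstimate(k=k, beta=beta, beta_ci=(beta, beta), k_b=kb, k_q=2e11,
                            k_ci=(k, k))

    def test_single_cluster_unchanged(self):
        e = self.est(3e9)
        w = weighted_rate([e], [1.0])
        assert w.k == e.k and w.provenance == "weighted"

    def test_equal_rates_preserved(self):
        w = weighted_rate([self.est(5e9), self.est(5e9)], [0.4, 0.6])
        assert w.k == pytest.approx(5e9)

    def test_reference_arithmetic(self):
        w = weighted_rate([self.est(2e9), self.est(6e9)], [0.75, 0.25])
        assert w.k == pytest.approx(3e9)

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            weighted_rate([self.est(1e9), self.est(2e9)], [0.5, 0.6])


class TestPMFBarrier:
    @staticmethod
    def planted_profile(height=3.0, pos=4.0, noise=0.0, seed=0):
        r = np.arange(2.0, 12.01, 0.1)
        g = np.where(r < pos, -2.0 * (1 - (r - 2.0) / (pos - 2.0)), 0.0)
        g = g + height * np.exp(-((r - pos) ** 2) / 0.18)
        if noise:
            g = g + np.random.default_rng(seed).normal(0, noise, r.shape)
        return PMFProfile(r, g)

    def test_planted_barrier_recovered_exactly(self):
        out = pmf_barrier(self.planted_profile())
        assert out["barrier_kcal"] == pytest.approx(3.0, abs=0.05)
        assert out["position_A"] == pytest.approx(4.0, abs=0.1)
        assert not out["flagged"]

    def test_monotone_profile_flagged_zero(self):
        r = np.linspace(2, 12, 50)
        out = pmf_barrier(PMFProfile(r, -r))
        assert out["barrier_kcal"] == 0.0 and out["flagged"]

    def test_noisy_barrier_within_band(self):
        out = pmf_barrier(self.planted_profile(noise=0.1, seed=1))
        assert out["barrier_kcal"] == pytest.approx(3.0, abs=0.3)

    def test_text_round_trip(self, tmp_path):
        p = self.planted_profile()
        path = tmp_path / "pmf.dat"
        np.savetxt(path, np.column_stack([p.grid, p.free_energy]))
        p2 = PMFProfile.from_text(path)
        assert np.allclose(p2.free_energy, p.free_energy, atol=1e-6)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PMFProfile(np.array([1.0, 3.0, 2.0, 4.0, 5.0]), np.zeros(5))


class TestKramers:
    def test_zero_barrier_identity(self):
        assert kramers_attenuation(1e10, 0.0) == pytest.approx(1e10)

    def test_three_kcal_barrier_at_310K(self):
        """1e10 attenuated by 3 kcal/mol at 310 K lands at ~7.7e7, inside
        the experimentally observed 1e7–1e8 window."""
        k = kramers_attenuation(1e10, 3.0, 310.0)
        assert k == pytest.approx(7.7e7, rel=0.02)
        assert 1e7 <= k <= 1e8

    def test_infinite_barrier_limit(self):
        assert kramers_attenuation(1e10, 500.0) == pytest.approx(0.0, abs=1e-60)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            kramers_attenuation(1e10, -1.0)
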