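"""Drude dipoles, dipole tensor, permanent fields and the SCF solver."""

import numpy as np
import pytest

from thzwater.constants import EA_TO_DEBYE
from thzwater.polarization import (
    PolarizableSystem,
    PolarizationCatastropheError,
    PolarizationOptions,
    build_system,
    dipole_tensor,
    drude_induced,
    permanent_field,
    post_trajectory_polarization,
    scale_polarizability,
    scf_induced_dipoles,
)
from thzwater.synthetic import ClusterConfig, generate_cluster
from thzwater.water_models import build_reference_molecule, load_model


class TestDrudeInduced:
    def test_unit_conversion(self):
        mu = drude_induced([0, 0, 0], [0.1, 0, 0], q_d=1.0)
        np.testing.assert_allclose(mu, [0.480321, 0, 0], atol=1e-9)

    def test_zero_displacement(self):
        np.testing.assert_allclose(drude_induced([1, 2, 3], [1, 2, 3], -1.7), 0.0)

    def test_negative_drude_charge(self):
        # q_d = -1.71636 e, d = (0, 0, -0.05) A -> (0, 0, 0.0858) e*A
        mu = drude_induced([0, 0, 0], [0, 0, -0.05], q_d=-1.71636)
        np.testing.assert_allclose(mu, [0, 0, 0.085818 * EA_TO_DEBYE], atol=1e-6)
        assert mu[2] == pytest.approx(0.4122, abs=2e-4)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            drude_induced([0, 0, 0], [0.1, 0, 0], q_d=0.0)


class TestDipoleTensor:
    def test_axis_aligned_closed_forms(self):
        np.testing.assert_allclose(
            dipole_tensor([1.0, 0, 0]), np.diag([2.0, -1.0, -1.0]), atol=1e-12
        )
        np.testing.assert_allclose(
            dipole_tensor([0, 2.0, 0]), np.diag([-1 / 8, 2 / 8, -1 / 8]), atol=1e-12
        )

    def test_traceless_and_symmetric_random(self, rng):
        for _ in range(200):
            t = dipole_tensor(rng.normal(size=3) * 5)
            assert np.trace(t) == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(t, t.T, atol=1e-14)

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            dipole_tensor([0, 0, 1e-8])

    def test_thole_damping_limits(self):
        bare = dipole_tensor([6.0, 1.0, -2.0])
        damped_far = dipole_tensor(
            [6.0, 1.0, -2.0], "thole_damped", thole_a=0.39, alpha_i=1.0, alpha_j=1.0
        )
        np.testing.assert_allclose(damped_far, bare, rtol=1e-6)
        damped_near = dipole_tensor(
            [0.3, 0, 0], "thole_damped", thole_a=0.39, alpha_i=1.0, alpha_j=1.0
        )
        assert np.abs(damped_near).max() < np.abs(dipole_tensor([0.3, 0, 0])).max()


def _point_system(positions, charges, molecule, alphas):
    return PolarizableSystem(
        positions=np.asarray(positions, float),
        charges=np.asarray(charges, float),
        molecule=np.asarray(molecule, int),
        alphas=np.asarray(alphas, float),
    )


class TestPermanentField:
    def test_single_charge_coulomb(self):
        sys = _point_system([[0, 0, 0], [1, 0, 0]], [0, 1.0], [0, 1], [1.0, 0])
        e = permanent_field(sys)
        np.testing.assert_allclose(e, [[-1.0, 0, 0]], atol=1e-12)

    def test_symmetric_charges_cancel_transverse(self):
        sys = _point_system(
            [[0, 0, 0], [1, 1, 0], [1, -1, 0]], [0, 1.0, 1.0], [0, 1, 2], [1.0, 0, 0]
        )
        e = permanent_field(sys)
        assert e[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_matches_naive_double_loop(self, rng):
        n = 9
        pos = rng.uniform(0, 8, size=(n, 3))
        q = rng.normal(size=n)
        mol = np.arange(n)
        sys = _point_system(pos, q, mol, np.r_[1.0, np.zeros(n - 1)])
        e = permanent_field(sys)[0]
        brute = np.zeros(3)
        for j in range(1, n):
            d = pos[0] - pos[j]
            brute += q[j] * d / np.linalg.norm(d) ** 3
        np.testing.assert_allclose(e, brute, atol=1e-12)

    def test_overlapping_intermolecular_sites_rejected(self):
        sys = _point_system([[0, 0, 0], [0, 0, 0]], [1.0, 1.0], [0, 1], [1.0, 0])
        with pytest.raises(ValueError, match="singular field"):
            permanent_field(sys)


class TestSCF:
    def test_isolated_site_uniform_field(self):
        sys = _point_system([[0, 0, 0]], [0.0], [0], [1.47])
        sol = scf_induced_dipoles(sys, external_field=np.array([[0.1, -0.2, 0.3]]))
        np.testing.assert_allclose(
            sol.dipoles, 1.47 * np.array([[0.1, -0.2, 0.3]]) * EA_TO_DEBYE, atol=1e-9
        )
        assert sol.converged

    def test_two_sites_match_direct_6x6_inverse(self, rng):
        pos = np.array([[0, 0, 0], [0, 0, 3.1]])
        alphas = np.array([1.2, 0.9])
        e0 = rng.normal(size=(2, 3)) * 0.05
        sys = _point_system(pos, [0, 0], [0, 1], alphas)
        sol = scf_induced_dipoles(
            sys, PolarizationOptions(tol=1e-11), external_field=e0
        )
        t = dipole_tensor(pos[0] - pos[1])
        big_t = np.zeros((6, 6))
        big_t[:3, 3:] = t
        big_t[3:, :3] = t
        a = np.repeat(alphas, 3)
        mu_oracle = np.linalg.solve(np.eye(6) - a[:, None] * big_t, a * e0.reshape(-1))
        np.testing.assert_allclose(
            sol.dipoles.reshape(-1), mu_oracle * EA_TO_DEBYE, atol=1e-8
        )

    def test_mirror_symmetric_dimer(self, spce):
        opts = PolarizationOptions(tol=1e-9)
        geoms = []
        from thzwater.water_models import RigidTransform

        flip = np.diag([1.0, 1.0, -1.0])
        geoms.append(build_reference_molecule(spce, RigidTransform(np.eye(3), [0, 0, -2]), 0))
        geoms.append(build_reference_molecule(spce, RigidTransform(flip, [0, 0, 2]), 1))
        spec = _with_alpha(spce, 1.0)
        sol = scf_induced_dipoles(build_system(geoms, spec), opts)
        mu1, mu2 = sol.dipoles
        np.testing.assert_allclose(mu1, flip @ mu2, atol=1e-8)

    def test_linearity_in_external_field(self, rng):
        pos = rng.uniform(0, 7, size=(4, 3)) + np.arange(4)[:, None] * 3
        sys = _point_system(pos, np.zeros(4), np.arange(4), np.full(4, 1.47))
        e0 = rng.normal(size=(4, 3)) * 0.02
        for interaction in ("bare_tensor", "thole_damped"):
            opts = PolarizationOptions(interaction=interaction, tol=1e-10)
            mu1 = scf_induced_dipoles(sys, opts, external_field=e0).dipoles
            mu2 = scf_induced_dipoles(sys, opts, external_field=2 * e0).dipoles
            np.testing.assert_allclose(mu2, 2 * mu1, atol=1e-7)

    def test_fixed_point_equals_direct_linear_on_random_clusters(self, spce):
        spec = _with_alpha(spce, 1.47)
        tol = 1e-8
        for seed in range(10):
            cfg = ClusterConfig(n_molecules=6, box_edge=12.0, min_oo_distance=2.8, seed=seed)
            system = build_system(generate_cluster(cfg, spec), spec)
            fp = scf_induced_dipoles(system, PolarizationOptions(tol=tol))
            dl = scf_induced_dipoles(
                system, PolarizationOptions(solver="direct_linear", tol=tol)
            )
            assert np.abs(fp.dipoles - dl.dipoles).max() <= 10 * tol

    def test_polarization_catastrophe_detected(self):
        # alpha*T eigenvalue 2*alpha/r^3 >= 1 for r <= (2*1.47)^(1/3) = 1.43 A
        sys = _point_system([[0, 0, 0], [0, 0, 1.2]], [0, 0], [0, 1], [1.47, 1.47])
        with pytest.raises(PolarizationCatastropheError, match=r"\(0, 1\)"):
            scf_induced_dipoles(sys, external_field=np.full((2, 3), 0.01))

    def test_converges_at_liquid_like_separation(self):
        sys = _point_system([[0, 0, 0], [0, 0, 2.6]], [0, 0], [0, 1], [1.47, 1.47])
        sol = scf_induced_dipoles(sys, external_field=np.full((2, 3), 0.01))
        assert sol.converged and sol.iterations < 50

    def test_minimum_image_large_cutoff_equals_open_cluster(self, spce):
        spec = _with_alpha(spce, 1.0)
        cfg = ClusterConfig(n_molecules=4, box_edge=7.0, min_oo_distance=2.8, seed=2)
        mols = generate_cluster(cfg, spec)
        system = build_system(mols, spec)
        open_sol = scf_induced_dipoles(system, PolarizationOptions(tol=1e-10))
        # configuration fits in a box large enough that no image interacts
        mi = PolarizationOptions(
            boundary="minimum_image", box=40.0, cutoff=19.9, switch_width=0.5, tol=1e-10
        )
        mi_sol = scf_induced_dipoles(system, mi)
        np.testing.assert_allclose(open_sol.dipoles, mi_sol.dipoles, atol=1e-8)


class TestPostTrajectory:
    def test_single_molecule_zero(self, spce):
        geom = build_reference_molecule(spce)
        frames = geom.coords[None, None, :3, :]
        induced = post_trajectory_polarization(frames, spce)
        np.testing.assert_allclose(induced, 0.0, atol=1e-12)

    def test_warm_start_equals_cold_start(self, spce, rng):
        frames = _two_molecule_frames(spce, rng, n_frames=3)
        warm = post_trajectory_polarization(frames, spce)
        cold = np.stack([
            post_trajectory_polarization(frames[f:f + 1], spce)[0]
            for f in range(len(frames))
        ])
        np.testing.assert_allclose(warm, cold, atol=1e-5)

    def test_zero_polarizability_gives_zero(self, spce, rng):
        frames = _two_molecule_frames(spce, rng, n_frames=2)
        induced = post_trajectory_polarization(frames, spce, alpha_override=0.0)
        np.testing.assert_allclose(induced, 0.0)


class TestScalePolarizability:
    def test_identity_factor(self, swm4):
        assert scale_polarizability(swm4, 1.0).drude.alpha == swm4.drude.alpha

    def test_swm4_twenty_percent_increase(self, swm4):
        scaled = scale_polarizability(swm4, 1.2)
        assert scaled.drude.alpha == pytest.approx(1.2 * swm4.drude.alpha, rel=1e-12)
        assert scaled.drude.alpha == pytest.approx(1.176, rel=5e-3)

    def test_qm_downscaling_workflow(self, amoeba):
        scaled = scale_polarizability(amoeba, 0.85)
        assert scaled.polarizability["O"] == pytest.approx(0.85 * 1.47, rel=1e-12)

    def test_invalid_factor_rejected(self, swm4):
        with pytest.raises(Exception):
            scale_polarizability(swm4, 0.0)


def _with_alpha(spec, alpha):
    from dataclasses import replace

    return replace(spec, polarizability={"O": alpha})


def _two_molecule_frames(spce, rng, n_frames):
    from conftest import random_rotation
    from thzwater.water_models import RigidTransform

    frames = []
    for _ in range(n_frames):
        g1 = build_reference_molecule(
            spce, RigidTransform(random_rotation(rng), [0, 0, 0]), 0
        )
        g2 = build_reference_molecule(
            spce, RigidTransform(random_rotation(rng), [0, 0, 3.0]), 1
        )
        frames.append(np.stack([g1.coords[:3], g2.coords[:3]]))
    return np.asarray(frames)
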