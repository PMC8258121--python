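"""Finite-element stage: closed-form checks, symmetry, convergence."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cared import fe
from cared.config import preset, build_model
from cared.fixtures import isotropic_swelling_stretch, unit_cube_model
from cared.materials import MaterialProfiles


def _no_fibrils(model):
    model.fibrils.primary_density[:] = 0.0
    model.fibrils.secondary_density[:] = 0.0
    return model


class TestSingleElement:
    def test_stress_free_state_without_load_or_charge(self):
        model = unit_cube_model(FCD0=0.0)
        solver = fe.FELite(model.mesh)
        state = solver.solve_swelling(model)
        assert np.abs(state.u).max() < 1e-12
        np.testing.assert_allclose(state.ip_F,
                                   np.broadcast_to(np.eye(3), (1, 8, 3, 3)),
                                   atol=1e-12)

    def test_free_swelling_matches_scalar_donnan_equilibrium(self):
        """3-D FE free swelling of a uniform cube equals the isotropic
        closed-form balance of matrix stress against Donnan pressure."""
        model = _no_fibrils(unit_cube_model(FCD0=0.2, n_f0=0.8))
        # uniform matrix: neutralise the depth scaling at this element
        model.profiles = MaterialProfiles(
            nf0_coeffs=(0.8,), matrix_solid_ref=0.2)
        solver = fe.FELite(model.mesh)
        state = solver.solve_swelling(model)
        lam_expected = isotropic_swelling_stretch(model.profiles, 0.2, 0.8)
        J = state.ip_J
        np.testing.assert_allclose(J, lam_expected ** 3, rtol=1e-6)

    def test_drained_uniaxial_matches_scalar_reduction(self):
        """Platen compression of a charge-free cube against the 1-D
        uniaxial solution of the same neo-Hookean law."""
        model = _no_fibrils(unit_cube_model(FCD0=0.0, n_f0=0.8))
        model.profiles = MaterialProfiles(nf0_coeffs=(0.8,),
                                          matrix_solid_ref=0.2)
        solver = fe.FELite(model.mesh)
        sw = solver.solve_swelling(model)
        strain = 0.10
        state, reaction = solver.solve_platen_strain(model, strain, sw)
        mu, lam = model.profiles.lame

        def lateral_balance(lz):
            def sxx(lx):
                J = lx * lx * lz
                return mu * (lx * lx - 1) + lam * np.log(J)
            return brentq(sxx, 0.5, 2.0)

        lz = 1.0 - strain
        lx = lateral_balance(lz)
        J = lx * lx * lz
        # nominal axial traction of the 1-D solution
        Pzz = (mu * (lz * lz - 1) + lam * np.log(J)) / lz
        # unit cube: bottom area = 1; the support reaction balances the
        # compressive platen traction, so compare magnitudes
        assert abs(reaction) == pytest.approx(abs(Pzz), rel=1e-5, abs=1e-8)
        np.testing.assert_allclose(state.ip_J, J, rtol=1e-6)

    def test_fluid_fraction_stays_physical(self):
        model = unit_cube_model(FCD0=0.25, n_f0=0.85)
        solver = fe.FELite(model.mesh)
        sw = solver.solve_swelling(model)
        ramp = solver.solve_platen_pressure(model, 2.0, sw)
        for state in (sw, ramp):
            n_f = (0.85 - 1.0 + state.ip_J) / state.ip_J
            assert np.all((n_f > 0) & (n_f < 1))


@pytest.fixture(scope="module")
def small_model():
    return build_model(preset("reference", target_elements=250))


class TestExplantSolves:
    def test_mirror_symmetry_of_intact_solution(self, small_model):
        """The intact explant, architecture and loading are symmetric
        across the y-z plane; so must be the displacement field."""
        model = small_model
        solver = fe.get_solver(model.mesh)
        sw = solver.solve_swelling(model)
        ramp = solver.solve_platen_pressure(model, 2.0, sw)
        nodes = model.mesh.nodes
        u = ramp.u.reshape(-1, 3)
        # pair nodes with their mirrors
        key = np.round(np.stack([-nodes[:, 0], nodes[:, 1], nodes[:, 2]], 1), 9)
        lookup = {tuple(np.round(p, 9)): i for i, p in enumerate(nodes)}
        scale = np.abs(u).max()
        for i, k in enumerate(map(tuple, key)):
            j = lookup[k]
            assert abs(u[i, 0] + u[j, 0]) < 1e-5 * scale
            assert abs(u[i, 1] - u[j, 1]) < 1e-5 * scale
            assert abs(u[i, 2] - u[j, 2]) < 1e-5 * scale

    def test_superficial_tension_is_surface_parallel(self, small_model):
        """Platen compression stretches the superficial zone laterally:
        its in-plane tensile strain exceeds the deep zone's."""
        model = small_model
        snap = fe.solve_load_step(model, fe.LoadingProtocol(pressure=2.0))
        lams, _ = snap.element_principal
        sup = lams[model.mesh.layer == 0, 0]
        deep = lams[model.mesh.layer == 2, 0]
        assert sup.mean() > 0
        assert sup.mean() > deep.mean()

    def test_swelling_raises_volume(self, small_model):
        solver = fe.get_solver(small_model.mesh)
        sw = solver.solve_swelling(small_model)
        assert sw.ip_J.min() > 1.0

    def test_zero_pressure_returns_swollen_snapshot(self, small_model):
        snap = fe.solve_load_step(small_model, fe.LoadingProtocol(pressure=0.0))
        assert snap.n_elements == small_model.mesh.n_elements
        assert np.all(np.linalg.det(snap.ip_F) > 1.0)


class TestMeshConvergence:
    def test_swelling_field_converges_with_refinement(self):
        """Volume-averaged swelling stretch approaches the fine-mesh
        value monotonically as the mesh refines."""
        means = {}
        for target in (250, 360, 640, 1000):
            model = build_model(preset("reference", target_elements=target))
            solver = fe.FELite(model.mesh)
            sw = solver.solve_swelling(model)
            w = solver.wdet.ravel()
            means[target] = float(np.average(sw.ip_J.ravel(), weights=w))
        ref = means.pop(1000)
        errors = [abs(means[t] - ref) for t in (250, 360, 640)]
        assert errors[0] > errors[1] > errors[2]
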