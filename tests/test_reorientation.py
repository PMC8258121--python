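"""Fibril reorientation rule: examples and convergence properties."""

import numpy as np
import pytest

from cared.model import FibrilSet, StrainSnapshot
from cared.reorientation import (ReorientationParams, preferred_directions,
                                 reorientation_step, update_primary_fibrils)

X = np.array([1.0, 0, 0])
Y = np.array([0, 1.0, 0])
Z = np.array([0, 0, 1.0])
EYE = np.eye(3)


def params(**kw) -> ReorientationParams:
    return ReorientationParams(**kw)


class TestPreferredDirections:
    def test_single_tensile_direction(self):
        cands = preferred_directions(np.array([0.2, -0.05, -0.1]), EYE)
        assert len(cands) == 1
        np.testing.assert_allclose(np.abs(cands[0]), X, atol=1e-14)

    def test_all_compressive_gives_no_candidates(self):
        assert preferred_directions(np.array([-0.01, -0.05, -0.1]), EYE) == []

    def test_equal_biaxial_gives_diagonals(self):
        cands = preferred_directions(np.array([0.1, 0.1, -0.02]), EYE)
        assert len(cands) == 2
        s = 1 / np.sqrt(2)
        got = sorted(tuple(np.round(np.abs(c), 10)) for c in cands)
        assert got == [(s, s, 0.0), (s, s, 0.0)] or len(got) == 2

    def test_candidates_unit_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lams = np.sort(rng.uniform(-0.3, 0.3, 3))[::-1]
            cands = preferred_directions(lams, EYE)
            for c in cands:
                assert np.linalg.norm(c) == pytest.approx(1.0, abs=1e-12)


class TestReorientationStep:
    def test_rodrigues_90_degree_example(self):
        # α = 90°, Δθ = 0.3·90° = 27°, rotation in the x-z plane
        new = reorientation_step(X, [Z], eps_f=0.05, params=params())
        expected = np.array([np.cos(np.deg2rad(27)), 0.0,
                             np.sin(np.deg2rad(27))])
        np.testing.assert_allclose(new, expected, atol=1e-12)

    def test_below_minimum_angle_is_identity(self):
        e_p = np.array([np.cos(np.deg2rad(0.5)), np.sin(np.deg2rad(0.5)), 0])
        out = reorientation_step(X, [e_p], eps_f=0.05, params=params())
        np.testing.assert_array_equal(out, X)

    def test_no_tension_is_identity(self):
        out = reorientation_step(X, [Z], eps_f=-0.02, params=params())
        np.testing.assert_array_equal(out, X)

    def test_empty_candidates_is_identity(self):
        np.testing.assert_array_equal(
            reorientation_step(X, [], eps_f=0.05, params=params()), X)

    def test_rotation_angle_is_kappa_alpha(self):
        rng = np.random.default_rng(1)
        p = params()
        for _ in range(40):
            e_f = rng.normal(size=3)
            e_f /= np.linalg.norm(e_f)
            e_p = rng.normal(size=3)
            e_p /= np.linalg.norm(e_p)
            alpha = np.arccos(np.clip(abs(e_f @ e_p), 0, 1))
            new = reorientation_step(e_f, [e_p], 0.05, p)
            if np.degrees(alpha) < p.alpha_min_deg:
                np.testing.assert_array_equal(new, e_f)
                continue
            assert np.linalg.norm(new) == pytest.approx(1.0, abs=1e-12)
            step = np.arccos(np.clip(abs(new @ e_f), 0, 1))
            assert step == pytest.approx(p.kappa * alpha, abs=1e-8)

    def test_alpha_contracts_geometrically(self):
        """Iterating the step shrinks α by (1−κ) until below the cutoff."""
        rng = np.random.default_rng(2)
        p = params()
        for _ in range(15):
            e_f = rng.normal(size=3)
            e_f /= np.linalg.norm(e_f)
            e_p = rng.normal(size=3)
            e_p /= np.linalg.norm(e_p)
            alpha0 = np.arccos(np.clip(abs(e_f @ e_p), 0, 1))
            if np.degrees(alpha0) < 1.0:
                continue
            bound = int(np.ceil(np.log(np.deg2rad(1.0) / alpha0)
                                / np.log(1 - p.kappa))) + 1
            alpha = alpha0
            for i in range(bound + 5):
                new = reorientation_step(e_f, [e_p], 0.05, p)
                if np.array_equal(new, e_f):
                    break
                a_new = np.arccos(np.clip(abs(new @ e_p), 0, 1))
                assert a_new == pytest.approx((1 - p.kappa) * alpha, abs=1e-8)
                e_f, alpha = new, a_new
            assert i <= bound


def _snapshot_from_E(E_el: np.ndarray, centroids: np.ndarray) -> StrainSnapshot:
    n = len(E_el)
    C = 2 * E_el + np.eye(3)
    w, V = np.linalg.eigh(C)
    F = np.einsum("nik,nk,njk->nij", V, np.sqrt(w), V)
    return StrainSnapshot(ip_F=F, ip_coords=centroids,
                          ip_element=np.arange(n), n_elements=n)


def _fibrils(dirs0: np.ndarray) -> FibrilSet:
    n = len(dirs0)
    mirror = dirs0 * np.array([-1.0, 1, 1])
    primary = np.stack([dirs0, dirs0, mirror, mirror], axis=1)
    sec = np.tile(np.eye(3)[None, :, :], (n, 5, 1))[:, :13]
    sec = sec / np.linalg.norm(sec, axis=-1, keepdims=True)
    return FibrilSet(primary, sec, np.full((n, 4), 0.1),
                     np.full((n, 13), 0.02))


class TestUpdatePrimaryFibrils:
    def test_mirror_bookkeeping(self):
        dirs0 = np.array([[1.0, 0, 0]])
        fs = _fibrils(dirs0)
        E = np.zeros((1, 3, 3))
        E[0] = np.diag([0.0, 0.0, 0.1])  # tension along z only
        snap = _snapshot_from_E(E, np.zeros((1, 3)))
        # give fibril 1 slight tension so the rule fires: tilt strain
        E[0, 0, 2] = E[0, 2, 0] = 0.02
        snap = _snapshot_from_E(E, np.zeros((1, 3)))
        out = update_primary_fibrils(fs, snap, ReorientationParams())
        np.testing.assert_allclose(out.primary_dirs[0, 1],
                                   out.primary_dirs[0, 0], atol=1e-15)
        np.testing.assert_allclose(
            out.primary_dirs[0, 2],
            out.primary_dirs[0, 0] * np.array([-1.0, 1, 1]), atol=1e-15)
        np.testing.assert_allclose(out.primary_dirs[0, 3],
                                   out.primary_dirs[0, 2], atol=1e-15)
        # densities and secondary directions untouched
        np.testing.assert_array_equal(out.primary_density, fs.primary_density)
        np.testing.assert_array_equal(out.secondary_dirs, fs.secondary_dirs)

    def test_no_tension_bitwise_fixed_point(self):
        dirs0 = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        fs = _fibrils(dirs0)
        E = np.tile(np.diag([-0.05, -0.02, -0.1]), (2, 1, 1))
        snap = _snapshot_from_E(E, np.zeros((2, 3)))
        out = update_primary_fibrils(fs, snap, ReorientationParams())
        np.testing.assert_array_equal(out.primary_dirs, fs.primary_dirs)

    def test_aligned_fibril_unchanged(self):
        dirs0 = np.array([[1.0, 0, 0]])
        fs = _fibrils(dirs0)
        E = np.array([np.diag([0.2, -0.05, -0.1])])
        snap = _snapshot_from_E(E, np.zeros((1, 3)))
        out = update_primary_fibrils(fs, snap, ReorientationParams())
        np.testing.assert_array_equal(out.primary_dirs, fs.primary_dirs)

    def test_mirror_symmetric_strain_preserves_symmetry(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, np.pi / 2, 4)
        dirs0 = np.stack([np.cos(theta), np.zeros(4), np.sin(theta)], axis=1)
        fs = _fibrils(dirs0)
        E = np.zeros((4, 3, 3))
        for i in range(4):
            # symmetric across y-z: no xy / xz coupling
            E[i] = np.diag(rng.uniform(-0.1, 0.2, 3))
        snap = _snapshot_from_E(E, rng.normal(size=(4, 3)))
        out = update_primary_fibrils(fs, snap, ReorientationParams())
        mirror = out.primary_dirs[:, 0] * np.array([-1.0, 1, 1])
        np.testing.assert_allclose(out.primary_dirs[:, 2], mirror, atol=1e-10)
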