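"""Reference finite-element stage (FRPVES-lite).

A total-Lagrangian 8-node hexahedron solver for the quasi-static
mechanics of the explant.  The constitutive description is a reduced
fibril-reinforced poroelastic swelling law:

* compressible neo-Hookean non-fibrillar matrix;
* tension-only exponential-toe fibril stress along each of the element's 17
  fibril directions, weighted by the fibril's relative density share;
* ideal Donnan osmotic pressure from the current fixed charge density
  (diluted by the volumetric deformation) against the external bath;
* for the fast compression ramp (0.1 s — far shorter than the
  poroelastic drainage time of the explant) a stiff volumetric penalty
  about the swollen state renders the response effectively undrained;
  equilibria (free swelling, stress-relaxation end state) are solved
  fully drained.

Loading phases: a drained free-swelling equilibrium, then a rigid,
frictionless flat platen on the top surface, applied either load- or
displacement-controlled.  The platen is a single master degree of
freedom to which every top-node vertical displacement is slaved.
Newton's method with numerically differentiated consistent element
tangents and adaptive load stepping solves each phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import donnan_pressure
from .mesh import HexMesh, _DN_REF, _N_REF
from .model import ExplantModel, StrainSnapshot

__all__ = ["LoadingProtocol", "SolverFailure", "FELite", "solve_load_step",
           "equilibrium_reaction"]

log = logging.getLogger(__name__)

_I3 = np.eye(3)
_DELTA = 1e-4   # fibril slack→taut smoothing width [strain]


@dataclass
class LoadingProtocol:
    """Platen loading applied after free swelling."""

    pressure: float = 2.0        # [MPa]
    ramp_time: float = 0.1       # [s]; used to justify the undrained limit
    friction_mu: float = 0.05    # platen friction (treated as free sliding)
    mode: str = "normal"         # normal | injurious | stress_relaxation

    def __post_init__(self) -> None:
        if self.pressure < 0.0 or self.ramp_time <= 0.0:
            raise ValueError("pressure must be ≥ 0 and ramp_time > 0")


class SolverFailure(RuntimeError):
    """Nonlinear solve did not converge; carries the residual report."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass
class _Ctx:
    """Per-solve constitutive context."""

    dirs: np.ndarray            # (n_el, 17, 3)
    dens: np.ndarray            # (n_el, 17)
    FCD: np.ndarray             # (n_el,) current fixed charge density
    n_f0: np.ndarray            # (n_el,)
    mu: float
    lam: float
    m_scale: np.ndarray         # (n_el,) depth factor on the matrix stiffness
    k1: float
    k2: float
    eps_lin: float
    salt: float
    phi: float
    donnan_scale: float = 1.0
    J_ref: np.ndarray | None = None   # (n_el, 8); undrained reference
    K_u: float = 0.0


@dataclass
class PhaseState:
    """Converged displacement field of one loading phase."""

    u: np.ndarray               # (n_dof,) full displacement vector
    ip_F: np.ndarray            # (n_el, 8, 3, 3)
    ip_J: np.ndarray            # (n_el, 8)


class FELite:
    """Assembled solver for one mesh; reusable across iterations."""

    def __init__(self, mesh: HexMesh, newton_tol: float = 1e-7,
                 newton_maxit: int = 30, fd_step: float = 1e-6):
        self.mesh = mesh
        self.newton_tol = newton_tol
        self.newton_maxit = newton_maxit
        self.fd_step = fd_step

        Xe = mesh.nodes[mesh.conn]                              # (n_el, 8, 3)
        Jac = np.einsum("gak,eai->egki", _DN_REF, Xe)           # (n_el,8,3,3)
        detJ = np.linalg.det(Jac)
        Jinv = np.linalg.inv(Jac)
        # dN_a/dX_j at each Gauss point of each element
        self.dNdX = np.einsum("egjk,gak->egaj", Jinv, _DN_REF)
        self.wdet = detJ                                        # unit weights
        self.gp_coords = np.einsum("ga,eai->egi", _N_REF, Xe)   # (n_el,8,3)

        n_el = mesh.n_elements
        self.n_dof = 3 * mesh.n_nodes
        self.edofs = (3 * mesh.conn[:, :, None] + np.arange(3)).reshape(n_el, 24)
        self._rows = np.repeat(self.edofs, 24, axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, 24)).ravel()

        bot = mesh.bottom_nodes
        self.bottom_z_dofs = 3 * bot + 2
        self._build_rigid_elimination(bot)
        self.top_z_dofs = 3 * mesh.top_nodes + 2
        self.area = np.pi * mesh.radius ** 2   # nominal platen area [mm²]

    def _build_rigid_elimination(self, bot: np.ndarray) -> None:
        """Momentum-style constraints removing the in-plane rigid modes.

        Point pins would have to sit exactly on the symmetry plane /
        axis, which graded meshes need not provide, and off-plane pins
        bias the solution.  Instead the three in-plane rigid modes are
        removed globally over the bottom nodes — Σu_x = 0, Σu_y = 0 and
        Σ(x·u_y − y·u_x) = 0 — which are mirror-invariant and exert no
        local reaction on the elastic field.  Three pivot dofs are
        eliminated in favour of the rest of the constrained support.
        """
        import scipy.linalg as sla

        X = self.mesh.nodes[bot]
        dof_x, dof_y = 3 * bot, 3 * bot + 1
        sup = np.concatenate([dof_x, dof_y])
        C = np.zeros((3, len(sup)))
        nb = len(bot)
        C[0, :nb] = 1.0                  # Σ u_x
        C[1, nb:] = 1.0                  # Σ u_y
        C[2, :nb] = -X[:, 1]             # Σ (x u_y − y u_x)
        C[2, nb:] = X[:, 0]
        _, R, piv = sla.qr(C, pivoting=True, mode="economic")
        self._elim_pivots = sup[piv[:3]]
        others = sup[piv[3:]]
        coeff = -np.linalg.solve(R[:, :3], R[:, 3:])   # u_piv = coeff @ u_oth
        coeff[np.abs(coeff) < 1e-14] = 0.0
        self._elim_others = others
        self._elim_coeff = coeff

    # ---------------------------------------------------------------- forces
    def _piola(self, F: np.ndarray, ctx: _Ctx) -> np.ndarray:
        J = np.linalg.det(F)
        if np.any(J < 0.05) or not np.all(np.isfinite(J)):
            return np.full_like(F, np.nan)
        FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
        lnJ = np.log(J)
        sc = ctx.m_scale[:, None, None, None]
        P = sc * (ctx.mu * (F - FinvT)
                  + (ctx.lam * lnJ)[..., None, None] * FinvT)

        d = np.einsum("egij,efj->egfi", F, ctx.dirs)
        lamf = np.linalg.norm(d, axis=-1)
        eps = lamf - 1.0
        # tension-only exponential-toe stress with a smooth slack→taut
        # transition (R(0)=0, R(ε)→ε in tension, →0 in compression) so the
        # Newton tangent is well-defined at the stress-free state; the toe
        # is linearised beyond eps_lin for robustness at trial iterates
        ramp = 0.5 * (eps + np.sqrt(eps * eps + _DELTA * _DELTA) - _DELTA)
        e_t = np.minimum(ramp, ctx.eps_lin)
        sig = ctx.k1 * (np.exp(ctx.k2 * e_t) - 1.0)
        slope_end = ctx.k1 * ctx.k2 * np.exp(ctx.k2 * ctx.eps_lin)
        sig = sig + slope_end * np.maximum(ramp - ctx.eps_lin, 0.0)
        coef = ctx.dens[:, None, :] * sig / lamf
        P += np.einsum("egf,egfi,efj->egij", coef, d, ctx.dirs)

        p = np.zeros_like(J)
        if ctx.donnan_scale > 0.0:
            denom = np.clip(ctx.n_f0[:, None] - 1.0 + J, 0.05, None)
            cF = ctx.FCD[:, None] * ctx.n_f0[:, None] / denom
            p += ctx.donnan_scale * donnan_pressure(cF, ctx.salt, ctx.phi)
        if ctx.J_ref is not None:
            p += ctx.K_u * np.log(ctx.J_ref / J)
        P -= (p * J)[..., None, None] * FinvT
        return P

    def _element_forces(self, ue: np.ndarray, ctx: _Ctx) -> np.ndarray:
        F = _I3 + np.einsum("eai,egaj->egij", ue, self.dNdX)
        P = self._piola(F, ctx)
        return np.einsum("eg,egij,egaj->eai", self.wdet, P, self.dNdX)

    def internal_forces(self, u: np.ndarray, ctx: _Ctx) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.conn]
        fe = self._element_forces(ue, ctx)
        f = np.zeros(self.n_dof)
        np.add.at(f, self.edofs.ravel(), fe.reshape(-1, 24).ravel())
        return f

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.conn]
        return _I3 + np.einsum("eai,egaj->egij", ue, self.dNdX)

    def _tangent(self, u: np.ndarray, ctx: _Ctx) -> sp.csr_matrix:
        ue = u.reshape(-1, 3)[self.mesh.conn]
        n_el = ue.shape[0]
        Ke = np.empty((n_el, 24, 24))
        h = self.fd_step
        # central differences: even error, and (unlike one-sided steps)
        # mirror-equivariant at the fibril slack/taut transition, so a
        # symmetric model keeps a symmetric Newton path
        for j in range(24):
            du = np.zeros(24)
            du[j] = h
            du = du.reshape(1, 8, 3)
            f1 = self._element_forces(ue + du, ctx)
            f2 = self._element_forces(ue - du, ctx)
            Ke[:, :, j] = (f1.reshape(-1, 24) - f2.reshape(-1, 24)) / (2 * h)
        K = sp.coo_matrix((Ke.ravel(), (self._rows, self._cols)),
                          shape=(self.n_dof, self.n_dof))
        return K.tocsr()

    # ----------------------------------------------------------- constraints
    def _base_fixed(self) -> dict[int, float]:
        return {int(d): 0.0 for d in self.bottom_z_dofs}

    def _reduction(self, fixed: dict[int, float],
                   slaved: dict[int, float] | None = None):
        """Build u_full = T u_red + u_presc.

        ``slaved`` maps dofs to constant offsets; all slaved dofs share
        one master column (appended last) with unit coefficient.
        """
        slaved = slaved or {}
        pivots = set(int(d) for d in self._elim_pivots)
        free = [d for d in range(self.n_dof)
                if d not in fixed and d not in slaved and d not in pivots]
        n_red = len(free) + (1 if slaved else 0)
        col_of = {d: c for c, d in enumerate(free)}
        rows = list(free)
        cols = list(range(len(free)))
        vals = [1.0] * len(free)
        # rigid-mode elimination: pivot dofs follow the constrained rest
        for a, pdof in enumerate(self._elim_pivots):
            for b, odof in enumerate(self._elim_others):
                c = self._elim_coeff[a, b]
                if c != 0.0 and int(odof) in col_of:
                    rows.append(int(pdof))
                    cols.append(col_of[int(odof)])
                    vals.append(c)
        if slaved:
            rows += list(slaved.keys())
            cols += [n_red - 1] * len(slaved)
            vals += [1.0] * len(slaved)
        T = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_dof, n_red)).tocsr()
        u_presc = np.zeros(self.n_dof)
        for d, v in fixed.items():
            u_presc[d] = v
        for d, v in slaved.items():
            u_presc[d] = v
        return T, u_presc, np.array(free, int)

    # ---------------------------------------------------------------- newton
    def _newton(self, T, u_presc, ctx: _Ctx, f_ext_red, u_red):
        ref = max(0.1, float(np.linalg.norm(f_ext_red)))
        last = np.inf
        lu = None
        stale = False
        for it in range(self.newton_maxit):
            u_full = T @ u_red + u_presc
            f_int = self.internal_forces(u_full, ctx)
            if not np.all(np.isfinite(f_int)):
                return None, np.inf
            r = T.T @ f_int - f_ext_red
            norm = float(np.linalg.norm(r))
            if norm < self.newton_tol * ref + 1e-12:
                return u_red, norm
            # modified Newton: keep the factorised tangent while the
            # residual contracts fast; rebuild when progress slows
            if lu is None or norm > 0.2 * last:
                K = self._tangent(u_full, ctx)
                Kr = (T.T @ K @ T).tocsc()
                try:
                    lu = splu(Kr)
                except Exception:
                    return None, norm
                stale = False
            else:
                stale = True
            du = lu.solve(-r)
            if not np.all(np.isfinite(du)):
                return None, norm
            # backtracking on the residual norm
            step, accepted = 1.0, False
            for _ in range(6):
                trial = u_red + step * du
                f_t = self.internal_forces(T @ trial + u_presc, ctx)
                if np.all(np.isfinite(f_t)):
                    rn = float(np.linalg.norm(T.T @ f_t - f_ext_red))
                    if rn < max(norm * (1.0 - 0.1 * step), norm - 1e-14) or rn < norm * 1.001:
                        u_red, accepted = trial, True
                        break
                step *= 0.5
            if not accepted:
                if stale:
                    lu = None     # stale Jacobian: rebuild and retry
                    continue
                return None, norm
            if norm > 0.999 * last and it > 12:
                return None, norm   # stagnation
            last = norm
        return None, last

    def _ramped(self, make, u_red0, initial_frac: float = 1.0):
        """Adaptive continuation: solve at scale 1 by subdividing on failure.

        ``make(scale)`` returns (T, u_presc, ctx, f_ext_red); the
        reduced vector layout must not change with scale.
        """
        s, ds = 0.0, initial_frac
        u_red = u_red0
        while s < 1.0 - 1e-12:
            target = min(1.0, s + ds)
            T, u_presc, ctx, f_ext = make(target)
            sol, resid = self._newton(T, u_presc, ctx, f_ext, u_red)
            if sol is not None:
                s, u_red = target, sol
                ds = min(ds * 2.0, 1.0 - s + 1e-9) if ds < 1.0 else ds
            else:
                ds *= 0.5
                if ds < 1.0 / 256.0:
                    raise SolverFailure(
                        f"load stepping stalled at scale {s:.4f}", resid)
        return u_red

    # ----------------------------------------------------------------- phases
    def _ctx(self, model: ExplantModel, donnan_scale: float = 1.0,
             J_ref: np.ndarray | None = None) -> _Ctx:
        prof = model.profiles
        mu, lam = prof.lame
        return _Ctx(dirs=model.fibrils.all_dirs, dens=model.fibrils.all_density,
                    FCD=model.composition.FCD, n_f0=model.composition.n_f0,
                    mu=mu, lam=lam,
                    m_scale=prof.matrix_scale(self.mesh.z_norm),
                    k1=prof.fibril_k1, k2=prof.fibril_k2,
                    eps_lin=prof.fibril_eps_lin, salt=prof.external_salt,
                    phi=prof.osmotic_coefficient, donnan_scale=donnan_scale,
                    J_ref=J_ref, K_u=prof.K_undrained)

    def _phase_state(self, u_full: np.ndarray) -> PhaseState:
        F = self.deformation_gradients(u_full)
        return PhaseState(u=u_full, ip_F=F, ip_J=np.linalg.det(F))

    def solve_swelling(self, model: ExplantModel,
                       u0: np.ndarray | None = None) -> PhaseState:
        """Drained free-swelling equilibrium (Donnan pressure ramped up)."""
        fixed = self._base_fixed()
        T, u_presc, free = self._reduction(fixed)
        u_red0 = np.zeros(T.shape[1])
        if u0 is not None:
            u_red0 = u0[free]

        def make(scale):
            return T, u_presc, self._ctx(model, donnan_scale=scale), \
                np.zeros(T.shape[1])

        u_red = self._ramped(make, u_red0)
        return self._phase_state(T @ u_red + u_presc)

    def _platen_reduction(self, swollen_u: np.ndarray):
        """Constraint set with a rigid flat platen on the top surface."""
        fixed = self._base_fixed()
        z_ref = self.mesh.nodes[self.mesh.top_nodes, 2]
        z_sw = z_ref + swollen_u[self.top_z_dofs]
        h_flat = float(z_sw.max())
        offsets = {int(d): float(h_flat - zr)
                   for d, zr in zip(self.top_z_dofs, z_ref)}
        T, u_presc, free = self._reduction(fixed, slaved=offsets)
        return T, u_presc, free, h_flat

    def solve_platen_pressure(self, model: ExplantModel, pressure: float,
                              swollen: PhaseState,
                              u0: np.ndarray | None = None) -> PhaseState:
        """Undrained, load-controlled platen ramp from the swollen state."""
        T, u_presc, free, h_flat = self._platen_reduction(swollen.u)
        n_red = T.shape[1]
        start = swollen.u if u0 is None else u0
        u_red0 = np.zeros(n_red)
        u_red0[:len(free)] = start[free]
        u_red0[-1] = float(np.mean(start[self.top_z_dofs]
                                   - (u_presc[self.top_z_dofs])))
        ctx = self._ctx(model, J_ref=swollen.ip_J)

        def make(scale):
            f_ext = np.zeros(n_red)
            f_ext[-1] = -pressure * self.area * scale
            return T, u_presc, ctx, f_ext

        # a warm start from the previous degeneration iteration is close
        # enough to attempt the full load in one step
        u_red = self._ramped(make, u_red0,
                             initial_frac=1.0 if u0 is not None else 0.5)
        return self._phase_state(T @ u_red + u_presc)

    def solve_platen_strain(self, model: ExplantModel, strain: float,
                            swollen: PhaseState,
                            u0: np.ndarray | None = None) -> tuple[PhaseState, float]:
        """Drained, displacement-controlled compression; returns reaction [N].

        The platen moves down by ``strain`` times the swollen height;
        the returned reaction is the total vertical internal force on
        the bottom support at equilibrium.
        """
        T, u_presc0, free, h_flat = self._platen_reduction(swollen.u)
        # drop the master column: displacement control prescribes it
        T = T[:, :len(free)]
        start = swollen.u if u0 is None else u0
        u_red0 = start[free]
        ctx = self._ctx(model)
        s_total = -strain * h_flat
        top_mask = np.zeros(self.n_dof, bool)
        top_mask[self.top_z_dofs] = True

        def make(scale):
            u_presc = u_presc0.copy()
            u_presc[top_mask] += s_total * scale
            return T, u_presc, ctx, np.zeros(T.shape[1])

        u_red = self._ramped(make, u_red0,
                             initial_frac=1.0 if u0 is not None else 0.5)
        u_presc = u_presc0.copy()
        u_presc[top_mask] += s_total
        u_full = T @ u_red + u_presc
        f_int = self.internal_forces(u_full, ctx)
        reaction = float(f_int[self.bottom_z_dofs].sum())
        return self._phase_state(u_full), reaction


# --------------------------------------------------------------- module API
_solver_cache: dict[int, FELite] = {}


def get_solver(mesh: HexMesh) -> FELite:
    key = id(mesh)
    if key not in _solver_cache:
        _solver_cache.clear()   # one mesh in flight at a time
        _solver_cache[key] = FELite(mesh)
    return _solver_cache[key]


def snapshot_from_state(mesh: HexMesh, solver: FELite,
                        state: PhaseState) -> StrainSnapshot:
    n_el = mesh.n_elements
    return StrainSnapshot(
        ip_F=state.ip_F.reshape(-1, 3, 3),
        ip_coords=solver.gp_coords.reshape(-1, 3),
        ip_element=np.repeat(np.arange(n_el), 8),
        n_elements=n_el,
    )


def solve_load_step(model: ExplantModel, protocol: LoadingProtocol,
                    warm: dict | None = None) -> StrainSnapshot:
    """Free swelling followed by the undrained platen pressure ramp.

    Returns the end-of-ramp deformation-gradient snapshot measured from
    the undeformed reference configuration.  ``warm`` (optional dict)
    carries displacement fields between consecutive degeneration
    iterations to accelerate the Newton solves.
    """
    solver = get_solver(model.mesh)
    warm = warm if warm is not None else {}
    sw = solver.solve_swelling(model, u0=warm.get("swell"))
    warm["swell"] = sw.u
    if protocol.pressure == 0.0:
        return snapshot_from_state(model.mesh, solver, sw)
    ramp = solver.solve_platen_pressure(model, protocol.pressure, sw,
                                        u0=warm.get("ramp"))
    warm["ramp"] = ramp.u
    return snapshot_from_state(model.mesh, solver, ramp)


def equilibrium_reaction(model: ExplantModel, strain: float = 0.10,
                         warm: dict | None = None) -> tuple[float, float]:
    """Equilibrium reaction stress [MPa] at the bottom under platen strain.

    Simulates free swelling, then a drained platen compression of
    ``strain`` (the long-time limit of the stress-relaxation test) and
    returns ``(reaction_stress, swollen_height)``.
    """
    solver = get_solver(model.mesh)
    warm = warm if warm is not None else {}
    sw = solver.solve_swelling(model, u0=warm.get("swell"))
    warm["swell"] = sw.u
    state, reaction = solver.solve_platen_strain(model, strain, sw,
                                                 u0=warm.get("relax"))
    warm["relax"] = state.u
    return abs(reaction) / solver.area, float(
        sw.u[solver.top_z_dofs].mean() + model.mesh.height)
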