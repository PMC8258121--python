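"""Adaptive reorientation of primary collagen fibrils.

Fibrils rotate toward a strain-preferred direction built from the
positive principal strains: candidates e_p = (g₁n₁ ± g₂n₂ ± g₃n₃)/‖·‖
with g_j = max(λ_j, 0).  The candidate closest (by the unsigned angle
α = arccos|e_f·e_p|) to the current direction is selected; if the
fibril is in tension and α exceeds a minimum angle, the direction is
rotated by κ·α about the mutual normal (Rodrigues rotation).  The
rotation rate κ is a per-iteration computational parameter without a
physical time scale.

Only the first of the four primary fibrils is computed; the second
copies it and the remaining two are its mirror image across the y-z
plane, reproducing the split-line symmetry of the explant model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics
from .model import FibrilSet, StrainSnapshot

__all__ = ["ReorientationParams", "preferred_directions",
           "reorientation_step", "update_primary_fibrils"]

_SIGNS = ((1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0))


@dataclass
class ReorientationParams:
    kappa: float = 0.3          # fraction of α rotated per iteration
    alpha_min_deg: float = 1.0  # below this angle no reorientation occurs
    fibril_strain_measure: str = "nominal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.alpha_min_deg <= 0.0:
            raise ValueError("alpha_min_deg must be positive")


def preferred_directions(lams: np.ndarray, dirs: np.ndarray) -> list[np.ndarray]:
    """Strain-preferred fibril directions from sorted principal strains.

    ``lams`` sorted descending, ``dirs[j]`` the matching unit
    directions.  Only positive principal strains contribute; all sign
    combinations of the second and third terms are formed and
    duplicates (up to overall sign) removed.  Returns an empty list
    when no principal strain is tensile.
    """
    g = np.maximum(np.asarray(lams, dtype=float), 0.0)
    if np.all(g == 0.0):
        return []
    out: list[np.ndarray] = []
    for s2, s3 in _SIGNS:
        v = g[0] * dirs[0] + s2 * g[1] * dirs[1] + s3 * g[2] * dirs[2]
        v = v / np.linalg.norm(v)
        if not any(abs(abs(v @ u) - 1.0) < 1e-12 for u in out):
            out.append(v)
    return out


def _rodrigues(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def reorientation_step(e_f: np.ndarray, candidates: list[np.ndarray],
                       eps_f: float, params: ReorientationParams) -> np.ndarray:
    """One reorientation update of a single fibril direction.

    Returns the (unit) direction after rotating by κ·α toward the
    closest preferred direction, or ``e_f`` unchanged when the fibril
    is not in tension, no candidate exists, or α is below the minimum
    angle.
    """
    e_f = np.asarray(e_f, dtype=float)
    if not candidates or eps_f <= 0.0:
        return e_f
    # closest candidate by unsigned angle; ties broken by enumeration order
    best, alpha_best = None, np.inf
    for e_p in candidates:
        alpha = float(np.arccos(np.clip(abs(e_f @ e_p), 0.0, 1.0)))
        if alpha < alpha_best - 1e-12:
            best, alpha_best = e_p, alpha
    if alpha_best < np.deg2rad(params.alpha_min_deg):
        return e_f
    # rotate toward the signed representative on e_f's side
    e_p = best if (e_f @ best) >= 0.0 else -best
    axis = np.cross(e_f, e_p)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:  # parallel guard; unreachable for α ≥ alpha_min ≤ 90°
        return e_f
    new = _rodrigues(e_f, axis / norm, params.kappa * alpha_best)
    return new / np.linalg.norm(new)


def _mirror_x(v: np.ndarray) -> np.ndarray:
    """Mirror a direction across the y-z plane (negate x)."""
    return v * np.array([-1.0, 1.0, 1.0])


def update_primary_fibrils(fibrils: FibrilSet, strain: StrainSnapshot,
                           params: ReorientationParams) -> FibrilSet:
    """Apply the reorientation rule to every element's primary fibrils.

    Fibril 0 is the computed fibril; fibril 1 copies its new direction;
    fibrils 2 and 3 are the mirror image across the y-z plane.
    Secondary fibrils do not reorient.
    """
    out = fibrils.copy()
    lams_all, dirs_all = strain.element_principal
    E_all = strain.element_E
    for e in range(fibrils.n_elements):
        lams = lams_all[e]
        if lams[0] <= 0.0:
            continue
        cands = preferred_directions(lams, dirs_all[e])
        e_f = fibrils.primary_dirs[e, 0]
        eps_f = kinematics.fibril_strain(E_all[e], e_f,
                                         params.fibril_strain_measure)
        new = reorientation_step(e_f, cands, eps_f, params)
        if new is e_f or np.array_equal(new, e_f):
            continue  # no rotation fired; leave the set bitwise unchanged
        out.primary_dirs[e, 0] = new
        out.primary_dirs[e, 1] = new
        out.primary_dirs[e, 2] = _mirror_x(new)
        out.primary_dirs[e, 3] = _mirror_x(new)
    return out
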