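"""Strain measures derived from the deformation gradient.

All adaptive rules of the degeneration loop consume quantities computed
here: the Green–Lagrange strain tensor evaluated in the reference
(Lagrangian) frame, its principal values and directions, the tensile
strain of a material line element along a fibril direction, and the
maximum shear strain (largest pairwise difference of principal strains).

Functions accept either a single tensor or a leading batch axis; the
batched forms are what the finite-element stage uses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "green_lagrange_strain",
    "principal_decomposition",
    "fibril_strain",
    "max_shear_strain",
]

_I3 = np.eye(3)


def green_lagrange_strain(F: np.ndarray) -> np.ndarray:
    """Green–Lagrange strain E = (FᵀF − I)/2.

    Parameters
    ----------
    F : (..., 3, 3) array
        Deformation gradient(s); ``det(F)`` must be positive.

    Returns
    -------
    (..., 3, 3) array, symmetric by construction.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError(f"F must be (...,3,3), got {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite entries in deformation gradient")
    if np.any(np.linalg.det(F) <= 0.0):
        raise ValueError("det(F) must be positive (orientation-preserving)")
    C = np.swapaxes(F, -1, -2) @ F
    E = 0.5 * (C - _I3)
    # symmetrise away floating-point asymmetry from the matmul
    return 0.5 * (E + np.swapaxes(E, -1, -2))


def _fix_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip eigenvector sign so its first non-negligible component is > 0."""
    v = v.copy()
    for i in range(3):
        if abs(v[i]) > tol:
            if v[i] < 0:
                v = -v
            break
    return v


def principal_decomposition(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal strains and directions of a symmetric strain tensor.

    Returns ``(lams, dirs)`` with eigenvalues sorted descending
    (λ₁ ≥ λ₂ ≥ λ₃) and ``dirs[j]`` the unit eigenvector of ``lams[j]``.
    Each eigenvector's sign is fixed deterministically (first nonzero
    component positive) so downstream rotation rules are reproducible.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (3, 3):
        raise ValueError("principal_decomposition expects a single 3x3 tensor")
    if not np.allclose(E, E.T, atol=1e-10):
        raise ValueError("strain tensor must be symmetric")
    w, V = np.linalg.eigh(0.5 * (E + E.T))
    order = np.argsort(w)[::-1]
    lams = w[order]
    dirs = np.stack([_fix_sign(V[:, j]) for j in order], axis=0)
    return lams, dirs


def fibril_strain(E: np.ndarray, e_f: np.ndarray, measure: str = "nominal") -> float:
    """Tensile strain experienced by a fibril with reference direction ``e_f``.

    ``measure="nominal"`` (default) returns the engineering strain of the
    material line element along ``e_f``::

        ε_f = sqrt(1 + 2 e_fᵀ E e_f) − 1

    which is the stretch of that line minus one.  ``measure="green"``
    returns the Green–Lagrange normal strain ``e_fᵀ E e_f`` instead; both
    agree to first order and share the same sign.
    """
    e_f = np.asarray(e_f, dtype=float)
    if abs(np.linalg.norm(e_f) - 1.0) > 1e-8:
        raise ValueError("fibril direction must be a unit vector")
    Eff = float(e_f @ np.asarray(E, dtype=float) @ e_f)
    if measure == "green":
        return Eff
    if measure != "nominal":
        raise ValueError(f"unknown fibril strain measure {measure!r}")
    arg = 1.0 + 2.0 * Eff
    if arg <= 0.0:
        raise ValueError("degenerate deformation: line element annihilated")
    return float(np.sqrt(arg) - 1.0)


def fibril_strain_batch(E: np.ndarray, dirs: np.ndarray, measure: str = "nominal") -> np.ndarray:
    """Vectorised :func:`fibril_strain`.

    ``E`` is ``(n, 3, 3)``, ``dirs`` is ``(n, k, 3)``; returns ``(n, k)``.
    Degenerate line elements (stretch² ≤ 0) are clipped to full
    annihilation (strain −1) rather than raising, so the element-wise
    degradation rules stay total on pathological fields.
    """
    Eff = np.einsum("nki,nij,nkj->nk", dirs, E, dirs)
    if measure == "green":
        return Eff
    return np.sqrt(np.clip(1.0 + 2.0 * Eff, 0.0, None)) - 1.0


def max_shear_strain(l1: float, l2: float, l3: float) -> float:
    """Maximum shear strain: largest pairwise |λ_i − λ_j| of principal strains."""
    return float(max(abs(l1 - l2), abs(l1 - l3), abs(l2 - l3)))


def max_shear_strain_batch(lams: np.ndarray) -> np.ndarray:
    """Batched max shear strain from ``(n, 3)`` principal values."""
    lams = np.asarray(lams, dtype=float)
    return lams.max(axis=-1) - lams.min(axis=-1)
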