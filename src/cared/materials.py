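"""Depth-dependent composition profiles and FRPVES-lite material law.

The mechanics stage uses a fibril-reinforced poroelastic swelling
description reduced to what the adaptive loop consumes: a compressible
neo-Hookean non-fibrillar matrix, exponential-toe tension-only fibril stress
weighted by per-fibril relative density shares, ideal Donnan osmotic
pressure from the fixed charge density and the external bath salt, and
a stiff volumetric penalty that renders the fast (0.1 s) compression
ramp effectively undrained.  All parameters are configuration-driven
approximations of a full fibril-reinforced poro-viscoelastic swelling
parameter set; the defaults below are calibrated once so an intact
explant's equilibrium modulus lands near the 1.6 MPa typical of
healthy bovine explants.

Depth profiles are given as polynomials in the normalised depth
ẑ ∈ [0, 1] measured from the articular surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialProfiles", "donnan_pressure"]

# R·T at 310 K expressed in MPa per (mEq/ml) of ion concentration
RT_MPA_PER_MEQ_ML = 8.314 * 310.0 * 1e-3


def _polyval(coeffs: tuple[float, ...], z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(z, dtype=float))
    for k, c in enumerate(coeffs):
        out = out + c * np.asarray(z, dtype=float) ** k
    return out


@dataclass
class MaterialProfiles:
    """Material parameters and depth profiles of the explant model."""

    # non-fibrillar matrix (neo-Hookean); the local stiffness is scaled
    # by the solid volume fraction (1 − n_f0)/matrix_solid_ref, so the
    # water-rich superficial zone is the softest
    E_matrix: float = 0.70          # [MPa] at solid fraction matrix_solid_ref
    nu_matrix: float = 0.15
    matrix_solid_ref: float = 0.2

    # collagen fibrils: tension-only exponential-toe stress per unit
    # relative density, σ = k1·(exp(k2·ε) − 1), linearised beyond eps_lin
    fibril_k1: float = 0.16         # [MPa]
    fibril_k2: float = 60.0         # [-]
    fibril_eps_lin: float = 0.15    # toe→linear transition strain
    # density fraction carried by the 4 primary fibrils; the classical
    # arcade description weighs each primary ~3× a secondary fibril:
    # 4·3/(4·3+13) ≈ 0.48
    primary_split: float = 0.48

    # relative collagen density ρ_z(ẑ): moderate at the surface, lowest
    # mid-depth, highest in the deep zone (the arcade anchorage)
    rho_z_coeffs: tuple[float, ...] = (0.75, -0.5, 1.25)
    # initial fixed charge density [mEq/ml]
    fcd0_coeffs: tuple[float, ...] = (0.11, 0.14)
    # initial fluid volume fraction
    nf0_coeffs: tuple[float, ...] = (0.90, -0.25)

    # Donnan osmotic pressure
    external_salt: float = 0.15     # bath concentration [mEq/ml] (≈150 mM NaCl)
    osmotic_coefficient: float = 0.9

    # volumetric penalty making the fast ramp effectively undrained
    K_undrained: float = 100.0      # [MPa]

    # permeability metadata (the equilibrium solver works in the drained /
    # undrained limits, so these only document the transport regime)
    permeability_k0: float = 2e-3   # [mm⁴/(N·s)]
    permeability_M: float = 5.0     # strain-dependence exponent

    def rho_z(self, z_norm: np.ndarray) -> np.ndarray:
        return _polyval(self.rho_z_coeffs, z_norm)

    def FCD0(self, z_norm: np.ndarray) -> np.ndarray:
        return _polyval(self.fcd0_coeffs, z_norm)

    def n_f0(self, z_norm: np.ndarray) -> np.ndarray:
        return _polyval(self.nf0_coeffs, z_norm)

    def matrix_scale(self, z_norm: np.ndarray) -> np.ndarray:
        """Depth factor on the matrix stiffness from the solid fraction."""
        return (1.0 - self.n_f0(z_norm)) / self.matrix_solid_ref

    @property
    def lame(self) -> tuple[float, float]:
        E, nu = self.E_matrix, self.nu_matrix
        mu = E / (2.0 * (1.0 + nu))
        lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return mu, lam

    def validate(self, z_norm: np.ndarray) -> None:
        for name, vals in (("rho_z", self.rho_z(z_norm)),
                           ("FCD0", self.FCD0(z_norm)),
                           ("n_f0", self.n_f0(z_norm))):
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0.0):
                raise ValueError(f"profile {name} must be finite and positive")
        nf = self.n_f0(z_norm)
        if np.any(nf >= 1.0):
            raise ValueError("fluid fraction profile must stay below 1")
        if not 0.0 <= self.primary_split <= 1.0:
            raise ValueError("primary_split must lie in [0, 1]")


def donnan_pressure(c_F: np.ndarray, external_salt: float,
                    osmotic_coefficient: float = 0.9) -> np.ndarray:
    """Ideal Donnan osmotic pressure difference [MPa].

    π = φ·RT·(√(c_F² + 4c̄²) − 2c̄) with c_F the (non-negative) fixed
    charge density and c̄ the external bath concentration, both in
    mEq/ml.
    """
    c_F = np.maximum(np.asarray(c_F, dtype=float), 0.0)
    c_ext = external_salt
    return osmotic_coefficient * RT_MPA_PER_MEQ_ML * (
        np.sqrt(c_F * c_F + 4.0 * c_ext * c_ext) - 2.0 * c_ext)
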