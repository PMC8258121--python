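"""In-memory containers shared by the simulation stages.

The evolving object of a degeneration run is an :class:`ExplantModel`:
a hexahedral mesh of a cylindrical cartilage explant, a per-element
collagen fibril set (4 primary arcade fibrils + 13 secondary
directions, each carrying a density share), and a per-element
composition state (relative proteoglycan content, fixed charge density,
fluid volume fraction).  A :class:`StrainSnapshot` holds one loading
step's deformation-gradient field and the strain quantities derived
from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import kinematics

LAYERS = ("superficial", "middle", "deep")


@dataclass
class FibrilSet:
    """Per-element collagen fibril directions and density shares.

    ``primary_dirs``  : (n_el, 4, 3) unit vectors (unsigned directions).
    ``secondary_dirs``: (n_el, 13, 3) unit vectors.
    ``primary_density``, ``secondary_density``: matching non-negative
    density shares; their row sum is the element's total relative
    collagen density ρ_z.
    """

    primary_dirs: np.ndarray
    secondary_dirs: np.ndarray
    primary_density: np.ndarray
    secondary_density: np.ndarray

    def copy(self) -> "FibrilSet":
        return FibrilSet(
            self.primary_dirs.copy(),
            self.secondary_dirs.copy(),
            self.primary_density.copy(),
            self.secondary_density.copy(),
        )

    @property
    def n_elements(self) -> int:
        return self.primary_dirs.shape[0]

    @property
    def rho_z(self) -> np.ndarray:
        """Total relative collagen density per element (sum of shares)."""
        return self.primary_density.sum(axis=1) + self.secondary_density.sum(axis=1)

    @property
    def all_dirs(self) -> np.ndarray:
        """(n_el, 17, 3) all fibril directions, primary first."""
        return np.concatenate([self.primary_dirs, self.secondary_dirs], axis=1)

    @property
    def all_density(self) -> np.ndarray:
        return np.concatenate([self.primary_density, self.secondary_density], axis=1)

    def validate(self) -> None:
        for dirs in (self.primary_dirs, self.secondary_dirs):
            norms = np.linalg.norm(dirs, axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise ValueError("fibril directions must be unit vectors")
        if np.any(self.primary_density < 0) or np.any(self.secondary_density < 0):
            raise ValueError("fibril density shares must be non-negative")


@dataclass
class CompositionState:
    """Per-element proteoglycan-linked composition.

    Invariants maintained by the update rules: ``0 ≤ PG_rel ≤ 1``,
    ``FCD == FCD0 * PG_rel`` exactly, ``n_f0 ≤ n_f ≤ 1``.
    """

    PG_rel: np.ndarray          # relative PG content, initially 1
    FCD0: np.ndarray            # initial fixed charge density [mEq/ml]
    FCD: np.ndarray             # current fixed charge density [mEq/ml]
    n_f0: np.ndarray            # initial fluid volume fraction
    n_f: np.ndarray             # current fluid volume fraction

    @classmethod
    def initial(cls, FCD0: np.ndarray, n_f0: np.ndarray) -> "CompositionState":
        FCD0 = np.asarray(FCD0, dtype=float)
        n_f0 = np.asarray(n_f0, dtype=float)
        return cls(np.ones_like(FCD0), FCD0, FCD0.copy(), n_f0, n_f0.copy())

    def copy(self) -> "CompositionState":
        return CompositionState(
            self.PG_rel.copy(), self.FCD0.copy(), self.FCD.copy(),
            self.n_f0.copy(), self.n_f.copy(),
        )


@dataclass
class StrainSnapshot:
    """Deformation gradients for one loading step plus derived strains.

    The field lives at integration points: ``ip_F`` is (n_ip, 3, 3),
    ``ip_coords`` the reference coordinates of each point [mm] and
    ``ip_element`` maps points to elements.  The finite-element stage
    produces 8 Gauss points per element; the synthetic provider one
    point per element (the centroid).  Element-level quantities are
    means over an element's points.
    """

    ip_F: np.ndarray
    ip_coords: np.ndarray
    ip_element: np.ndarray
    n_elements: int

    @cached_property
    def ip_E(self) -> np.ndarray:
        return kinematics.green_lagrange_strain(self.ip_F)

    @cached_property
    def element_E(self) -> np.ndarray:
        """(n_el, 3, 3) element-mean Green–Lagrange strain."""
        out = np.zeros((self.n_elements, 3, 3))
        counts = np.bincount(self.ip_element, minlength=self.n_elements).astype(float)
        for i in range(3):
            for j in range(3):
                out[:, i, j] = np.bincount(
                    self.ip_element, weights=self.ip_E[:, i, j],
                    minlength=self.n_elements) / counts
        return out

    @cached_property
    def element_principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted principal strains (n_el, 3) and directions (n_el, 3, 3)."""
        E = 0.5 * (self.element_E + np.swapaxes(self.element_E, -1, -2))
        w, V = np.linalg.eigh(E)
        lams = w[:, ::-1]
        dirs = np.swapaxes(V, -1, -2)[:, ::-1, :]
        # deterministic sign: first component with |v|>1e-12 positive
        for k in range(3):
            v = dirs[:, k, :]
            lead = np.where(np.abs(v[:, 0]) > 1e-12, v[:, 0],
                            np.where(np.abs(v[:, 1]) > 1e-12, v[:, 1], v[:, 2]))
            dirs[:, k, :] = v * np.where(lead < 0, -1.0, 1.0)[:, None]
        return lams, dirs

    def element_F_flat(self) -> np.ndarray:
        """(n_el, 9) element-mean deformation gradient, row-major."""
        out = np.zeros((self.n_elements, 9))
        counts = np.bincount(self.ip_element, minlength=self.n_elements).astype(float)
        flat = self.ip_F.reshape(-1, 9)
        for k in range(9):
            out[:, k] = np.bincount(self.ip_element, weights=flat[:, k],
                                    minlength=self.n_elements) / counts
        return out

    @cached_property
    def ip_eps_max(self) -> np.ndarray:
        """Maximum shear strain at each integration point."""
        w = np.linalg.eigvalsh(self.ip_E)
        return w[:, -1] - w[:, 0]


@dataclass
class ExplantModel:
    """Mesh + fibril architecture + composition: the evolving state."""

    mesh: "HexMesh"               # noqa: F821 - defined in cared.mesh
    fibrils: FibrilSet
    composition: CompositionState
    profiles: "MaterialProfiles"  # noqa: F821 - defined in cared.materials

    def copy(self) -> "ExplantModel":
        return ExplantModel(self.mesh, self.fibrils.copy(),
                            self.composition.copy(), self.profiles)
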