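"""Strain providers: pluggable sources of deformation-gradient fields.

The degeneration loop only needs a per-element deformation-gradient
snapshot per iteration.  Three providers satisfy that contract:

* the reference finite-element stage (:func:`cared.fe.solve_load_step`);
* a deterministic synthetic provider that realises requested per-layer
  principal strains (plus an optional Gaussian defect-tip
  amplification blob) as pure-stretch deformation gradients — used to
  exercise every adaptive rule without finite elements;
* an external reader that takes per-element tensors from a VTK
  unstructured-grid file's ``deformation_gradient`` cell-data array.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import fe
from .model import ExplantModel, StrainSnapshot

__all__ = ["SyntheticStrainProfile", "synthetic_strain_provider",
           "FELiteProvider", "SyntheticProvider", "ExternalVTKProvider"]


@dataclass
class GaussianBlob:
    """Local amplification of strain around a point (e.g. a lesion tip).

    Adds a traceless stretch/compression pair whose maximum shear
    strain contribution is ``amplitude`` at the centre, decaying as a
    Gaussian of width ``sigma``.
    """

    center: tuple[float, float, float]
    sigma: float          # [mm]
    amplitude: float      # peak added maximum shear strain


@dataclass
class SyntheticStrainProfile:
    """Per-layer principal strain triples with optional tip blob.

    ``layer_strains`` maps layer names (superficial/middle/deep) to
    (λ₁, λ₂, λ₃) Green–Lagrange principal strains; ``layer_dirs`` maps
    to 3×3 row-stacked principal directions (default: x, y, z axes).
    """

    layer_strains: dict[str, tuple[float, float, float]] = dc_field(
        default_factory=dict)
    layer_dirs: dict[str, np.ndarray] = dc_field(default_factory=dict)
    blob: GaussianBlob | None = None


def _stretch_from_strain(E: np.ndarray) -> np.ndarray:
    """Pure-stretch F with Green–Lagrange strain E (symmetric sqrt of C)."""
    C = 2.0 * E + np.eye(3)
    w, V = np.linalg.eigh(C)
    if np.any(w <= 0.0):
        raise ValueError(
            "invalid synthetic profile: requested principal stretch ≤ -1")
    return (V * np.sqrt(w)) @ V.T


def synthetic_strain_provider(model: ExplantModel,
                              profile: SyntheticStrainProfile) -> StrainSnapshot:
    """Deterministic per-element snapshot realising the requested strains.

    One integration point per element (the centroid).  The round trip
    through the strain kinematics recovers the requested principal
    values exactly (pure stretch, no rotation part).
    """
    mesh = model.mesh
    n_el = mesh.n_elements
    names = mesh.layer_names()
    F = np.tile(np.eye(3), (n_el, 1, 1))
    E = np.zeros((n_el, 3, 3))
    for lname, lam in profile.layer_strains.items():
        dirs = np.asarray(profile.layer_dirs.get(lname, np.eye(3)), float)
        El = sum(l * np.outer(d, d) for l, d in zip(lam, dirs))
        E[names == lname] = El
    if profile.blob is not None:
        b = profile.blob
        d2 = np.sum((mesh.centroids - np.asarray(b.center)) ** 2, axis=1)
        g = 0.5 * b.amplitude * np.exp(-d2 / (2.0 * b.sigma ** 2))
        E[:, 0, 0] += g
        E[:, 2, 2] -= g
    for e in range(n_el):
        F[e] = _stretch_from_strain(E[e])
    return StrainSnapshot(ip_F=F, ip_coords=mesh.centroids.copy(),
                          ip_element=np.arange(n_el), n_elements=n_el)


class FELiteProvider:
    """Reference provider: the built-in finite-element stage."""

    def __init__(self) -> None:
        self.warm: dict = {}

    def __call__(self, model: ExplantModel,
                 protocol: fe.LoadingProtocol) -> StrainSnapshot:
        return fe.solve_load_step(model, protocol, warm=self.warm)


class SyntheticProvider:
    """Provider wrapping a fixed synthetic profile (protocol ignored)."""

    def __init__(self, profile: SyntheticStrainProfile) -> None:
        self.profile = profile

    def __call__(self, model: ExplantModel, protocol=None) -> StrainSnapshot:
        return synthetic_strain_provider(model, self.profile)


class ExternalVTKProvider:
    """Provider reading per-element deformation gradients from a VTK file."""

    def __init__(self, path: str) -> None:
        self.path = path

    def __call__(self, model: ExplantModel, protocol=None) -> StrainSnapshot:
        from .vtkio import read_vtk
        _, conn, cell_data = read_vtk(self.path)
        if "deformation_gradient" not in cell_data:
            raise ValueError(
                "VTK file lacks the 'deformation_gradient' cell-data array")
        Fflat = cell_data["deformation_gradient"]
        n_el = model.mesh.n_elements
        if Fflat.shape != (n_el, 9):
            raise ValueError(
                f"deformation_gradient shape {Fflat.shape} does not match "
                f"the model's {n_el} elements")
        return StrainSnapshot(ip_F=Fflat.reshape(n_el, 3, 3),
                              ip_coords=model.mesh.centroids.copy(),
                              ip_element=np.arange(n_el), n_elements=n_el)
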