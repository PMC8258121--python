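"""Declarative scenario configuration (YAML + schema validation).

A scenario bundles explant geometry, loading protocol, material
profiles, adaptive-rule parameters, provider selection, output
location and the seed.  Unknown keys are rejected.  The five study
scenarios are available as named presets:

* ``reference`` — intact explant, 2 MPa ramp in 0.1 s;
* ``injurious`` — intact explant, 4 MPa ramp in 0.1 s;
* ``icrs1`` / ``icrs2`` / ``icrs3`` — 100 / 380 / 750 μm deep,
  20 μm wide full-diameter lesions under the 2 MPa ramp.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .degradation import DegradationParams
from .experiments import AdaptiveConfig
from .fe import LoadingProtocol
from .fibrils import init_fibril_architecture
from .materials import MaterialProfiles
from .mesh import DefectSpec, ExplantGeometry, build_explant_mesh
from .model import CompositionState, ExplantModel
from .pg_depletion import NonlocalParams
from .reorientation import ReorientationParams

__all__ = ["ScenarioConfig", "load_config", "dump_config", "preset",
           "PRESETS", "build_model"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DefectConfig(_Strict):
    depth_um: float = Field(gt=0)
    width_um: float = Field(default=20.0, gt=0)


class GeometryConfig(_Strict):
    height_mm: float = Field(default=1.5, gt=0)
    radius_mm: float = Field(default=1.5, gt=0)
    defect: Optional[DefectConfig] = None
    superficial_fraction: float = Field(default=0.12, gt=0, lt=1)
    middle_fraction: float = Field(default=0.33, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self):
        if self.defect is not None and \
                self.defect.depth_um >= self.height_mm * 1000.0:
            raise ValueError("defect.depth_um must be smaller than the height")
        return self


class ProtocolConfig(_Strict):
    pressure_mpa: float = Field(default=2.0, ge=0)
    ramp_time_s: float = Field(default=0.1, gt=0)
    friction_mu: float = Field(default=0.05, ge=0)
    mode: Literal["normal", "injurious", "stress_relaxation"] = "normal"


class MaterialConfig(_Strict):
    E_matrix: float = Field(default=0.70, gt=0)
    nu_matrix: float = Field(default=0.15, ge=0, lt=0.5)
    matrix_solid_ref: float = Field(default=0.2, gt=0, lt=1)
    fibril_k1: float = Field(default=0.16, gt=0)
    fibril_k2: float = Field(default=60.0, gt=0)
    fibril_eps_lin: float = Field(default=0.15, gt=0)
    primary_split: float = Field(default=0.48, ge=0, le=1)
    rho_z_coeffs: tuple[float, ...] = (0.75, -0.5, 1.25)
    fcd0_coeffs: tuple[float, ...] = (0.11, 0.14)
    nf0_coeffs: tuple[float, ...] = (0.90, -0.25)
    external_salt: float = Field(default=0.15, gt=0)
    osmotic_coefficient: float = Field(default=0.9, gt=0, le=1)
    K_undrained: float = Field(default=100.0, gt=0)

    def to_profiles(self) -> MaterialProfiles:
        return MaterialProfiles(**self.model_dump())


class AdaptiveSettings(_Strict):
    n_iterations: int = Field(default=50, ge=1)
    early_stop_tol: Optional[float] = None
    kappa: float = Field(default=0.3, ge=0, le=1)
    alpha_min_deg: float = Field(default=1.0, gt=0)
    K0_f: float = Field(default=0.10, gt=0)
    m_coll: float = Field(default=1.0, gt=0)
    degradation_variant: Literal["printed", "complement"] = "printed"
    K0_PG: float = Field(default=0.30, gt=0)
    nonlocal_l_mm: Optional[float] = None   # default: 0.12 × height
    fibril_strain_measure: Literal["nominal", "green"] = "nominal"

    def to_adaptive(self, height_mm: float, seed: int) -> AdaptiveConfig:
        l = self.nonlocal_l_mm if self.nonlocal_l_mm is not None \
            else 0.12 * height_mm
        return AdaptiveConfig(
            n_iterations=self.n_iterations,
            early_stop_tol=self.early_stop_tol,
            reorientation=ReorientationParams(
                kappa=self.kappa, alpha_min_deg=self.alpha_min_deg,
                fibril_strain_measure=self.fibril_strain_measure),
            degradation=DegradationParams(
                K0_f=self.K0_f, m_coll=self.m_coll,
                variant=self.degradation_variant,
                fibril_strain_measure=self.fibril_strain_measure),
            nonlocal_params=NonlocalParams(l=l, K0_PG=self.K0_PG),
            seed=seed,
        )


class ScenarioConfig(_Strict):
    name: str = "custom"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    adaptive: AdaptiveSettings = Field(default_factory=AdaptiveSettings)
    target_elements: int = Field(default=360, ge=200)
    seed: int = 0
    out_dir: str = "cared_out"
    provider: Literal["fe_lite", "synthetic", "external_vtk"] = "fe_lite"
    external_vtk_path: Optional[str] = None

    def to_geometry(self) -> ExplantGeometry:
        d = None
        if self.geometry.defect is not None:
            d = DefectSpec(depth_um=self.geometry.defect.depth_um,
                           width_um=self.geometry.defect.width_um)
        return ExplantGeometry(
            height=self.geometry.height_mm, radius=self.geometry.radius_mm,
            defect=d, superficial_fraction=self.geometry.superficial_fraction,
            middle_fraction=self.geometry.middle_fraction)

    def to_protocol(self) -> LoadingProtocol:
        return LoadingProtocol(pressure=self.protocol.pressure_mpa,
                               ramp_time=self.protocol.ramp_time_s,
                               friction_mu=self.protocol.friction_mu,
                               mode=self.protocol.mode)

    def to_adaptive(self) -> AdaptiveConfig:
        return self.adaptive.to_adaptive(self.geometry.height_mm, self.seed)


PRESETS: dict[str, dict] = {
    "reference": {"name": "reference",
                  "protocol": {"pressure_mpa": 2.0, "mode": "normal"}},
    "injurious": {"name": "injurious",
                  "protocol": {"pressure_mpa": 4.0, "mode": "injurious"}},
    "icrs1": {"name": "icrs1",
              "geometry": {"defect": {"depth_um": 100.0}},
              "protocol": {"pressure_mpa": 2.0}},
    "icrs2": {"name": "icrs2",
              "geometry": {"defect": {"depth_um": 380.0}},
              "protocol": {"pressure_mpa": 2.0}},
    "icrs3": {"name": "icrs3",
              "geometry": {"defect": {"depth_um": 750.0}},
              "protocol": {"pressure_mpa": 2.0}},
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """Named study scenario, optionally with top-level field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    data = {**PRESETS[name], **overrides}
    return ScenarioConfig.model_validate(data)


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping")
    if "preset" in raw:
        name = raw.pop("preset")
        base = dict(PRESETS[name])
        base.update(raw)
        raw = base
    return ScenarioConfig.model_validate(raw)


def dump_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def build_model(config: ScenarioConfig) -> ExplantModel:
    """Construct the explant model a scenario describes."""
    geom = config.to_geometry()
    mesh = build_explant_mesh(geom, config.target_elements)
    profiles = config.material.to_profiles()
    profiles.validate(mesh.z_norm)
    fibrils = init_fibril_architecture(mesh, profiles, seed=config.seed)
    comp = CompositionState.initial(profiles.FCD0(mesh.z_norm),
                                    profiles.n_f0(mesh.z_norm))
    return ExplantModel(mesh=mesh, fibrils=fibrils, composition=comp,
                        profiles=profiles)
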