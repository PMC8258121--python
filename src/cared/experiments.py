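"""Orchestration of the adaptive degeneration loop and its readouts.

One degeneration iteration is: solve the loading step for a
deformation-gradient snapshot, then apply — simultaneously, from the
beginning-of-iteration state — fibril reorientation, collagen
degradation, and non-local proteoglycan depletion with its coupled
fixed-charge-density and hydration updates.  The loop runs a fixed
number of iterations (50 by default, matching the convergence horizon
of the adaptive rules) and records per-layer, volume-weighted summary
curves.  A stress-relaxation characterisation converts a model state
into an equilibrium modulus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import pg_depletion
from .degradation import DegradationParams, apply_collagen_degradation
from .fe import LoadingProtocol, SolverFailure, equilibrium_reaction
from .model import ExplantModel, FibrilSet, LAYERS, StrainSnapshot
from .pg_depletion import NonlocalParams
from .providers import FELiteProvider
from .reorientation import ReorientationParams, update_primary_fibrils

__all__ = ["AdaptiveConfig", "IterationHistory", "run_cared",
           "layer_summary", "equilibrium_modulus"]

log = logging.getLogger(__name__)

METRICS = ("reorientation_deg", "collagen_rel", "fcd_rel", "fluid_frac")
GROUPS = LAYERS + ("bulk",)


@dataclass
class AdaptiveConfig:
    n_iterations: int = 50
    early_stop_tol: float | None = None   # relative change; None = fixed count
    reorientation: ReorientationParams = dc_field(default_factory=ReorientationParams)
    degradation: DegradationParams = dc_field(default_factory=DegradationParams)
    nonlocal_params: NonlocalParams = dc_field(default_factory=NonlocalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


@dataclass
class IterationHistory:
    """Tidy per-iteration, per-layer summary curves.

    ``df`` columns: iteration, layer, metric, value.  Iteration 0 is
    the initial state.  ``failure`` records a mid-loop solver failure,
    in which case the history covers the iterations completed.
    """

    df: pd.DataFrame
    failure: str | None = None

    def series(self, layer: str, metric: str) -> np.ndarray:
        sel = self.df[(self.df.layer == layer) & (self.df.metric == metric)]
        return sel.sort_values("iteration")["value"].to_numpy()

    @property
    def n_iterations(self) -> int:
        return int(self.df.iteration.max())

    def final(self) -> pd.DataFrame:
        last = self.df.iteration.max()
        return self.df[self.df.iteration == last].pivot(
            index="layer", columns="metric", values="value")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _unsigned_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    dots = np.abs(np.einsum("ni,ni->n", a, b))
    return np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))


def layer_summary(model: ExplantModel, reference: ExplantModel) -> pd.DataFrame:
    """Volume-weighted per-layer (and bulk) state relative to a reference.

    Rows: superficial/middle/deep/bulk; columns: mean reorientation
    angle from the reference fibril directions [deg], relative collagen
    density, relative FCD, and fluid volume fraction.
    """
    if model.mesh is not reference.mesh and (
            model.mesh.n_elements != reference.mesh.n_elements
            or not np.array_equal(model.mesh.conn, reference.mesh.conn)):
        raise ValueError("layer_summary requires both states on the same mesh")
    mesh = model.mesh
    ang = _unsigned_angle_deg(model.fibrils.primary_dirs[:, 0],
                              reference.fibrils.primary_dirs[:, 0])
    rho = model.fibrils.rho_z
    rho0 = reference.fibrils.rho_z
    fcd_rel = np.divide(model.composition.FCD, reference.composition.FCD0,
                        out=np.ones_like(rho), where=reference.composition.FCD0 > 0)
    vals = {
        "reorientation_deg": ang,
        "collagen_rel": rho / rho0,
        "fcd_rel": fcd_rel,
        "fluid_frac": model.composition.n_f,
    }
    w = mesh.volumes
    rows = {}
    for g, mask in _group_masks(mesh).items():
        wm = w[mask]
        if wm.sum() == 0.0:   # a coarse mesh may lack a layer entirely
            rows[g] = {m: float("nan") for m in vals}
            continue
        rows[g] = {m: float(np.average(v[mask], weights=wm))
                   for m, v in vals.items()}
    return pd.DataFrame(rows).T.loc[list(GROUPS)]


def _group_masks(mesh) -> dict[str, np.ndarray]:
    masks = {name: mesh.layer == k for k, name in enumerate(LAYERS)}
    masks["bulk"] = np.ones(mesh.n_elements, bool)
    return masks


def _apply_rules(model: ExplantModel, snap: StrainSnapshot,
                 config: AdaptiveConfig) -> None:
    """One simultaneous application of all adaptive rules, in place."""
    reoriented = update_primary_fibrils(model.fibrils, snap,
                                        config.reorientation)
    degraded = apply_collagen_degradation(model.fibrils, snap,
                                          config.degradation)
    model.fibrils = FibrilSet(reoriented.primary_dirs,
                              reoriented.secondary_dirs,
                              degraded.primary_density,
                              degraded.secondary_density)

    nl_ip = pg_depletion.nonlocal_field(snap.ip_eps_max, snap.ip_coords,
                                        config.nonlocal_params)
    eps_nl_el = pg_depletion.element_average(nl_ip, snap.ip_element,
                                             snap.n_elements)
    comp = model.composition
    comp.PG_rel = pg_depletion.update_pg(comp.PG_rel, eps_nl_el,
                                         config.nonlocal_params.K0_PG)
    comp.FCD = pg_depletion.fcd_from_pg(comp.FCD0, comp.PG_rel)
    comp.n_f = pg_depletion.hydration_from_pg(comp.n_f0, comp.PG_rel)


def _history_rows(it: int, summary: pd.DataFrame) -> list[dict]:
    return [{"iteration": it, "layer": g, "metric": m,
             "value": summary.loc[g, m]}
            for g in GROUPS for m in METRICS]


def run_cared(model: ExplantModel, protocol: LoadingProtocol,
              config: AdaptiveConfig, provider=None) -> IterationHistory:
    """Run the adaptive degeneration loop.

    ``provider`` is any callable ``(model, protocol) -> StrainSnapshot``;
    by default the built-in finite-element stage (with warm starting
    across iterations).  The model is updated in place; the returned
    history holds the per-layer summary curves.  On a mid-loop solver
    failure the history up to the last completed iteration is returned
    with the failure recorded.
    """
    if provider is None:
        provider = FELiteProvider()
        _warn_if_coarse(model, config.nonlocal_params.l)
    reference = model.copy()
    rows = _history_rows(0, layer_summary(model, reference))
    failure = None
    prev = None
    for it in range(1, config.n_iterations + 1):
        try:
            snap = provider(model, protocol)
        except SolverFailure as exc:
            failure = f"iteration {it}: {exc} (residual {exc.residual:.3e})"
            log.error(failure)
            break
        _apply_rules(model, snap, config)
        summary = layer_summary(model, reference)
        rows.extend(_history_rows(it, summary))
        log.info("iteration %d: bulk collagen %.4f, bulk FCD %.4f", it,
                 summary.loc["bulk", "collagen_rel"],
                 summary.loc["bulk", "fcd_rel"])
        if config.early_stop_tol is not None and prev is not None:
            delta = float(np.max(np.abs(summary.values - prev.values)
                                 / np.maximum(np.abs(prev.values), 1e-12)))
            if delta < config.early_stop_tol:
                break
        prev = summary
    return IterationHistory(pd.DataFrame(rows), failure=failure)


def _warn_if_coarse(model: ExplantModel, l: float) -> None:
    mesh = model.mesh
    # longest element edge from the 12 hex edges
    edges = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
             (0, 4), (1, 5), (2, 6), (3, 7)]
    X = mesh.nodes[mesh.conn]
    emax = max(float(np.linalg.norm(X[:, a] - X[:, b], axis=1).max())
               for a, b in edges)
    if emax > l:
        warnings.warn(
            f"max element edge {emax:.3f} mm exceeds the non-local "
            f"characteristic length {l:.3f} mm; the damage field may be "
            "under-resolved", RuntimeWarning, stacklevel=3)


def equilibrium_modulus(model: ExplantModel, strain: float = 0.10,
                        warm: dict | None = None) -> float:
    """Equilibrium modulus [MPa] from a simulated stress-relaxation test.

    Free swelling, platen compression of ``strain`` (10% default) and
    drained equilibrium; the modulus is the equilibrium reaction stress
    at the bottom surface divided by the applied strain.
    """
    stress, _ = equilibrium_reaction(model, strain=strain, warm=warm)
    return stress / strain
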