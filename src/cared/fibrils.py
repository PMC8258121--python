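"""Initial collagen fibril architecture of the explant.

Primary fibrils follow a Benninghoff arcade: parallel to the
split-line (±x) at the articular surface, bending through the middle
zone to surface-normal in the deep zone.  Each element also carries 13
secondary fibril directions; the set is drawn once per model from the
seed as 6 uniform hemisphere directions, their mirror images across
the y-z plane, and one direction inside the y-z plane — a
deterministic, exactly mirror-symmetric quasi-isotropic set shared by
all elements.
"""

from __future__ import annotations

import numpy as np

from .materials import MaterialProfiles
from .mesh import HexMesh
from .model import FibrilSet

__all__ = ["arcade_angle", "secondary_direction_set", "init_fibril_architecture"]

N_PRIMARY = 4
N_SECONDARY = 13


def arcade_angle(z_norm: np.ndarray, bend_start: float = 0.12,
                 bend_end: float = 0.45) -> np.ndarray:
    """Angle [rad] of the primary fibril from the surface plane.

    0 (horizontal) through the superficial zone, π/2 (surface-normal)
    in the deep zone, with a smooth cosine bend through the middle zone.
    """
    z = np.asarray(z_norm, dtype=float)
    t = np.clip((z - bend_start) / (bend_end - bend_start), 0.0, 1.0)
    smooth = 0.5 * (1.0 - np.cos(np.pi * t))
    return smooth * (np.pi / 2.0)


def secondary_direction_set(seed: int) -> np.ndarray:
    """13 deterministic unit directions, mirror-symmetric across y-z."""
    rng = np.random.default_rng(seed)
    half = []
    while len(half) < 6:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n < 1e-12:
            continue
        v = v / n
        if v[2] < 0:          # hemisphere: unsigned directions
            v = -v
        if abs(v[0]) < 1e-3:  # keep clear of the mirror plane
            continue
        half.append(v)
    half = np.array(half)
    mirrored = half * np.array([-1.0, 1.0, 1.0])
    inplane = rng.normal(size=3)
    inplane[0] = 0.0
    inplane /= np.linalg.norm(inplane)
    if inplane[2] < 0:
        inplane = -inplane
    return np.vstack([half, mirrored, inplane[None, :]])


def init_fibril_architecture(mesh: HexMesh, profiles: MaterialProfiles,
                             seed: int = 0) -> FibrilSet:
    """Build the per-element fibril set with depth-dependent density."""
    n_el = mesh.n_elements
    theta = arcade_angle(mesh.z_norm)
    d1 = np.stack([np.cos(theta), np.zeros(n_el), np.sin(theta)], axis=1)
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d_mirror = d1 * np.array([-1.0, 1.0, 1.0])
    primary = np.stack([d1, d1, d_mirror, d_mirror], axis=1)

    secondary = np.broadcast_to(secondary_direction_set(seed),
                                (n_el, N_SECONDARY, 3)).copy()

    rho = profiles.rho_z(mesh.z_norm)
    p_share = profiles.primary_split * rho / N_PRIMARY
    s_share = (1.0 - profiles.primary_split) * rho / N_SECONDARY
    primary_density = np.repeat(p_share[:, None], N_PRIMARY, axis=1)
    secondary_density = np.repeat(s_share[:, None], N_SECONDARY, axis=1)

    fs = FibrilSet(primary, secondary, primary_density, secondary_density)
    fs.validate()
    return fs
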