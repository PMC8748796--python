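"""Equal-area 2-D cortical maps via Lambert azimuthal projection.

Each hemisphere's nodes are radially normalized onto a sphere about the
hemisphere centroid and projected with Lambert's azimuthal equal-area
projection about a configurable pole (defaults approximate the lateral
superior directions of central 10-20 electrode positions).  Planar
radii are rescaled by the sphere radius so map coordinates stay in mm,
and the two hemispheres are offset onto disjoint half-planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectomeNetwork

# lateral-superior unit poles (left/right), roughly over the central sulci
DEFAULT_POLE_L = np.array([-0.45, 0.0, 0.893])
DEFAULT_POLE_R = np.array([0.45, 0.0, 0.893])
DEFAULT_POLE_L = DEFAULT_POLE_L / np.linalg.norm(DEFAULT_POLE_L)
DEFAULT_POLE_R = DEFAULT_POLE_R / np.linalg.norm(DEFAULT_POLE_R)


@dataclass
class SurfaceMap:
    """2-D node positions on the projected cortical surface (mm)."""

    coords2d: np.ndarray          # (N, 2)
    hemisphere: np.ndarray        # (N,) 'L'/'R'
    hemisphere_centers: np.ndarray  # (2, 2): map centre of L and R
    sphere_radii: np.ndarray      # (2,) fitted sphere radius per hemisphere
    poles: np.ndarray             # (2, 3) unit pole per hemisphere
    antipodal: np.ndarray = None  # (N,) bool, flagged boundary placements

    @property
    def n_nodes(self) -> int:
        return self.coords2d.shape[0]

    def same_hemisphere(self, j: int) -> np.ndarray:
        return self.hemisphere == self.hemisphere[j]


def _tangent_basis(pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane tangent at the pole."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(pole @ ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, pole)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    return e1, e2


def lambert_azimuthal(unit_dirs: np.ndarray, pole: np.ndarray,
                      antipode_tol: float = 1e-6):
    """Lambert azimuthal equal-area projection of unit vectors about a pole.

    Returns planar coordinates (on the unit sphere: planar radius
    ``2 sin(c/2)`` at angular distance ``c`` from the pole) and a boolean
    flag for points at/near the antipode, which are placed on the
    boundary circle with a warning since their azimuth is undefined.
    """
    pole = np.asarray(pole, dtype=float)
    pole = pole / np.linalg.norm(pole)
    u = np.asarray(unit_dirs, dtype=float)
    cosc = np.clip(u @ pole, -1.0, 1.0)
    c = np.arccos(cosc)
    rho = 2.0 * np.sin(c / 2.0)
    e1, e2 = _tangent_basis(pole)
    az_x = u @ e1
    az_y = u @ e2
    az_norm = np.hypot(az_x, az_y)
    antipodal = (np.pi - c) < antipode_tol
    safe = np.maximum(az_norm, 1e-300)
    xy = np.column_stack([rho * az_x / safe, rho * az_y / safe])
    degen = (az_norm < 1e-12) & ~antipodal  # exactly at the pole
    xy[degen] = 0.0
    if antipodal.any():
        warnings.warn(
            f"{int(antipodal.sum())} node(s) at the projection antipode; "
            "placed on the map boundary with arbitrary azimuth"
        )
        xy[antipodal & (az_norm < 1e-12)] = [2.0, 0.0]
    return xy, antipodal


def project(net: ConnectomeNetwork, pole_L: np.ndarray = DEFAULT_POLE_L,
            pole_R: np.ndarray = DEFAULT_POLE_R) -> SurfaceMap:
    """Project node coordinates onto the 2-D equal-area cortical map.

    Per hemisphere the nodes are normalized to the sphere about the
    hemisphere centroid (radius = mean node distance from it), Lambert
    projected about the hemisphere's pole, scaled back to mm, and offset
    so the left hemisphere occupies x < 0 and the right x > 0.
    """
    poles = {"L": np.asarray(pole_L, float), "R": np.asarray(pole_R, float)}
    for s, p in poles.items():
        if not np.isclose(np.linalg.norm(p), 1.0, atol=1e-6):
            raise ValueError(f"pole for hemisphere {s} must be unit length")
    n = net.n_nodes
    coords2d = np.zeros((n, 2))
    antipodal = np.zeros(n, dtype=bool)
    centers = np.zeros((2, 2))
    radii = np.zeros(2)
    for i, s in enumerate(("L", "R")):
        idx = np.where(net.hemisphere == s)[0]
        if idx.size == 0:
            continue
        pts = net.coords3d[idx]
        centroid = pts.mean(axis=0)
        rel = pts - centroid
        norms = np.linalg.norm(rel, axis=1)
        if np.any(norms < 1e-9):
            raise ValueError("node coincides with hemisphere centroid")
        radius = float(norms.mean())
        xy, anti = lambert_azimuthal(rel / norms[:, None], poles[s])
        # offset so hemispheres land on disjoint half-planes (|xy| <= 2R)
        offset = np.array([-2.5 * radius if s == "L" else 2.5 * radius, 0.0])
        coords2d[idx] = xy * radius + offset
        antipodal[idx] = anti
        centers[i] = offset
        radii[i] = radius
    return SurfaceMap(
        coords2d=coords2d,
        hemisphere=net.hemisphere.copy(),
        hemisphere_centers=centers,
        sphere_radii=radii,
        poles=np.vstack([poles["L"], poles["R"]]),
        antipodal=antipodal,
    )
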