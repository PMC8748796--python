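"""Local phase gradients, propagation speed/direction, and source-sink index.

The spatial gradient of the relative-phase field is estimated per node
by circular-linear regression: within a Gaussian window (SD
``window_sigma`` mm, same hemisphere only) the planar phase model
``theta(x) ~ phi0 + a . (x - x_j)`` is fitted by maximizing the weighted
mean resultant length

    F(a) = | sum_i w_i exp(i (theta_i - a . dx_i)) |

which is immune to phase wrapping.  The maximization runs a coarse
gradient-vector grid bounded by a propagation-speed floor, two local
grid refinements, and a damped Newton polish to machine precision.

Speeds follow the contour identity ``v = |dtheta/dt| / |grad theta|``;
the propagation direction points down-gradient (from phase-leading to
phase-lagging regions) for advancing phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import SurfaceMap
from .simulate import PhaseTrajectory

MIN_GRAD = 1e-4  # rad/mm; below this a patch counts as near-synchronous


@dataclass
class WaveField:
    """Per-sample, per-node wave descriptors on the 2-D map."""

    gradients: np.ndarray   # (S, N, 2) rad/mm, NaN where the fit failed
    speeds: np.ndarray      # (S, N) m/s, NaN where |grad| < MIN_GRAD
    prop_dirs: np.ndarray   # (S, N, 2) unit vectors, NaN where undefined
    inst_rates: np.ndarray  # (S, N) rad/s
    window_sigma: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.speeds)

    def propagation_field(self, sample: int, raw_gradient: bool = False) -> np.ndarray:
        """Outward-positive propagation field for one sample (rad/mm).

        By default this is the negated phase gradient, sign-corrected by
        the instantaneous rate, so wave sources (phase-leading centres of
        radial waves) score positive in the source-sink index.  With
        ``raw_gradient=True`` the unnegated gradient is returned.
        """
        g = self.gradients[sample]
        if raw_gradient:
            return g.copy()
        return -g * np.sign(self.inst_rates[sample])[:, None]


def _newton_polish(a, E, dx, n_iter=6):
    """Damped Newton refinement of F(a)^2 = |sum E_i exp(-i a.dx_i)|^2.

    ``a``: (S, 2) start points; ``E``: (S, nb) complex weighted phasors
    w_i exp(i theta_i); ``dx``: (nb, 2).  Vectorized over samples.
    """
    def components(a):
        ph = np.exp(-1j * (a @ dx.T))          # (S, nb)
        T = E * ph
        C = T.sum(axis=1)                       # (S,)
        dC = -1j * (T @ dx)                     # (S, 2)
        d2 = -np.einsum("si,im,in->smn", T, dx, dx)  # (S, 2, 2)
        return C, dC, d2

    C, dC, d2 = components(a)
    F2 = np.abs(C) ** 2
    for _ in range(n_iter):
        grad = 2.0 * (np.conj(C)[:, None] * dC).real          # (S, 2)
        H = 2.0 * ((np.conj(dC)[:, :, None] * dC[:, None, :]).real
                   + (np.conj(C)[:, None, None] * d2).real)
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        ok = np.abs(det) > 1e-300
        step = np.zeros_like(a)
        step[ok, 0] = -(H[ok, 1, 1] * grad[ok, 0] - H[ok, 0, 1] * grad[ok, 1]) / det[ok]
        step[ok, 1] = -(H[ok, 0, 0] * grad[ok, 1] - H[ok, 1, 0] * grad[ok, 0]) / det[ok]
        # line-search damping: never accept a step that lowers F^2
        trial = a + step
        improved = np.zeros(a.shape[0], dtype=bool)
        for _half in range(8):
            C_t = (E * np.exp(-1j * (trial @ dx.T))).sum(axis=1)
            F2_t = np.abs(C_t) ** 2
            better = F2_t >= F2 - 1e-15
            newly = better & ~improved
            a[newly] = trial[newly]
            F2[newly] = F2_t[newly]
            improved |= better
            if improved.all():
                break
            trial = np.where(improved[:, None], trial, a + (trial - a) * 0.5)
        C, dC, d2 = components(a)
        F2 = np.abs(C) ** 2
    return a


def _fit_node(phases, dx, w, amax, coarse=21, refine=7):
    """Fit gradient vectors for one node across all samples.

    phases: (S, nb) neighbour phases; dx: (nb, 2) offsets from the node;
    w: (nb,) Gaussian weights.  Returns (S, 2) gradients.
    """
    E = w[None, :] * np.exp(1j * phases)  # (S, nb)
    ax = np.linspace(-amax, amax, coarse)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])          # (G, 2)
    M = np.exp(-1j * (grid @ dx.T))                           # (G, nb)
    F = np.abs(E @ M.T)                                       # (S, G)
    best = grid[np.argmax(F, axis=1)]                         # (S, 2)
    spacing = ax[1] - ax[0]
    for _ in range(2):
        off = np.linspace(-spacing, spacing, refine)
        ox, oy = np.meshgrid(off, off, indexing="ij")
        offsets = np.column_stack([ox.ravel(), oy.ravel()])   # (g, 2)
        cand = best[:, None, :] + offsets[None, :, :]         # (S, g, 2)
        shift = np.einsum("sgm,im->sgi", cand, dx)
        Fl = np.abs(np.einsum("si,sgi->sg", E, np.exp(-1j * shift)))
        best = np.take_along_axis(
            cand, np.argmax(Fl, axis=1)[:, None, None], axis=1
        )[:, 0, :]
        spacing = off[1] - off[0]
    return _newton_polish(best.copy(), E, dx)


def fit_phase_gradients(smap: SurfaceMap, phases: np.ndarray,
                        window_sigma: float = 20.0,
                        amax: float | None = None,
                        max_radius_sigmas: float = 3.0,
                        min_neighbors: int = 3) -> np.ndarray:
    """Circular-linear phase gradients for a (S, N) phase array.

    Returns (S, N, 2) gradient vectors in rad/mm; NaN where the node's
    neighbourhood is degenerate (fewer than ``min_neighbors`` in-window
    same-hemisphere neighbours, or collinear geometry).
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    S, n = phases.shape
    if amax is None:
        amax = 0.15  # rad/mm; generous bound ~ 24 Hz wave at the 1 m/s floor
    out = np.full((S, n, 2), np.nan)
    coords = smap.coords2d
    for j in range(n):
        same = smap.hemisphere == smap.hemisphere[j]
        dx_all = coords[same] - coords[j]
        r = np.linalg.norm(dx_all, axis=1)
        keep = r <= max_radius_sigmas * window_sigma
        dx = dx_all[keep]
        if dx.shape[0] < min_neighbors:
            continue
        w = np.exp(-(r[keep] ** 2) / (2.0 * window_sigma**2))
        # collinearity check on the weighted scatter of offsets
        cov = (dx * w[:, None]).T @ dx / w.sum()
        if np.linalg.eigvalsh(cov)[0] < 1e-6 * max(np.linalg.eigvalsh(cov)[1], 1e-30):
            continue
        out[:, j, :] = _fit_node(phases[:, np.where(same)[0][keep]], dx, w, amax)
    return out


def phase_gradient(smap: SurfaceMap, rel_phases_snapshot: np.ndarray,
                   window_sigma: float = 20.0, **kwargs) -> np.ndarray:
    """Gradient vectors (N, 2) for a single phase snapshot."""
    return fit_phase_gradients(smap, rel_phases_snapshot[None, :],
                               window_sigma=window_sigma, **kwargs)[0]


def wave_speed(grad: np.ndarray, inst_rate: float,
               min_grad: float = MIN_GRAD):
    """Propagation speed (m/s) and unit direction from the contour identity.

    speed = |dtheta/dt| / |grad|, with the direction pointing from
    phase-leading to phase-lagging regions (``-grad`` for advancing
    phase).  Near-synchronous patches (|grad| below ``min_grad`` rad/mm)
    return NaN speed and direction.
    """
    grad = np.asarray(grad, dtype=float)
    norm = float(np.linalg.norm(grad))
    if not np.isfinite(norm) or norm < min_grad:
        return float("nan"), np.array([np.nan, np.nan])
    speed = abs(float(inst_rate)) / norm / 1000.0  # (rad/s)/(rad/mm) -> m/s
    direction = -grad / norm * np.sign(inst_rate) if inst_rate != 0 else -grad / norm
    return speed, direction


def compute_wave_field(smap: SurfaceMap, traj: PhaseTrajectory,
                       window_sigma: float = 20.0,
                       min_grad: float = MIN_GRAD,
                       amax: float | None = None) -> WaveField:
    """Estimate gradients, speeds and propagation directions for all samples."""
    if amax is None:
        # speed floor of 1 m/s at the run's mean frequency, with margin
        amax = 1.5 * 2.0 * np.pi * traj.config.f0 / 1000.0 if traj.config else 0.15
    grads = fit_phase_gradients(smap, traj.rel_phases,
                                window_sigma=window_sigma, amax=amax)
    norms = np.linalg.norm(grads, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        speeds = np.abs(traj.inst_rates) / norms / 1000.0
        speeds[~(norms >= min_grad)] = np.nan
        dirs = -grads / norms[..., None] * np.sign(traj.inst_rates)[..., None]
        dirs[~(norms >= min_grad)] = np.nan
    return WaveField(gradients=grads, speeds=speeds, prop_dirs=dirs,
                     inst_rates=traj.inst_rates.copy(), window_sigma=window_sigma)


def mean_direction_map(field: WaveField, min_resultant: float = 1e-3):
    """Circular mean propagation direction and circular SD per node.

    Uses all samples with a valid direction; nodes whose mean resultant
    length falls below ``min_resultant`` (e.g. opposite directions in
    equal number) get NaN direction and SD, flagged as undefined.
    """
    angles = np.arctan2(field.prop_dirs[..., 1], field.prop_dirs[..., 0])
    valid = np.isfinite(angles)
    z = np.where(valid, np.exp(1j * np.where(valid, angles, 0.0)), 0.0)
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_z = z.sum(axis=0) / counts
    resultant = np.abs(mean_z)
    defined = (counts >= 2) & (resultant >= min_resultant)
    mean_angle = np.where(defined, np.angle(mean_z), np.nan)
    circ_sd = np.where(
        defined, np.sqrt(np.maximum(-2.0 * np.log(np.maximum(resultant, 1e-300)), 0.0)),
        np.nan,
    )
    mean_dir = np.column_stack([np.cos(mean_angle), np.sin(mean_angle)])
    mean_dir[~defined] = np.nan
    return mean_dir, circ_sd, defined


def ssi(smap: SurfaceMap, prop_field: np.ndarray, center_node: int,
        r: float, dr: float = 10.0, min_nodes: int = 5) -> float:
    """Source-sink index: mean radial component of the propagation field.

    ``S_j(r) = mean_{k in annulus} (x_k - x_j) . g_k`` where ``g`` is the
    outward-positive propagation field (rad/mm) and the annulus is
    ``r - dr < |x_k - x_j| < r + dr`` on the same hemisphere.  Positive
    values mark sources (outward radial waves), negative values sinks.
    Returns NaN when fewer than ``min_nodes`` members are valid.
    """
    x = smap.coords2d
    xj = x[center_node]
    same = smap.hemisphere == smap.hemisphere[center_node]
    d = np.linalg.norm(x - xj, axis=1)
    members = same & (d > r - dr) & (d < r + dr)
    members[center_node] = False
    g = np.asarray(prop_field, dtype=float)
    members &= np.isfinite(g).all(axis=1)
    if members.sum() < min_nodes:
        return float("nan")
    return float(np.mean(np.sum((x[members] - xj) * g[members], axis=1)))
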