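"""Spatially embedded connectome networks: synthetic generation and file I/O.

The synthetic generator emulates the statistical structure of a
tractography-derived human connectome that the wave analyses rely on:
nodes quasi-uniformly covering two hemispheric spherical surfaces,
connection weights that decay with distance and are concentrated on a
minority of hub regions, tract lengths mildly exceeding Euclidean
distance, conduction delays ``tau = L / v`` under a fixed axonal
velocity, and seven spatially contiguous, roughly bilateral network
labels standing in for resting-state networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ._rng import substream
from .errors import ConnectomeLoadError, InvalidConfigError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic connectome generator.

    Parameters
    ----------
    n_nodes : int
        Total number of regions across both hemispheres.
    mean_volume, volume_sd : float
        Mean and SD of region volumes (mm^3); volumes are clipped to
        ``volume_range``.
    weight_decay_length : float
        Exponential decay length (mm) of connection weight with
        Euclidean distance.
    hub_fraction : float
        Fraction of nodes designated as hubs.
    hub_gain : float
        Multiplicative weight gain applied to each hub endpoint.
    conduction_velocity : float
        Axonal conduction velocity v (m/s); delays are ``L / v``.
    n_networks : int
        Number of contiguous network labels (resting-state surrogate).
    density : float
        Fraction of node pairs retained (strongest weights kept).
    tortuosity : float
        Fractional excess of tract length over Euclidean distance.
    sphere_radius : float
        Radius (mm) of each hemispheric sphere.
    hemisphere_gap : float
        Distance (mm) between the two sphere centres along x.
    medial_wall_deg : float
        Half-angle (degrees) of the medial cap left free of nodes.
    seed : int
        Root seed; fixed seed gives byte-identical networks.
    """

    n_nodes: int = 468
    mean_volume: float = 2144.0
    volume_sd: float = 399.0
    volume_range: tuple = (753.0, 3077.0)
    weight_decay_length: float = 45.0
    hub_fraction: float = 0.2
    hub_gain: float = 3.0
    conduction_velocity: float = 10.8
    n_networks: int = 7
    density: float = 0.25
    tortuosity: float = 0.15
    sphere_radius: float = 55.0
    hemisphere_gap: float | None = None  # None: caps just clear the midline
    medial_wall_deg: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise InvalidConfigError("n_nodes must be >= 2")
        if self.n_networks < 2:
            raise InvalidConfigError("n_networks must be >= 2")
        if self.n_nodes < self.n_networks:
            raise InvalidConfigError(
                f"n_nodes={self.n_nodes} is smaller than n_networks={self.n_networks}"
            )
        if self.conduction_velocity <= 0:
            raise InvalidConfigError("conduction_velocity must be positive")
        if not 0.0 < self.density <= 1.0:
            raise InvalidConfigError("density must lie in (0, 1]")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise InvalidConfigError("hub_fraction must lie in [0, 1]")
        if self.tortuosity < 0.0:
            raise InvalidConfigError("tortuosity must be nonnegative")


@dataclass
class ConnectomeNetwork:
    """A spatially embedded oscillator network.

    ``weights`` and ``tract_lengths`` are symmetric with zero diagonal;
    ``delays`` equals ``tract_lengths / v`` elementwise (seconds).
    ``degrees`` are weighted row sums rescaled to [0, 1].
    """

    coords3d: np.ndarray  # (N, 3) mm
    hemisphere: np.ndarray  # (N,) 'L'/'R'
    weights: np.ndarray  # (N, N)
    tract_lengths: np.ndarray  # (N, N) mm
    delays: np.ndarray  # (N, N) s
    volumes: np.ndarray  # (N,) mm^3
    network_labels: np.ndarray  # (N,) ints in 1..n_networks
    conduction_velocity: float = 10.8

    @property
    def n_nodes(self) -> int:
        return self.coords3d.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        s = self.weights.sum(axis=1)
        m = s.max()
        return s / m if m > 0 else s

    def validate(self, atol: float = 1e-9) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        n = self.n_nodes
        w, L, D = self.weights, self.tract_lengths, self.delays
        assert w.shape == L.shape == D.shape == (n, n)
        assert np.allclose(w, w.T, atol=atol), "weights not symmetric"
        assert np.allclose(L, L.T, atol=atol), "tract lengths not symmetric"
        assert np.all(np.diag(w) == 0), "weights diagonal nonzero"
        assert np.all(np.diag(L) == 0), "lengths diagonal nonzero"
        assert np.all(w >= 0) and np.all(L >= 0)
        assert np.allclose(D, L / self.conduction_velocity / 1000.0, atol=atol), (
            "delays != L / v"
        )
        d = euclidean_distances(self.coords3d)
        both = (L > 0) & (d > 0)
        assert np.all(L[both] >= d[both] - 1e-6), "tract length below Euclidean"
        deg = self.degrees
        assert np.all((deg >= 0) & (deg <= 1))
        labels = np.unique(self.network_labels)
        assert labels.min() >= 1


def euclidean_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix (mm)."""
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _cap_points(n: int, axis: np.ndarray, cap_half_angle: float,
                radius: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform jittered Fibonacci points on a spherical cap.

    The cap has half-angle ``cap_half_angle`` about ``axis``; jitter is
    tangential with SD a quarter of the mean point spacing, preserving
    quasi-uniform coverage without lattice artifacts.
    """
    i = np.arange(n)
    # uniform in cos(theta) over [cos(cap), 1] -> equal-area bands
    z = 1.0 - (i + 0.5) / n * (1.0 - np.cos(cap_half_angle))
    phi = i * _GOLDEN_ANGLE
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])

    # rotate +z onto the cap axis
    axis = axis / np.linalg.norm(axis)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(zhat, axis)
    c = float(zhat @ axis)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    pts = pts @ rot.T

    spacing = np.sqrt(4.0 * np.pi / n * (1.0 - np.cos(cap_half_angle)) / 2.0)
    base = pts
    jitter = rng.normal(scale=0.15 * spacing, size=(n, 3))
    pts = base + jitter - (jitter * base).sum(axis=1, keepdims=True) * base
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # enforce a minimum separation of half the mean spacing (keeps the
    # shortest conduction delay above the integration step)
    min_sep = 0.5 * spacing
    for _ in range(50):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if pairs.size == 0:
            break
        bad = np.unique(pairs[:, 1])  # redraw the later point of each pair
        jit = rng.normal(scale=0.15 * spacing, size=(bad.size, 3))
        moved = base[bad] + jit - (jit * base[bad]).sum(axis=1, keepdims=True) * base[bad]
        pts[bad] = moved / np.linalg.norm(moved, axis=1, keepdims=True)
    return pts * radius


def spatial_adjacency(coords3d: np.ndarray, hemisphere: np.ndarray,
                      k: int = 6) -> csr_matrix:
    """Spatial adjacency graph used for label growing and contiguity.

    Symmetric k-nearest-neighbour edges within each hemisphere, plus one
    homotopic edge per node linking it to the nearest node of the other
    hemisphere after mirroring about the midsagittal plane (x -> -x).
    Edge weights are Euclidean distances (mirror edges use the mirrored
    distance, making homotopic crossings cheap).
    """
    n = coords3d.shape[0]
    rows, cols, vals = [], [], []
    side_idx = {s: np.where(hemisphere == s)[0] for s in ("L", "R")}
    for s, idx in side_idx.items():
        if idx.size < 2:
            continue
        pts = coords3d[idx]
        kk = min(k, idx.size - 1)
        tree = cKDTree(pts)
        dist, nbr = tree.query(pts, k=kk + 1)
        for a in range(idx.size):
            for b, dd in zip(nbr[a, 1:], dist[a, 1:]):
                rows.append(idx[a])
                cols.append(idx[b])
                vals.append(dd)
    # homotopic mirror edges
    mirrored = coords3d.copy()
    mirrored[:, 0] *= -1
    for s, other in (("L", "R"), ("R", "L")):
        idx, oidx = side_idx[s], side_idx[other]
        if idx.size == 0 or oidx.size == 0:
            continue
        tree = cKDTree(coords3d[oidx])
        dist, nbr = tree.query(mirrored[idx], k=1)
        rows.extend(idx.tolist())
        cols.extend(oidx[nbr].tolist())
        vals.extend(dist.tolist())
    adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return adj.maximum(adj.T)


def _grow_labels(coords3d: np.ndarray, hemisphere: np.ndarray,
                 n_networks: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous label partition by graph-Voronoi region growing.

    Seeds are picked greedily (farthest-point) among left-hemisphere
    nodes; every node takes the label of its graph-nearest seed, which
    makes each label class connected in the adjacency graph.
    """
    n = coords3d.shape[0]
    pool = np.where(hemisphere == "L")[0]
    if pool.size < n_networks:
        pool = np.arange(n)
    seeds = [int(rng.choice(pool))]
    d_seed = np.linalg.norm(coords3d[pool] - coords3d[seeds[0]], axis=1)
    while len(seeds) < n_networks:
        nxt = int(pool[np.argmax(d_seed)])
        seeds.append(nxt)
        d_seed = np.minimum(d_seed,
                            np.linalg.norm(coords3d[pool] - coords3d[nxt], axis=1))
    adj = spatial_adjacency(coords3d, hemisphere)
    dist = dijkstra(adj, directed=False, indices=seeds)
    unreachable = ~np.isfinite(dist).any(axis=0)
    labels = np.argmin(dist, axis=0) + 1
    if unreachable.any():  # isolated nodes fall back to Euclidean nearest seed
        d_eu = np.linalg.norm(
            coords3d[unreachable][:, None, :] - coords3d[seeds][None, :, :], axis=-1
        )
        labels[unreachable] = np.argmin(d_eu, axis=1) + 1
    return labels.astype(np.int64)


def generate_connectome(cfg: SyntheticConfig) -> ConnectomeNetwork:
    """Generate a synthetic spatially embedded connectome.

    Nodes are placed quasi-uniformly on two hemispheric sphere surfaces
    separated by a midline gap.  Weights follow
    ``exp(-d/decay) * hub gains / d / sqrt(vol_j vol_k)``, the strongest
    ``density`` fraction of pairs is kept, and the surviving weights are
    rescaled so the mean nonzero weight equals one.  Tract lengths are
    Euclidean distances inflated by the tortuosity factor and delays are
    ``L / v``.
    """
    cfg.validate()
    rng = substream(cfg.seed, "connectome")
    n = cfg.n_nodes
    n_left = n // 2
    n_right = n - n_left
    cap = np.deg2rad(180.0 - cfg.medial_wall_deg)
    if cfg.hemisphere_gap is None:
        # place sphere centres so the cap rims clear the midline by 10 mm
        half_gap = cfg.sphere_radius * np.cos(np.deg2rad(cfg.medial_wall_deg)) + 5.0
    else:
        half_gap = cfg.hemisphere_gap / 2.0

    left = _cap_points(n_left, np.array([-1.0, 0.0, 0.0]), cap,
                       cfg.sphere_radius, rng)
    left[:, 0] -= half_gap
    right = _cap_points(n_right, np.array([1.0, 0.0, 0.0]), cap,
                        cfg.sphere_radius, rng)
    right[:, 0] += half_gap
    coords = np.vstack([left, right])
    hemisphere = np.array(["L"] * n_left + ["R"] * n_right)

    volumes = np.clip(rng.normal(cfg.mean_volume, cfg.volume_sd, size=n),
                      *cfg.volume_range)

    d = euclidean_distances(coords)
    gains = np.ones(n)
    # hubs come in homotopic pairs: cortical hub regions are bilaterally
    # symmetric, and i.i.d. hub placement would make network realizations
    # wildly variable in their synchronization regime
    n_hub_pairs = int(round(cfg.hub_fraction * n / 2.0))
    left_idx = np.where(hemisphere == "L")[0]
    right_idx = np.where(hemisphere == "R")[0]
    if n_hub_pairs > 0 and left_idx.size >= n_hub_pairs and right_idx.size > 0:
        hubs_left = rng.choice(left_idx, size=n_hub_pairs, replace=False)
        mirrored = coords[hubs_left].copy()
        mirrored[:, 0] *= -1.0
        tree = cKDTree(coords[right_idx])
        _, homotopic = tree.query(mirrored)
        gains[hubs_left] = cfg.hub_gain
        gains[right_idx[homotopic]] = cfg.hub_gain
    elif n_hub_pairs > 0:  # degenerate single-hemisphere layouts
        hubs = rng.choice(n, size=min(2 * n_hub_pairs, n), replace=False)
        gains[hubs] = cfg.hub_gain

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-d / cfg.weight_decay_length)
        w *= np.outer(gains, gains)
        w /= d  # stream-length division
        w /= np.sqrt(np.outer(volumes, volumes))
    np.fill_diagonal(w, 0.0)

    # keep the strongest `density` fraction of pairs (symmetric)
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    n_keep = max(1, int(round(cfg.density * vals.size)))
    thresh = np.partition(vals, vals.size - n_keep)[vals.size - n_keep]
    w[w < thresh] = 0.0
    nz = w > 0
    w[nz] /= w[nz].mean()

    L = d * (1.0 + cfg.tortuosity)
    np.fill_diagonal(L, 0.0)
    delays = L / cfg.conduction_velocity / 1000.0  # mm / (m/s) -> s

    labels = _grow_labels(coords, hemisphere, cfg.n_networks, rng)

    return ConnectomeNetwork(
        coords3d=coords,
        hemisphere=hemisphere,
        weights=w,
        tract_lengths=L,
        delays=delays,
        volumes=volumes,
        network_labels=labels,
        conduction_velocity=cfg.conduction_velocity,
    )


# ---------------------------------------------------------------------------
# File I/O: delimited text, 0-based node indexing
# ---------------------------------------------------------------------------

def save_connectome(net: ConnectomeNetwork, out_dir) -> Path:
    """Write weights.tsv, lengths.tsv and nodes.tsv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "weights.tsv", net.weights, delimiter="\t")
    np.savetxt(out / "lengths.tsv", net.tract_lengths, delimiter="\t")
    nodes = pd.DataFrame({
        "node_id": np.arange(net.n_nodes),
        "x": net.coords3d[:, 0],
        "y": net.coords3d[:, 1],
        "z": net.coords3d[:, 2],
        "hemisphere": net.hemisphere,
        "volume": net.volumes,
        "label": net.network_labels,
    })
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    return out


def _load_matrix(path, name: str) -> np.ndarray:
    try:
        m = np.loadtxt(path, delimiter="\t", ndmin=2)
    except Exception as exc:
        raise ConnectomeLoadError(f"could not parse {name} matrix {path}: {exc}")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeLoadError(
            f"{name} matrix {path} is not square (shape {m.shape})"
        )
    if np.any(m < 0):
        raise ConnectomeLoadError(f"{name} matrix {path} has negative entries")
    if not np.allclose(m, m.T, atol=1e-6 * max(1.0, np.abs(m).max())):
        raise ConnectomeLoadError(f"{name} matrix {path} is not symmetric")
    return m


def load_connectome(weights_path, lengths_path, coords_path,
                    labels_path=None, v: float = 10.8) -> ConnectomeNetwork:
    """Load a connectome from delimited text files.

    ``coords_path`` must be a TSV with columns
    node_id, x, y, z, hemisphere, volume[, label]; labels may instead be
    a separate single-column file.  Delays are computed as ``L / v``.
    """
    if v <= 0:
        raise ConnectomeLoadError("conduction velocity must be positive")
    w = _load_matrix(weights_path, "weights")
    L = _load_matrix(lengths_path, "lengths")
    if w.shape != L.shape:
        raise ConnectomeLoadError(
            f"weights {w.shape} and lengths {L.shape} differ in shape"
        )
    n = w.shape[0]
    try:
        nodes = pd.read_csv(coords_path, sep="\t")
    except Exception as exc:
        raise ConnectomeLoadError(f"could not parse nodes table {coords_path}: {exc}")
    required = {"x", "y", "z", "hemisphere", "volume"}
    missing = required - set(nodes.columns)
    if missing:
        raise ConnectomeLoadError(f"nodes table missing columns {sorted(missing)}")
    if len(nodes) != n:
        raise ConnectomeLoadError(
            f"nodes table has {len(nodes)} rows but matrices are {n}x{n}"
        )
    if labels_path is not None:
        labels = np.loadtxt(labels_path, dtype=np.int64, ndmin=1)
        if labels.size != n:
            raise ConnectomeLoadError("labels file length mismatch")
    elif "label" in nodes.columns:
        labels = nodes["label"].to_numpy(dtype=np.int64)
    else:
        raise ConnectomeLoadError("no labels: pass labels_path or a label column")
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(L, 0.0)
    return ConnectomeNetwork(
        coords3d=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=nodes["hemisphere"].to_numpy(dtype="U1"),
        weights=w,
        tract_lengths=L,
        delays=L / v / 1000.0,
        volumes=nodes["volume"].to_numpy(dtype=float),
        network_labels=labels,
        conduction_velocity=v,
    )
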