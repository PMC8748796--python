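"""Headline wave statistics: UCI, segmentation, PCA, SSI slopes, grouping scan.

These quantify the two functional roles attributed to cortical
traveling waves.  *Sequencing*: oscillators with faster intrinsic
frequency occupy earlier wave phases, which under
communication-through-coherence yields directed communication, measured
by the unidirectional communication index (UCI) and its regression
slope on intrinsic frequency.  *Segmentation*: the traveling wave's
iso-phase bands group regions into large-scale networks, measured by
pairwise Cohen's d between the relative-phase distributions of network
label classes, with permutation inference and FDR control.

Relative phases are treated as linear quantities: in the operating
regime they are centred at zero with single-peaked spread below pi, and
a warning is issued when that assumption fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .errors import ZeroVarianceError
from .projection import SurfaceMap
from .simulate import PhaseTrajectory
from .wavefield import WaveField, mean_direction_map, ssi

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Unidirectional communication index
# ---------------------------------------------------------------------------

def uci(phases_snapshot: np.ndarray, delays: np.ndarray, f0: float,
        literal_delay_term: bool = False) -> np.ndarray:
    """Per-node unidirectional communication index in [0, 1].

    ``U_j = mean_k (0.5 cos(theta_j - theta_k - phi_jk) + 0.5)`` where the
    delay offset ``phi_jk = 2 pi f0 tau_jk`` expresses the conduction
    delay as a phase at the mean frequency: U_j is maximal when j's
    phase lead over every partner equals the delay, so j's output
    arrives in the partner's receptive phase.  ``literal_delay_term``
    switches to the alternative offset ``2 pi tau_jk / f0``.
    """
    theta = np.asarray(phases_snapshot, dtype=float)
    tau = np.asarray(delays, dtype=float)
    offset = (TWO_PI * tau / f0) if literal_delay_term else (TWO_PI * f0 * tau)
    diff = theta[:, None] - theta[None, :] - offset
    return (0.5 * np.cos(diff) + 0.5).mean(axis=1)


def uci_series(traj: PhaseTrajectory, delays: np.ndarray, f0: float | None = None,
               literal_delay_term: bool = False) -> np.ndarray:
    """UCI for every retained snapshot, shape (S, N)."""
    if f0 is None:
        f0 = traj.config.f0
    tau = np.asarray(delays, dtype=float)
    offset = (TWO_PI * tau / f0) if literal_delay_term else (TWO_PI * f0 * tau)
    diff = traj.phases[:, :, None] - traj.phases[:, None, :] - offset[None]
    return (0.5 * np.cos(diff) + 0.5).mean(axis=2)


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var()
    if vx == 0.0:
        raise ZeroVarianceError("regressor has zero variance; slope undefined")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def uci_slope(uci_per_node: np.ndarray, freqs_per_node: np.ndarray):
    """Slope of UCI on intrinsic frequency (per Hz) with its t statistic."""
    res = _linregress_guarded(freqs_per_node, uci_per_node)
    if res.stderr > 0:
        t = res.slope / res.stderr
    else:
        t = float("nan") if res.slope == 0 else float(np.inf * np.sign(res.slope))
    return res.slope, t


def _linregress_guarded(x, y):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ZeroVarianceError("need at least 3 points for a slope")
    if np.var(x) == 0.0:
        raise ZeroVarianceError("regressor has zero variance; slope undefined")
    return stats.linregress(x, np.asarray(y, dtype=float))


def uci_slopes(traj: PhaseTrajectory, delays: np.ndarray,
               freqs: np.ndarray | None = None,
               literal_delay_term: bool = False) -> np.ndarray:
    """Per-sample slope of UCI on intrinsic frequency.

    ``freqs`` defaults to the scheduled intrinsic frequencies of each
    sampled epoch; an explicit (S, N) array supports sham-frequency
    controls where the schedule had zero variance.
    """
    U = uci_series(traj, delays, literal_delay_term=literal_delay_term)
    f = traj.sample_freqs if freqs is None else np.asarray(freqs, dtype=float)
    slopes = np.empty(U.shape[0])
    for s in range(U.shape[0]):
        slopes[s] = ols_slope(f[s], U[s])
    return slopes


def slope_t_test(slopes: np.ndarray):
    """One-sample t test of per-epoch slopes against zero.

    Returns (mean slope, t statistic, two-sided p).
    """
    slopes = np.asarray(slopes, dtype=float)
    t, p = stats.ttest_1samp(slopes, 0.0)
    return float(slopes.mean()), float(t), float(p)


# ---------------------------------------------------------------------------
# Network segmentation: Cohen's d between label-class phase distributions
# ---------------------------------------------------------------------------

def cohens_d(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Effect size between two phase sets.

    ``d = |mean(P_i) - mean(P_j)| / sqrt(((N_i-1) var(P_i) + (N_j-1) var(P_j))
    / (N_i + N_j))`` with unbiased variances; scale-free and symmetric.
    Returns inf when the pooled variance is zero but the means differ.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    ni, nj = p_i.size, p_j.size
    if ni == 0 or nj == 0:
        raise ValueError("empty phase set")
    num = abs(p_i.mean() - p_j.mean())
    vi = p_i.var(ddof=1) if ni > 1 else 0.0
    vj = p_j.var(ddof=1) if nj > 1 else 0.0
    denom_sq = ((ni - 1) * vi + (nj - 1) * vj) / (ni + nj)
    if denom_sq == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / np.sqrt(denom_sq))


def _group_stats(phases: np.ndarray, onehot: np.ndarray, counts: np.ndarray):
    """Per-sample group means and unbiased variances via one matmul each."""
    sums = phases @ onehot                    # (S, K)
    sumsq = (phases**2) @ onehot
    means = sums / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sumsq - counts * means**2) / np.maximum(counts - 1, 1)
    var[:, counts == 1] = 0.0
    return means, np.maximum(var, 0.0)


def _d_matrix_from_stats(means, var, counts):
    """(S, K, K) Cohen's d from per-sample group means/variances."""
    ni = counts[None, :, None]
    nj = counts[None, None, :]
    num = np.abs(means[:, :, None] - means[:, None, :])
    pooled = ((ni - 1) * var[:, :, None] + (nj - 1) * var[:, None, :]) / (ni + nj)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / np.sqrt(pooled)
    d[np.broadcast_to(pooled == 0.0, d.shape) & (num == 0.0)] = 0.0
    k = counts.size
    d[:, np.arange(k), np.arange(k)] = 0.0
    return d


@dataclass
class SegmentationResult:
    """Pairwise network phase separation and its inference."""

    labels: np.ndarray            # distinct network labels, sorted
    network_means: np.ndarray     # (S, K) per-sample mean relative phase
    d_matrix: np.ndarray          # (S, K, K) per-sample Cohen's d
    d_mean: np.ndarray            # (K, K) time-averaged Cohen's d
    anova_F: float                # one-way F across networks (node means)
    anova_p: float
    anova_df: tuple
    pairwise_p: np.ndarray        # (K, K) FDR-adjusted permutation p
    significant: np.ndarray       # (K, K) bool at the FDR threshold
    null_d_mean_q95: float        # 95th percentile of shuffled mean pairwise d
    mean_pairwise_d: float

    @property
    def n_pairs(self) -> int:
        k = self.labels.size
        return k * (k - 1) // 2


def segmentation(rel_phases: np.ndarray, labels: np.ndarray,
                 n_perm: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> SegmentationResult:
    """Phase-based network segmentation analysis.

    Computes per-sample pairwise Cohen's d between the relative-phase
    sets of the label classes, a one-way ANOVA across classes on the
    node time-mean phases, and pairwise permutation tests (label
    shuffling, ``n_perm`` resamples) on the time-averaged d with
    Benjamini-Hochberg FDR control at ``alpha``.
    """
    phases = np.atleast_2d(np.asarray(rel_phases, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k = classes.size
    onehot = (labels[:, None] == classes[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("every network label class must be nonempty")

    means, var = _group_stats(phases, onehot, counts)
    d = _d_matrix_from_stats(means, var, counts)
    d_mean = d.mean(axis=0)
    iu = np.triu_indices(k, 1)
    mean_pairwise = float(d_mean[iu].mean())

    node_means = phases.mean(axis=0)
    groups = [node_means[labels == c] for c in classes]
    F, p_anova = stats.f_oneway(*groups)
    dfs = (k - 1, labels.size - k)

    rng = substream(seed, "permutations")
    null_pair = np.empty((n_perm, iu[0].size))
    for b in range(n_perm):
        perm = rng.permutation(labels.size)
        oh = onehot[perm]
        m_b, v_b = _group_stats(phases, oh, counts)
        null_pair[b] = _d_matrix_from_stats(m_b, v_b, counts).mean(axis=0)[iu]
    obs_pair = d_mean[iu]
    p_raw = (1.0 + (null_pair >= obs_pair[None, :]).sum(axis=0)) / (1.0 + n_perm)
    rej, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")

    pairwise_p = np.full((k, k), np.nan)
    significant = np.zeros((k, k), dtype=bool)
    pairwise_p[iu] = p_adj
    pairwise_p[(iu[1], iu[0])] = p_adj
    significant[iu] = rej
    significant[(iu[1], iu[0])] = rej

    return SegmentationResult(
        labels=classes,
        network_means=means,
        d_matrix=d,
        d_mean=d_mean,
        anova_F=float(F),
        anova_p=float(p_anova),
        anova_df=dfs,
        pairwise_p=pairwise_p,
        significant=significant,
        null_d_mean_q95=float(np.quantile(null_pair.mean(axis=1), 0.95)),
        mean_pairwise_d=mean_pairwise,
    )


def network_phase_degree_correlation(rel_phases: np.ndarray, labels: np.ndarray,
                                     degrees: np.ndarray):
    """Pearson r between network-mean relative phase and network-mean degree.

    Means are pooled over all samples and the nodes of each network.
    Returns (r, t statistic, two-sided p) across the label classes.
    """
    phases = np.atleast_2d(np.asarray(rel_phases, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    mean_phase = np.array([phases[:, labels == c].mean() for c in classes])
    mean_deg = np.array([np.asarray(degrees)[labels == c].mean() for c in classes])
    r, p = stats.pearsonr(mean_deg, mean_phase)
    df = classes.size - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    return float(r), float(t), float(p)


# ---------------------------------------------------------------------------
# Topographic PCA of relative phases
# ---------------------------------------------------------------------------

@dataclass
class PhasePCAResult:
    components: np.ndarray        # (n_comp, N) node-space components
    explained_ratio: np.ndarray   # (n_comp,)
    wide_spread_fraction: float   # fraction of samples with range >= pi


def relative_phase_pca(rel_phases: np.ndarray,
                       n_components: int | None = None) -> PhasePCAResult:
    """PCA of the samples x nodes relative-phase matrix.

    Phases are linearized (valid for single-peaked spreads below pi);
    if more than 5% of samples have a phase range of pi or more, a
    warning flags that the linearization is unsafe.
    """
    phases = np.atleast_2d(np.asarray(rel_phases, dtype=float))
    if phases.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    # central 95% range: the linearization argument concerns the bulk of
    # the distribution, not individual weakly coupled stragglers
    spread = np.quantile(phases, 0.975, axis=1) - np.quantile(phases, 0.025, axis=1)
    wide = float(np.mean(spread >= np.pi))
    if wide > 0.05:
        warnings.warn(
            f"{wide:.0%} of samples have phase range >= pi; "
            "linearized PCA may be unreliable"
        )
    pca = PCA(n_components=n_components)
    pca.fit(phases)
    return PhasePCAResult(
        components=pca.components_,
        explained_ratio=pca.explained_variance_ratio_,
        wide_spread_fraction=wide,
    )


# ---------------------------------------------------------------------------
# SSI slopes vs intrinsic frequency and node degree
# ---------------------------------------------------------------------------

def ssi_slope(traj: PhaseTrajectory, fld: WaveField, smap: SurfaceMap,
              center_node: int, radii, dr: float = 10.0,
              min_samples: int = 20, raw_gradient: bool = False) -> np.ndarray:
    """Slope of SSI on the centre's intrinsic frequency, per radius.

    For each radius the SSI is evaluated at every sample and regressed
    on the centre node's scheduled frequency; radii with fewer than
    ``min_samples`` valid SSI values give NaN.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    f_center = traj.sample_freqs[:, center_node]
    slopes = np.full(radii.size, np.nan)
    for ir, r in enumerate(radii):
        vals = np.array([
            ssi(smap, fld.propagation_field(s, raw_gradient=raw_gradient),
                center_node, r, dr)
            for s in range(traj.n_samples)
        ])
        ok = np.isfinite(vals)
        if ok.sum() < min_samples or np.var(f_center[ok]) == 0.0:
            continue
        slopes[ir] = ols_slope(f_center[ok], vals[ok])
    return slopes


def ssi_slope_degree_table(traj: PhaseTrajectory, fld: WaveField,
                           smap: SurfaceMap, degrees: np.ndarray,
                           radii, centers=None, dr: float = 10.0,
                           min_samples: int = 20):
    """Rows of (center, degree, radius, ssi_slope) across centre nodes."""
    import pandas as pd

    centers = np.arange(smap.n_nodes) if centers is None else np.asarray(centers)
    rows = []
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    for c in centers:
        slopes = ssi_slope(traj, fld, smap, int(c), radii, dr=dr,
                           min_samples=min_samples)
        for r, s in zip(radii, slopes):
            rows.append((int(c), float(np.asarray(degrees)[c]), float(r), s))
    return pd.DataFrame(rows, columns=["center", "degree", "radius", "ssi_slope"])


# ---------------------------------------------------------------------------
# Grouping-size scan and gradient-frequency coupling
# ---------------------------------------------------------------------------

DEFAULT_AREAS_CM2 = np.geomspace(10.0, 400.0, 12)


@dataclass
class GroupingScanResult:
    areas_cm2: np.ndarray
    slopes: np.ndarray        # rad per Hz, NaN where the disk was skipped
    n_members: np.ndarray
    optimal_area_cm2: float   # NaN when no area yields a defined slope


def _disk_members(smap: SurfaceMap, center: int, radius_mm: float) -> np.ndarray:
    d = np.linalg.norm(smap.coords2d - smap.coords2d[center], axis=1)
    return (d <= radius_mm) & (smap.hemisphere == smap.hemisphere[center])


def grouping_scan(smap: SurfaceMap, traj: PhaseTrajectory, center: int,
                  areas_cm2=DEFAULT_AREAS_CM2,
                  min_nodes: int = 5) -> GroupingScanResult:
    """Slope of relative phase on intrinsic frequency vs grouping area.

    For each circular area the member nodes' frequencies and relative
    phases are averaged per sample, and the disk-mean phase is
    regressed on the disk-mean frequency across samples.  Averaging at
    the spatial scale over which phases actually integrate intrinsic
    frequencies maximizes the slope (a matched filter in area), so the
    optimal area estimates that scale.  Disks with fewer than
    ``min_nodes`` members are skipped.
    """
    areas = np.atleast_1d(np.asarray(areas_cm2, dtype=float))
    f = traj.sample_freqs
    th = traj.rel_phases
    slopes = np.full(areas.size, np.nan)
    n_members = np.zeros(areas.size, dtype=int)
    for ia, area in enumerate(areas):
        radius_mm = np.sqrt(area / np.pi) * 10.0
        members = _disk_members(smap, center, radius_mm)
        n_members[ia] = int(members.sum())
        if n_members[ia] < min_nodes:
            continue
        x = f[:, members].mean(axis=1)
        if np.var(x) == 0.0:
            continue
        slopes[ia] = ols_slope(x, th[:, members].mean(axis=1))
    if np.isfinite(slopes).any():
        optimal = float(areas[np.nanargmax(np.abs(slopes))])
    else:
        optimal = float("nan")
    return GroupingScanResult(areas_cm2=areas, slopes=slopes,
                              n_members=n_members, optimal_area_cm2=optimal)


def optimal_area_map(smap: SurfaceMap, traj: PhaseTrajectory,
                     areas_cm2=DEFAULT_AREAS_CM2, min_nodes: int = 5) -> np.ndarray:
    """Optimal grouping area (cm^2) for every centre node, vectorized.

    Same disk-mean regression as :func:`grouping_scan`, evaluated for
    all centres at once; NaN where no area has enough members.
    """
    areas = np.atleast_1d(np.asarray(areas_cm2, dtype=float))
    f = traj.sample_freqs
    th = traj.rel_phases
    S, n = f.shape
    d2 = ((smap.coords2d[:, None, :] - smap.coords2d[None, :, :]) ** 2).sum(-1)
    same = smap.hemisphere[:, None] == smap.hemisphere[None, :]
    all_slopes = np.full((areas.size, n), np.nan)
    for ia, area in enumerate(areas):
        radius_mm = np.sqrt(area / np.pi) * 10.0
        M = ((d2 <= radius_mm**2) & same).astype(float)  # (centers, nodes)
        n_mem = M.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = f @ M.T / n_mem                  # (S, centers) disk-mean freq
            Y = th @ M.T / n_mem                 # disk-mean phase
            vx = X.var(axis=0)
            cov = (X * Y).mean(axis=0) - X.mean(axis=0) * Y.mean(axis=0)
            slope = cov / vx
        slope[(n_mem < min_nodes) | ~(vx > 0)] = np.nan
        all_slopes[ia] = slope
    out = np.full(n, np.nan)
    any_valid = np.isfinite(all_slopes).any(axis=0)
    idx = np.nanargmax(np.abs(all_slopes[:, any_valid]), axis=0)
    out[any_valid] = areas[idx]
    return out


@dataclass
class GradientFrequencySlope:
    slope: float            # rad/mm per Hz along the mean propagation direction
    p_value: float          # two-sided permutation p
    n_members: int
    mean_direction: np.ndarray


def gradient_frequency_slope(smap: SurfaceMap, traj: PhaseTrajectory,
                             fld: WaveField, center: int,
                             area_cm2: float = 100.0, n_perm: int = 2000,
                             seed: int = 0, min_nodes: int = 5,
                             raw_gradient: bool = False) -> GradientFrequencySlope:
    """Dependence of the local phase gradient on grouped intrinsic frequency.

    Across samples, the signed component of the centre's propagation
    field along its mean propagation direction is regressed on the mean
    scheduled frequency of the disk's member nodes.  The null is built
    by shuffling the epoch frequency vectors across epochs (``n_perm``
    resamples, two-sided).
    """
    radius_mm = np.sqrt(area_cm2 / np.pi) * 10.0
    members = _disk_members(smap, center, radius_mm)
    if members.sum() < min_nodes:
        raise ValueError(f"disk around node {center} has <{min_nodes} members")
    mean_dir, _, defined = mean_direction_map(fld)
    if not defined[center]:
        return GradientFrequencySlope(float("nan"), float("nan"),
                                      int(members.sum()), mean_dir[center])
    u = mean_dir[center]
    prop = -fld.gradients[:, center, :] * np.sign(fld.inst_rates[:, center])[:, None]
    if raw_gradient:
        prop = fld.gradients[:, center, :]
    y = prop @ u
    x = traj.sample_freqs[:, members].mean(axis=1)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.var(x) == 0.0:
        raise ZeroVarianceError("grouped frequencies have no variance")
    obs = ols_slope(x, y)
    rng = substream(seed, "permutations")
    perm_slopes = np.empty(n_perm)
    for b in range(n_perm):
        perm_slopes[b] = ols_slope(x[rng.permutation(x.size)], y)
    p = (1.0 + (np.abs(perm_slopes) >= abs(obs)).sum()) / (1.0 + n_perm)
    return GradientFrequencySlope(float(obs), float(p), int(members.sum()), u)
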