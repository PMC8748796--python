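"""End-to-end experiment orchestration and parameter sweeps.

``run_experiment`` chains generate -> simulate -> project -> wave field
-> metrics, writes tidy TSV tables plus a summary JSON and a run
manifest, and is deterministic given the root seed.  ``run_sweep``
repeats the scaled-down experiment over grids of coupling strength,
frequency dispersion and mean frequency, reporting the four headline
panels (median speed, mean pairwise segmentation d, mean UCI slope,
mean order parameter) per grid point.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from ._rng import child_seed
from .connectome import ConnectomeNetwork, SyntheticConfig, generate_connectome, save_connectome
from .errors import InvalidConfigError
from .projection import SurfaceMap, project
from .simulate import (
    PhaseTrajectory,
    SimulationConfig,
    order_parameter_series,
    save_trajectory,
    simulate,
)
from .wavefield import compute_wave_field

logger = logging.getLogger("cortexwaves")

PROFILES = {
    "ci": {"n_nodes": 150, "t_total": 21.0},
    "full": {"n_nodes": 468, "t_total": 101.0},
}


@dataclass
class AnalysisConfig:
    """Parameters of the wave analyses."""

    window_sigma: float = 20.0       # mm, Gaussian window SD of the gradient fit
    ssi_radii: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    ssi_dr: float = 10.0             # mm, annulus half-width
    areas_cm2: tuple = tuple(np.geomspace(10.0, 400.0, 12))
    grouping_area_cm2: float = 100.0
    n_perm: int = 2000
    alpha: float = 0.05
    literal_uci_delay: bool = False  # use the 2*pi*tau/f0 offset variant
    raw_gradient_ssi: bool = False


@dataclass
class ExperimentConfig:
    """Full configuration of one experiment run."""

    profile: str = "ci"
    seed: int = 0
    connectome: SyntheticConfig = field(default_factory=SyntheticConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise InvalidConfigError(
                f"unknown profile {self.profile!r}; choose from {sorted(PROFILES)}"
            )

    @classmethod
    def default(cls, profile: str = "ci", seed: int = 0, **overrides) -> "ExperimentConfig":
        prof = PROFILES.get(profile)
        if prof is None:
            raise InvalidConfigError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
            )
        conn = SyntheticConfig(n_nodes=prof["n_nodes"],
                               seed=child_seed(seed, "connectome"))
        sim = SimulationConfig(t_total=prof["t_total"],
                               seed=child_seed(seed, "schedule"))
        cfg = cls(profile=profile, seed=seed, connectome=conn, simulation=sim)
        for key, val in overrides.items():
            scope, _, name = key.partition(".")
            if not name:
                raise InvalidConfigError(f"override {key!r} must be scope.name")
            target = getattr(cfg, scope, None)
            if target is None or not hasattr(target, name):
                raise InvalidConfigError(f"unknown config key {key!r}")
            setattr(target, name, val)
        return cfg

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise InvalidConfigError(f"config file {path} is not a mapping")
        for required in ("profile", "seed"):
            if required not in raw:
                raise InvalidConfigError(f"missing config key {required!r} in {path}")
        cfg = cls.default(profile=raw["profile"], seed=int(raw["seed"]))
        for scope in ("connectome", "simulation", "analysis"):
            section = raw.get(scope, {})
            if not isinstance(section, dict):
                raise InvalidConfigError(f"config section {scope!r} must be a mapping")
            target = getattr(cfg, scope)
            for name, val in section.items():
                if not hasattr(target, name):
                    raise InvalidConfigError(f"unknown config key {scope}.{name}")
                setattr(target, name, val)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"]["areas_cm2"] = [float(a) for a in d["analysis"]["areas_cm2"]]
        d["analysis"]["ssi_radii"] = [float(r) for r in d["analysis"]["ssi_radii"]]
        return d


def reference_center(net: ConnectomeNetwork, smap: SurfaceMap = None,
                     area_cm2: float = 100.0, min_members: int = 5) -> int:
    """Default centre for local-wave analyses: the lowest-degree node.

    Local radial waves are strongest around non-hub regions, so the
    least-connected node is the canonical example location.  When a map
    is given, nodes whose grouping disk holds fewer than ``min_members``
    same-hemisphere neighbours (possible at the stretched map periphery)
    are passed over for the next-lowest-degree node.
    """
    order = np.argsort(net.degrees)
    if smap is None:
        return int(order[0])
    radius_mm = np.sqrt(area_cm2 / np.pi) * 10.0
    for j in order:
        same = smap.hemisphere == smap.hemisphere[j]
        d = np.linalg.norm(smap.coords2d - smap.coords2d[j], axis=1)
        if int((same & (d <= radius_mm)).sum()) >= min_members:
            return int(j)
    return int(order[0])


def experiment_metrics(net: ConnectomeNetwork, traj: PhaseTrajectory,
                       smap: SurfaceMap, fld, cfg: ExperimentConfig,
                       quick: bool = False) -> dict:
    """Compute the summary statistics of one run.

    ``quick`` restricts the computation to the four sweep panels
    (median speed, mean pairwise d, mean UCI slope, mean R).
    """
    ana = cfg.analysis
    R = order_parameter_series(traj)
    speeds = fld.speeds[np.isfinite(fld.speeds)]
    uci_sl = mx.uci_slopes(traj, net.delays,
                           literal_delay_term=ana.literal_uci_delay)
    uci_mean, uci_t, uci_p = mx.slope_t_test(uci_sl)

    # the quick path only needs the observed d, so a token null suffices
    n_perm = 50 if quick else ana.n_perm
    seg = mx.segmentation(traj.rel_phases, net.network_labels, n_perm=n_perm,
                          seed=child_seed(cfg.seed, "permutations"),
                          alpha=ana.alpha)

    summary = {
        "n_nodes": int(net.n_nodes),
        "n_samples": int(traj.n_samples),
        "R_mean": float(R.mean()),
        "speed_median": float(np.median(speeds)) if speeds.size else float("nan"),
        "speed_iqr_low": float(np.quantile(speeds, 0.25)) if speeds.size else float("nan"),
        "speed_iqr_high": float(np.quantile(speeds, 0.75)) if speeds.size else float("nan"),
        "uci_slope_mean": float(uci_mean),
        "uci_slope_t": float(uci_t),
        "uci_slope_p": float(uci_p),
        "segmentation_d_mean": float(seg.mean_pairwise_d),
        "segmentation_null_q95": float(seg.null_d_mean_q95),
        "anova_F": float(seg.anova_F),
        "anova_p": float(seg.anova_p),
    }
    if quick:
        return summary

    pca = mx.relative_phase_pca(traj.rel_phases)
    r_deg, t_deg, p_deg = mx.network_phase_degree_correlation(
        traj.rel_phases, net.network_labels, net.degrees)
    center = reference_center(net, smap, area_cm2=ana.grouping_area_cm2)
    scan = mx.grouping_scan(smap, traj, center, areas_cm2=ana.areas_cm2)
    ssi_slopes = mx.ssi_slope(traj, fld, smap, center, ana.ssi_radii,
                              dr=ana.ssi_dr, raw_gradient=ana.raw_gradient_ssi)
    gfs = mx.gradient_frequency_slope(
        smap, traj, fld, center, area_cm2=ana.grouping_area_cm2,
        n_perm=ana.n_perm, seed=child_seed(cfg.seed, "permutations"))
    opt_map = mx.optimal_area_map(smap, traj, areas_cm2=ana.areas_cm2)

    summary.update({
        "pc1_explained": float(pca.explained_ratio[0]),
        "n_significant_pairs": int(seg.significant.sum() // 2),
        "n_pairs": int(seg.n_pairs),
        "phase_degree_r": float(r_deg),
        "phase_degree_t": float(t_deg),
        "phase_degree_p": float(p_deg),
        "reference_center": int(center),
        "reference_center_degree": float(net.degrees[center]),
        "ssi_slope_by_radius": {
            float(r): (float(s) if np.isfinite(s) else None)
            for r, s in zip(ana.ssi_radii, ssi_slopes)
        },
        "grouping_optimal_area_cm2": float(scan.optimal_area_cm2),
        "optimal_area_map_mean_cm2": float(np.nanmean(opt_map)),
        "gradient_freq_slope": float(gfs.slope),
        "gradient_freq_p": float(gfs.p_value),
    })
    return summary


def run_experiment(config, out_dir=None) -> dict:
    """Execute the full pipeline; optionally persist all artifacts.

    ``config`` may be an :class:`ExperimentConfig` or a path to a
    YAML/JSON config file.  Returns the summary dictionary; when
    ``out_dir`` is given, writes connectome tables, trajectory tables,
    wave-field table, summary.json and manifest.json there.
    """
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_file(config)
    stage = "generate"
    try:
        net = generate_connectome(config.connectome)
        stage = "simulate"
        traj = simulate(net, config.simulation)
        stage = "project"
        smap = project(net)
        stage = "wave_field"
        fld = compute_wave_field(smap, traj,
                                 window_sigma=config.analysis.window_sigma)
        stage = "analyze"
        summary = experiment_metrics(net, traj, smap, fld, config)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_connectome(net, out / "connectome")
        save_trajectory(traj, out / "trajectory")
        nodes = pd.read_csv(out / "connectome" / "nodes.tsv", sep="\t")
        nodes["map_x"] = smap.coords2d[:, 0]
        nodes["map_y"] = smap.coords2d[:, 1]
        nodes["degree"] = net.degrees
        nodes.to_csv(out / "connectome" / "nodes.tsv", sep="\t", index=False)
        S, n = fld.speeds.shape
        wf = pd.DataFrame({
            "time": np.repeat(traj.sample_times, n),
            "node": np.tile(np.arange(n), S),
            "gx": fld.gradients[..., 0].ravel(),
            "gy": fld.gradients[..., 1].ravel(),
            "speed": fld.speeds.ravel(),
            "dir": np.arctan2(fld.prop_dirs[..., 1], fld.prop_dirs[..., 0]).ravel(),
        })
        wf.to_csv(out / "wavefield.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        cfg_dict = config.to_dict()
        manifest = {
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "versions": _versions(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return summary


def _versions() -> dict:
    import numba
    import scipy
    import sklearn

    from . import __version__

    return {
        "cortexwaves": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "numba": numba.__version__,
    }


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """Grid specification for coupling / dispersion / frequency sweeps."""

    coupling_values: tuple = (0.1,)
    sigma_ratio_values: tuple = (0.05,)   # sigma_f / f0
    f0_values: tuple = (10.0,)            # Hz
    replicates: int = 1
    seed: int = 0
    profile: str = "ci"

    def validate(self) -> None:
        for name in ("coupling_values", "sigma_ratio_values", "f0_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(v <= 0 for v in vals):
                raise InvalidConfigError(f"{name} must be positive and nonempty")
        if self.replicates < 1:
            raise InvalidConfigError("replicates must be >= 1")


def run_sweep(spec: SweepSpec, out_path=None) -> pd.DataFrame:
    """Run the scaled experiment over the sweep grid.

    Each grid point reports median propagation speed, mean pairwise
    segmentation d, mean UCI slope and mean order parameter; per-point
    failures are recorded in an ``error`` column and the sweep
    continues.  A single-point sweep reproduces the corresponding
    ``run_experiment`` panels exactly.
    """
    spec.validate()
    rows = []
    for coupling in spec.coupling_values:
        for ratio in spec.sigma_ratio_values:
            for f0 in spec.f0_values:
                for rep in range(spec.replicates):
                    seed = spec.seed + rep
                    row = {
                        "coupling": coupling, "sigma_ratio": ratio,
                        "f0": f0, "replicate": rep, "seed": seed,
                    }
                    try:
                        cfg = ExperimentConfig.default(
                            profile=spec.profile, seed=seed)
                        cfg.simulation.coupling = float(coupling)
                        cfg.simulation.f0 = float(f0)
                        cfg.simulation.sigma_f = float(ratio * f0)
                        net = generate_connectome(cfg.connectome)
                        traj = simulate(net, cfg.simulation)
                        smap = project(net)
                        fld = compute_wave_field(
                            smap, traj, window_sigma=cfg.analysis.window_sigma)
                        summary = experiment_metrics(net, traj, smap, fld,
                                                     cfg, quick=True)
                        row.update({
                            "speed_median": summary["speed_median"],
                            "segmentation_d_mean": summary["segmentation_d_mean"],
                            "uci_slope_mean": summary["uci_slope_mean"],
                            "R_mean": summary["R_mean"],
                            "error": "",
                        })
                    except Exception as exc:  # record and continue
                        logger.warning("sweep point failed: %s", exc)
                        row.update({
                            "speed_median": np.nan,
                            "segmentation_d_mean": np.nan,
                            "uci_slope_mean": np.nan,
                            "R_mean": np.nan,
                            "error": str(exc),
                        })
                    rows.append(row)
    table = pd.DataFrame(rows)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, sep="\t", index=False)
    return table
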