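"""Delay-coupled Kuramoto integration with an intermittent frequency schedule.

The model is a network of phase oscillators

    dtheta_j/dt = omega_j(t) + lambda * sum_k w_jk sin(theta_k(t - tau_jk) - theta_j(t))

where ``tau_jk`` are axonal conduction delays and the intrinsic angular
frequencies ``omega_j = 2 pi f_j`` are redrawn from Gaussian(f0, sigma_f)
at fixed epoch boundaries.  Integration is forward Euler with a ring
buffer holding the phase history up to the maximum delay.  One phase
snapshot is retained per epoch (at ``sample_offset`` after the epoch
start) once the initial ``discard`` window has passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix

from ._rng import substream
from .connectome import ConnectomeNetwork
from .errors import InvalidConfigError, IntegrationDivergedError, UndefinedMeanError

logger = logging.getLogger("cortexwaves.simulate")

TWO_PI = 2.0 * np.pi


@dataclass
class SimulationConfig:
    """Integration and frequency-schedule parameters.

    ``coupling`` is the global gain ``lambda`` multiplying the weighted
    sine interactions; with generated connectomes (mean nonzero weight
    one) its effective per-node strength scales with the number of
    connections, so the default is tied to the package's standard
    network size.
    """

    f0: float = 10.0          # Hz, mean intrinsic frequency
    sigma_f: float = 0.5      # Hz, SD of intrinsic frequency
    coupling: float = 0.5     # global coupling lambda
    dt: float = 5e-4          # s, Euler step
    t_total: float = 101.0    # s
    epoch_len: float = 0.5    # s between frequency redraws
    sample_offset: float = 0.3  # s after each epoch start at which to sample
    discard: float = 1.0      # s discarded from the start
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise InvalidConfigError("dt must be positive")
        if self.f0 <= 0:
            raise InvalidConfigError("f0 must be positive")
        if self.sigma_f < 0:
            raise InvalidConfigError("sigma_f must be nonnegative")
        if not 0.0 <= self.sample_offset < self.epoch_len:
            raise InvalidConfigError("sample_offset must lie in [0, epoch_len)")
        if self.t_total < self.discard + self.epoch_len:
            raise InvalidConfigError("t_total must cover discard + one epoch")


@dataclass
class PhaseTrajectory:
    """Sampled output of a simulation run.

    phases and rel_phases are wrapped to (-pi, pi]; ``inst_rates`` is the
    model right-hand side (rad/s) evaluated at each snapshot, and
    ``epoch_freqs`` holds the scheduled intrinsic frequency (Hz) of every
    epoch, sampled or not.
    """

    sample_times: np.ndarray   # (S,)
    phases: np.ndarray         # (S, N)
    rel_phases: np.ndarray     # (S, N)
    inst_rates: np.ndarray     # (S, N) rad/s
    epoch_freqs: np.ndarray    # (n_epochs, N) Hz
    sample_epochs: np.ndarray  # (S,) epoch index per sample
    config: SimulationConfig = None

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    @property
    def sample_freqs(self) -> np.ndarray:
        """Per-sample, per-node intrinsic frequency (Hz)."""
        return self.epoch_freqs[self.sample_epochs]


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(theta, dtype=float)))


def relative_phase(phases_snapshot: np.ndarray) -> np.ndarray:
    """Phase of each node relative to the network mean phasor argument.

    Raises
    ------
    UndefinedMeanError
        If the mean phasor has (numerically) zero resultant length, in
        which case the mean direction is undefined.
    """
    theta = np.asarray(phases_snapshot, dtype=float)
    if theta.size == 0:
        raise UndefinedMeanError("empty phase snapshot")
    mean_phasor = np.exp(1j * theta).mean()
    if np.abs(mean_phasor) < 1e-9:
        raise UndefinedMeanError("zero resultant: circular mean undefined")
    return wrap_angle(theta - np.angle(mean_phasor))


def order_parameter(phases_snapshot: np.ndarray) -> float:
    """Kuramoto order parameter R = |mean exp(i theta)| in [0, 1]."""
    theta = np.asarray(phases_snapshot, dtype=float)
    return float(np.abs(np.exp(1j * theta).mean()))


@njit(cache=True)
def _integrate_kernel(indptr, indices, weights, lags, lam, omega, epoch_steps,
                      theta_init, omega0, dt, n_steps, sample_steps, buf_size):
    n = theta_init.size
    n_samples = sample_steps.size
    hist = np.empty((buf_size, n))
    # pre-t=0 history: backward extrapolation at initial intrinsic rate
    for m in range(buf_size):
        for j in range(n):
            hist[(-m) % buf_size, j] = theta_init[j] - omega0[j] * m * dt
    out_phases = np.empty((n_samples, n))
    out_rates = np.empty((n_samples, n))
    rhs = np.empty(n)
    ptr = 0
    for t in range(n_steps):
        row = t % buf_size
        epoch = t // epoch_steps
        if epoch >= omega.shape[0]:
            epoch = omega.shape[0] - 1
        for j in range(n):
            theta_j = hist[row, j]
            acc = omega[epoch, j]
            for e in range(indptr[j], indptr[j + 1]):
                k = indices[e]
                theta_k = hist[(t - lags[e]) % buf_size, k]
                acc += lam * weights[e] * np.sin(theta_k - theta_j)
            rhs[j] = acc
        if ptr < n_samples and t == sample_steps[ptr]:
            for j in range(n):
                out_phases[ptr, j] = hist[row, j]
                out_rates[ptr, j] = rhs[j]
            ptr += 1
        nxt = (t + 1) % buf_size
        ok = True
        for j in range(n):
            val = hist[row, j] + dt * rhs[j]
            hist[nxt, j] = val
            if not np.isfinite(val):
                ok = False
        if not ok:
            return out_phases, out_rates, t + 1
    return out_phases, out_rates, -1


def _integrate_python(indptr, indices, weights, lags, lam, omega, epoch_steps,
                      theta_init, omega0, dt, n_steps, sample_steps, buf_size):
    """Pure-Python twin of the compiled kernel (reference for tests)."""
    n = theta_init.size
    hist = np.empty((buf_size, n))
    for m in range(buf_size):
        hist[(-m) % buf_size] = theta_init - omega0 * m * dt
    out_phases = np.empty((sample_steps.size, n))
    out_rates = np.empty((sample_steps.size, n))
    ptr = 0
    for t in range(n_steps):
        row = t % buf_size
        epoch = min(t // epoch_steps, omega.shape[0] - 1)
        rhs = omega[epoch].copy()
        for j in range(n):
            for e in range(indptr[j], indptr[j + 1]):
                k = indices[e]
                theta_k = hist[(t - lags[e]) % buf_size, k]
                rhs[j] += lam * weights[e] * np.sin(theta_k - hist[row, j])
        if ptr < sample_steps.size and t == sample_steps[ptr]:
            out_phases[ptr] = hist[row]
            out_rates[ptr] = rhs
            ptr += 1
        hist[(t + 1) % buf_size] = hist[row] + dt * rhs
        if not np.all(np.isfinite(hist[(t + 1) % buf_size])):
            return out_phases, out_rates, t + 1
    return out_phases, out_rates, -1


def simulate(net: ConnectomeNetwork, cfg: SimulationConfig,
             init_phases: np.ndarray | None = None,
             epoch_freqs: np.ndarray | None = None,
             _kernel=_integrate_kernel) -> PhaseTrajectory:
    """Integrate the delay-coupled network and return sampled snapshots.

    Parameters
    ----------
    net : ConnectomeNetwork
    cfg : SimulationConfig
    init_phases : array, optional
        Initial phases; default uniform on (-pi, pi] from the seed's
        ``init_phases`` substream.
    epoch_freqs : array (n_epochs, n_nodes), optional
        Explicit intrinsic-frequency schedule (Hz), replacing the
        Gaussian(f0, sigma_f) redraws; useful for controlled detunings.

    Raises
    ------
    InvalidConfigError
        If ``dt`` is not smaller than the shortest positive delay of a
        coupled pair (such delays would round to instantaneous coupling).
    IntegrationDivergedError
        If any phase becomes non-finite.
    """
    cfg.validate()
    n = net.n_nodes
    coupled = net.weights > 0
    pos_delays = net.delays[coupled & (net.delays > 0)]
    if pos_delays.size and cfg.dt >= pos_delays.min():
        raise InvalidConfigError(
            f"dt={cfg.dt} s is not below the minimum positive coupled delay "
            f"({pos_delays.min():.3e} s); reduce dt"
        )

    sched_rng = substream(cfg.seed, "schedule")
    init_rng = substream(cfg.seed, "init_phases")

    n_steps = int(round(cfg.t_total / cfg.dt))
    epoch_steps = int(round(cfg.epoch_len / cfg.dt))
    n_epochs = int(np.ceil(n_steps / epoch_steps))
    if epoch_freqs is None:
        epoch_freqs = sched_rng.normal(cfg.f0, cfg.sigma_f, size=(n_epochs, n))
    else:
        epoch_freqs = np.asarray(epoch_freqs, dtype=float)
        if epoch_freqs.shape != (n_epochs, n):
            raise InvalidConfigError(
                f"epoch_freqs must have shape ({n_epochs}, {n})"
            )

    if init_phases is None:
        theta0 = init_rng.uniform(-np.pi, np.pi, size=n)
    else:
        theta0 = np.asarray(init_phases, dtype=float)
        if theta0.shape != (n,):
            raise InvalidConfigError("init_phases must have shape (n_nodes,)")

    sample_epochs = np.array([
        e for e in range(n_epochs)
        if e * cfg.epoch_len >= cfg.discard - 1e-12
        and int(round((e * cfg.epoch_len + cfg.sample_offset) / cfg.dt)) < n_steps
    ], dtype=np.int64)
    sample_steps = np.array([
        int(round((e * cfg.epoch_len + cfg.sample_offset) / cfg.dt))
        for e in sample_epochs
    ], dtype=np.int64)

    w_csr = csr_matrix(net.weights)
    lags = np.rint(net.delays[net.weights > 0] / cfg.dt).astype(np.int64)
    # CSR data order matches boolean-mask row-major order
    buf_size = int(lags.max()) + 1 if lags.size else 1

    omega = TWO_PI * epoch_freqs
    out_phases, out_rates, bad_step = _kernel(
        w_csr.indptr.astype(np.int64), w_csr.indices.astype(np.int64),
        w_csr.data.astype(np.float64), lags, float(cfg.coupling), omega,
        epoch_steps, theta0.astype(np.float64), omega[0].copy(),
        float(cfg.dt), n_steps, sample_steps, buf_size,
    )
    if bad_step >= 0:
        raise IntegrationDivergedError(bad_step * cfg.dt)

    phases = wrap_angle(out_phases)
    mean_phasor = np.exp(1j * phases).mean(axis=1, keepdims=True)
    if np.any(np.abs(mean_phasor) < 1e-9):
        raise UndefinedMeanError("zero resultant in a snapshot: relative phase undefined")
    rel = wrap_angle(phases - np.angle(mean_phasor))

    R = np.abs(np.exp(1j * phases).mean(axis=1))
    for s, (e, t) in enumerate(zip(sample_epochs, sample_steps * cfg.dt)):
        logger.info("epoch %d (t=%.2fs): mean f=%.3f Hz, R=%.3f",
                    e, t, epoch_freqs[e].mean(), R[s])
    return PhaseTrajectory(
        sample_times=sample_steps * cfg.dt,
        phases=phases,
        rel_phases=rel,
        inst_rates=out_rates,
        epoch_freqs=epoch_freqs,
        sample_epochs=sample_epochs,
        config=cfg,
    )


def order_parameter_series(traj: PhaseTrajectory) -> np.ndarray:
    """Order parameter R at every retained snapshot."""
    return np.abs(np.exp(1j * traj.phases).mean(axis=1))


# ---------------------------------------------------------------------------
# Persistence: a trajectory directory of delimited text tables
# ---------------------------------------------------------------------------

def save_trajectory(traj: PhaseTrajectory, out_dir) -> "Path":
    """Write samples.tsv, epoch_freqs.tsv and config.yaml to a directory."""
    import pandas as pd
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    S, n = traj.phases.shape
    samples = pd.DataFrame({
        "time": np.repeat(traj.sample_times, n),
        "node": np.tile(np.arange(n), S),
        "phase": traj.phases.ravel(),
        "rel_phase": traj.rel_phases.ravel(),
        "inst_rate": traj.inst_rates.ravel(),
    })
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    np.savetxt(out / "epoch_freqs.tsv", traj.epoch_freqs, delimiter="\t")
    np.savetxt(out / "sample_epochs.tsv", traj.sample_epochs, fmt="%d")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(traj.config) if traj.config else {}, fh)
    return out


def load_trajectory(in_dir) -> PhaseTrajectory:
    """Load a trajectory directory written by :func:`save_trajectory`."""
    import pandas as pd
    import yaml
    from pathlib import Path

    src = Path(in_dir)
    samples = pd.read_csv(src / "samples.tsv", sep="\t")
    times = np.unique(samples["time"].to_numpy())
    n = samples["node"].max() + 1
    S = times.size

    def pivot(col):
        return samples.sort_values(["time", "node"])[col].to_numpy().reshape(S, n)

    with open(src / "config.yaml") as fh:
        cfg_dict = yaml.safe_load(fh) or {}
    cfg = SimulationConfig(**cfg_dict) if cfg_dict else None
    return PhaseTrajectory(
        sample_times=times,
        phases=pivot("phase"),
        rel_phases=pivot("rel_phase"),
        inst_rates=pivot("inst_rate"),
        epoch_freqs=np.loadtxt(src / "epoch_freqs.tsv", delimiter="\t", ndmin=2),
        sample_epochs=np.loadtxt(src / "sample_epochs.tsv", dtype=np.int64, ndmin=1),
        config=cfg,
    )
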