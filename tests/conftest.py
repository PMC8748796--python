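"""Shared fixtures: small networks and the session-scoped reference run.

The "reference run" is the package's standard scaled study condition
(150 nodes, 21 s, f0 = 10 Hz, sigma_f/f0 = 0.05): one simulation shared
by all end-to-end tests, plus a matched zero-dispersion control.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from cortexwaves import (
    ExperimentConfig,
    SyntheticConfig,
    compute_wave_field,
    generate_connectome,
    project,
    simulate,
)

REFERENCE_SEED = 7


def _run(cfg: ExperimentConfig) -> SimpleNamespace:
    net = generate_connectome(cfg.connectome)
    traj = simulate(net, cfg.simulation)
    smap = project(net)
    fld = compute_wave_field(smap, traj, window_sigma=cfg.analysis.window_sigma)
    return SimpleNamespace(cfg=cfg, net=net, traj=traj, smap=smap, fld=fld)


@pytest.fixture(scope="session")
def reference_run():
    """Standard scaled run: N=150, 40 retained epochs, sigma_f = 0.5 Hz."""
    return _run(ExperimentConfig.default(profile="ci", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def null_run():
    """Matched control with sigma_f = 0: no frequency heterogeneity."""
    cfg = ExperimentConfig.default(profile="ci", seed=REFERENCE_SEED)
    cfg.simulation.sigma_f = 0.0
    return _run(cfg)


@pytest.fixture()
def small_net():
    """A fast 60-node network for unit tests."""
    return generate_connectome(SyntheticConfig(n_nodes=60, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
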