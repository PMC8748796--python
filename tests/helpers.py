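"""Hand-built network, map, trajectory and wave-field stubs for tests."""

import numpy as np

from cortexwaves import ConnectomeNetwork, PhaseTrajectory, SurfaceMap
from cortexwaves.wavefield import WaveField

TWO_PI = 2.0 * np.pi


def toy_net(weights, delays_s, v=10.8):
    """Network from explicit weight and delay matrices (collinear layout)."""
    w = np.asarray(weights, dtype=float)
    tau = np.asarray(delays_s, dtype=float)
    n = w.shape[0]
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * 20.0
    return ConnectomeNetwork(
        coords3d=coords,
        hemisphere=np.array(["L"] * n),
        weights=w,
        tract_lengths=tau * v * 1000.0,
        delays=tau,
        volumes=np.full(n, 2000.0),
        network_labels=np.ones(n, dtype=np.int64),
        conduction_velocity=v,
    )


def flat_map(coords2d, hemisphere=None):
    """A SurfaceMap standing in for a single flat patch of cortex."""
    coords2d = np.asarray(coords2d, dtype=float)
    n = coords2d.shape[0]
    hemi = np.array(["L"] * n) if hemisphere is None else hemisphere
    return SurfaceMap(
        coords2d=coords2d,
        hemisphere=hemi,
        hemisphere_centers=np.zeros((2, 2)),
        sphere_radii=np.array([60.0, 60.0]),
        poles=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
        antipodal=np.zeros(n, dtype=bool),
    )


def fake_trajectory(rel_phases, freqs):
    """Trajectory stub from explicit relative phases and frequencies."""
    S, n = rel_phases.shape
    return PhaseTrajectory(
        sample_times=1.3 + 0.5 * np.arange(S),
        phases=rel_phases.copy(),
        rel_phases=rel_phases.copy(),
        inst_rates=np.full((S, n), TWO_PI * 10.0),
        epoch_freqs=freqs.copy(),
        sample_epochs=np.arange(S),
        config=None,
    )


def fake_field(prop_field_by_sample):
    """WaveField whose outward-positive propagation field is as given."""
    g = np.asarray(prop_field_by_sample, dtype=float)
    S, n, _ = g.shape
    return WaveField(
        gradients=-g,
        speeds=np.ones((S, n)),
        prop_dirs=g / np.maximum(np.linalg.norm(g, axis=-1, keepdims=True),
                                 1e-12),
        inst_rates=np.ones((S, n)),
        window_sigma=20.0,
    )
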