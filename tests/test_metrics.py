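"""UCI, segmentation effect size, phase PCA, SSI slopes, grouping scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexwaves import (
    ZeroVarianceError,
    cohens_d,
    gradient_frequency_slope,
    grouping_scan,
    network_phase_degree_correlation,
    relative_phase_pca,
    segmentation,
    slope_t_test,
    ssi_slope,
    uci,
    uci_slope,
)
from cortexwaves.metrics import ols_slope, optimal_area_map

from helpers import fake_field, fake_trajectory, flat_map

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# UCI
# ---------------------------------------------------------------------------

def test_uci_extremes():
    f0 = 10.0
    tau = np.array([[0.0, 0.004, 0.007],
                    [0.004, 0.0, 0.002],
                    [0.007, 0.002, 0.0]])
    offs = TWO_PI * f0 * tau
    theta = np.array([0.0, -offs[0, 1], -offs[0, 2]])
    # node 0 leads each partner by exactly the delay phase -> U_0 = 1
    assert uci(theta, tau, f0)[0] == pytest.approx(1.0, abs=1e-12)
    theta_pi = np.array([0.0, -offs[0, 1] + np.pi, -offs[0, 2] + np.pi])
    # antiphase arrival: only the self term (1/N) survives
    assert uci(theta_pi, tau, f0)[0] == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_uci_three_node_hand_case():
    """Direct scalar evaluation of the defining sum."""
    f0 = 10.0
    theta = np.array([0.0, 0.4, 0.9])
    offsets = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.15], [0.2, 0.15, 0.0]])
    tau = offsets / (TWO_PI * f0)
    expected_u0 = (
        (0.5 * np.cos(0.0 - 0.0 - 0.0) + 0.5)
        + (0.5 * np.cos(0.0 - 0.4 - 0.1) + 0.5)
        + (0.5 * np.cos(0.0 - 0.9 - 0.2) + 0.5)
    ) / 3.0
    assert uci(theta, tau, f0)[0] == pytest.approx(expected_u0, abs=1e-12)


def test_uci_literal_delay_variant_differs():
    tau = np.array([[0.0, 0.004], [0.004, 0.0]])
    theta = np.array([0.2, -0.3])
    a = uci(theta, tau, 10.0)
    b = uci(theta, tau, 10.0, literal_delay_term=True)
    assert not np.allclose(a, b)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-10.0, 10.0))
def test_uci_invariant_under_global_rotation(shift):
    rng = np.random.default_rng(99)
    theta = rng.uniform(-np.pi, np.pi, size=6)
    tau = np.abs(rng.normal(0.005, 0.002, size=(6, 6)))
    tau = (tau + tau.T) / 2
    np.fill_diagonal(tau, 0.0)
    np.testing.assert_allclose(uci(theta + shift, tau, 10.0),
                               uci(theta, tau, 10.0), atol=1e-9)


def test_uci_slope_examples():
    f = np.array([9.0, 10.0, 11.0, 12.0])
    slope, _ = uci_slope(np.full(4, 0.6), f)
    assert slope == pytest.approx(0.0, abs=1e-12)
    slope, t = uci_slope(0.05 * f + 0.1, f)
    assert slope == pytest.approx(0.05, abs=1e-12)
    with pytest.raises(ZeroVarianceError):
        uci_slope(np.array([0.1, 0.2, 0.3]), np.full(3, 10.0))


# ---------------------------------------------------------------------------
# Segmentation / Cohen's d
# ---------------------------------------------------------------------------

def test_cohens_d_hand_case_exact():
    """P_i={0.1,0.2,0.3}, P_j={0.5,0.6,0.7}: independent scalar evaluation."""
    p_i = np.array([0.1, 0.2, 0.3])
    p_j = np.array([0.5, 0.6, 0.7])
    vi = sum((x - 0.2) ** 2 for x in p_i) / 2.0
    vj = sum((x - 0.6) ** 2 for x in p_j) / 2.0
    expected = abs(0.2 - 0.6) / np.sqrt((2 * vi + 2 * vj) / 6.0)
    assert cohens_d(p_i, p_j) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(4.898979485566356, abs=1e-12)
    assert cohens_d(p_i, p_i) == 0.0
    # scale-free: doubling all deviations leaves d unchanged
    assert cohens_d(2 * p_i, 2 * p_j) == pytest.approx(cohens_d(p_i, p_j),
                                                       abs=1e-12)
    constant = np.full(3, 0.25)  # binary-exact so variances are exactly zero
    assert cohens_d(constant, constant + 1.0) == np.inf  # zero pooled variance


def test_segmentation_matrix_matches_direct_formula(rng):
    labels = np.repeat(np.arange(1, 8), 10)
    phases = rng.normal(0.0, 0.5, size=(5, 70))
    res = segmentation(phases, labels, n_perm=50, seed=1)
    assert res.n_pairs == 21
    for s in (0, 3):
        for i in range(7):
            for j in range(7):
                direct = cohens_d(phases[s][labels == i + 1],
                                  phases[s][labels == j + 1]) if i != j else 0.0
                assert res.d_matrix[s, i, j] == pytest.approx(direct, abs=1e-10)
    # symmetry and zero diagonal
    np.testing.assert_allclose(res.d_matrix, res.d_matrix.transpose(0, 2, 1))


def test_segmentation_null_when_labels_uninformative(rng):
    labels = np.repeat(np.arange(1, 8), 8)
    phases = rng.normal(0.0, 0.5, size=(20, 56))
    res = segmentation(phases, labels, n_perm=500, seed=2)
    # i.i.d. phases: observed mean d should sit inside the shuffled null
    assert res.mean_pairwise_d < res.null_d_mean_q95
    assert res.significant.sum() == 0
    assert res.anova_p > 0.001


def test_segmentation_detects_planted_separation(rng):
    labels = np.repeat(np.arange(1, 8), 8)
    shift = 0.4 * (labels - 4)
    phases = rng.normal(0.0, 0.3, size=(20, 56)) + shift
    res = segmentation(phases, labels, n_perm=500, seed=3)
    assert res.mean_pairwise_d > res.null_d_mean_q95
    assert res.significant.sum() > 0
    assert res.anova_p < 1e-6


def test_segmentation_rejects_empty_group():
    with pytest.raises(ValueError, match="empty"):
        cohens_d(np.array([]), np.array([1.0]))


def test_network_phase_degree_correlation_sign(rng):
    labels = np.repeat(np.arange(1, 8), 8)
    degrees = rng.uniform(0.0, 1.0, size=56)
    # plant: network-mean phase decreases with network-mean degree
    net_deg = np.array([degrees[labels == c].mean() for c in range(1, 8)])
    phases = np.tile(-2.0 * net_deg[labels - 1], (10, 1))
    phases += rng.normal(0, 0.01, size=phases.shape)
    r, t, p = network_phase_degree_correlation(phases, labels, degrees)
    assert r < -0.95 and p < 0.01


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_recovers_planted_rank_one_field(rng):
    u = rng.standard_normal(80)
    u /= np.linalg.norm(u)
    c = rng.standard_normal(60)
    phases = np.outer(c, u) * 0.3 + rng.normal(0, 1e-3, size=(60, 80))
    res = relative_phase_pca(phases)
    assert res.explained_ratio[0] > 0.95
    assert abs(res.components[0] @ u) > 0.99


def test_pca_white_noise_has_no_dominant_component(rng):
    phases = rng.normal(0, 0.1, size=(2000, 10))
    res = relative_phase_pca(phases)
    assert res.explained_ratio.max() < 0.15  # ~1/N each


def test_pca_duplicated_samples_identical_components(rng):
    phases = rng.normal(0, 0.2, size=(15, 30))
    a = relative_phase_pca(phases)
    b = relative_phase_pca(np.vstack([phases, phases]))
    for k in range(3):
        assert abs(a.components[k] @ b.components[k]) == pytest.approx(1.0,
                                                                       abs=1e-9)


def test_pca_warns_on_wide_phase_spread(rng):
    phases = rng.uniform(-np.pi, np.pi, size=(20, 50))
    with pytest.warns(UserWarning, match="linearized"):
        relative_phase_pca(phases)


# ---------------------------------------------------------------------------
# SSI slope vs frequency
# ---------------------------------------------------------------------------

def _radial_layout(rng, n=400, extent=80.0):
    coords = np.vstack([[0.0, 0.0], rng.uniform(-extent, extent, size=(n, 2))])
    rhat = coords / np.maximum(np.linalg.norm(coords, axis=1, keepdims=True),
                               1e-12)
    rhat[0] = 0.0
    return coords, rhat


def test_ssi_slope_planted_frequency_coupling(rng):
    """Radial field with magnitude 0.1 f / 30 -> slope of SSI(30) ~ 0.1."""
    coords, rhat = _radial_layout(rng)
    S = 50
    f = np.tile(rng.normal(10.0, 0.5, size=(S, 1)), (1, coords.shape[0]))
    field = (0.1 / 30.0) * f[:, :, None] * rhat[None, :, :]
    traj = fake_trajectory(np.zeros_like(f), f)
    slopes = ssi_slope(traj, fake_field(field), flat_map(coords), 0,
                       radii=[30.0], dr=10.0)
    members = (np.linalg.norm(coords, axis=1) > 20.0) \
        & (np.linalg.norm(coords, axis=1) < 40.0)
    expected = 0.1 / 30.0 * np.linalg.norm(coords[members], axis=1).mean()
    assert slopes[0] == pytest.approx(expected, rel=1e-6)
    assert slopes[0] == pytest.approx(0.1, rel=0.1)


def test_ssi_slope_zero_when_field_frequency_independent(rng):
    coords, rhat = _radial_layout(rng)
    S = 50
    f = rng.normal(10.0, 0.5, size=(S, coords.shape[0]))
    field = np.tile(0.01 * rhat[None, :, :], (S, 1, 1))
    traj = fake_trajectory(np.zeros_like(f), f)
    slopes = ssi_slope(traj, fake_field(field), flat_map(coords), 0,
                       radii=[30.0], dr=10.0)
    assert slopes[0] == pytest.approx(0.0, abs=1e-12)


def test_ssi_slope_missing_with_too_few_samples(rng):
    coords, rhat = _radial_layout(rng)
    f = rng.normal(10.0, 0.5, size=(5, coords.shape[0]))
    field = np.tile(0.01 * rhat[None, :, :], (5, 1, 1))
    traj = fake_trajectory(np.zeros_like(f), f)
    slopes = ssi_slope(traj, fake_field(field), flat_map(coords), 0,
                       radii=[30.0], min_samples=20)
    assert np.isnan(slopes[0])


# ---------------------------------------------------------------------------
# Grouping scan
# ---------------------------------------------------------------------------

def _planted_local_coupling(rng, rho, n=600, S=120, c=0.5, extent=100.0):
    """Phases respond to the rho-local mean frequency, globally centred."""
    coords = rng.uniform(-extent, extent, size=(n, 2))
    f = rng.normal(10.0, 0.5, size=(S, n))
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    M = (d2 <= rho**2).astype(float)
    local = (f @ M.T) / M.sum(axis=1)
    th = c * (local - f.mean(axis=1, keepdims=True))
    return coords, f, th


def test_grouping_scan_recovers_planted_scale(rng):
    areas = np.geomspace(2.0, 300.0, 14)
    optima = {}
    for rho in (15.0, 35.0):
        coords, f, th = _planted_local_coupling(rng, rho)
        smap = flat_map(coords)
        center = int(np.argmin(np.linalg.norm(coords, axis=1)))
        scan = grouping_scan(smap, fake_trajectory(th, f), center,
                             areas_cm2=areas)
        # interior maximum (the scanned curve is peaked, not monotone)
        imax = np.nanargmax(np.abs(scan.slopes))
        assert 0 < imax < areas.size - 1
        # the scanned optimum tracks the planted scale with a known upward
        # bias (the captured-weight curve saturates gradually past rho)
        planted_area = np.pi * rho**2 / 100.0
        assert planted_area / 2 < scan.optimal_area_cm2 < planted_area * 8
        optima[rho] = scan.optimal_area_cm2
    assert optima[15.0] < optima[35.0]  # distinct scales resolved in order


def test_grouping_scan_flags_frequency_independent_phases(rng):
    coords = rng.uniform(-60, 60, size=(200, 2))
    f = rng.normal(10.0, 0.5, size=(30, 200))
    th = np.tile(rng.normal(0, 0.3, size=200), (30, 1))  # no f dependence
    scan = grouping_scan(flat_map(coords), fake_trajectory(th, f), 0)
    finite = scan.slopes[np.isfinite(scan.slopes)]
    assert np.abs(finite).max() < 0.05  # slopes ~ 0 up to sampling noise


def test_optimal_area_map_matches_scalar_scan(rng):
    coords, f, th = _planted_local_coupling(rng, 20.0, n=250, S=60)
    smap = flat_map(coords)
    traj = fake_trajectory(th, f)
    areas = np.geomspace(5.0, 200.0, 8)
    omap = optimal_area_map(smap, traj, areas_cm2=areas)
    for center in (0, 17, 101):
        scan = grouping_scan(smap, traj, center, areas_cm2=areas)
        assert omap[center] == pytest.approx(scan.optimal_area_cm2)


# ---------------------------------------------------------------------------
# Gradient-frequency coupling with permutation inference
# ---------------------------------------------------------------------------

def test_gradient_frequency_slope_detects_planted_coupling(rng):
    coords = np.vstack([[0.0, 0.0], rng.uniform(-60, 60, size=(300, 2))])
    smap = flat_map(coords)
    n, S = coords.shape[0], 40
    hits = 0
    for trial in range(10):
        f = rng.normal(10.0, 0.5, size=(S, n))
        members = np.linalg.norm(coords, axis=1) <= np.sqrt(100 / np.pi) * 10
        x = f[:, members].mean(axis=1)
        g = np.zeros((S, n, 2))
        g[:, 0, 0] = 0.02 * (x - 10.0) + rng.normal(0, 0.001, size=S)
        traj = fake_trajectory(np.zeros((S, n)), f)
        res = gradient_frequency_slope(smap, traj, fake_field(g), 0,
                                       area_cm2=100.0, n_perm=500, seed=trial)
        hits += res.p_value < 0.05
    assert hits >= 9  # power > 0.9 for a strong planted effect


def test_gradient_frequency_slope_zero_variance_error(rng):
    coords = np.vstack([[0.0, 0.0], rng.uniform(-60, 60, size=(100, 2))])
    f = np.full((30, 101), 10.0)
    g = rng.normal(0, 0.01, size=(30, 101, 2))
    traj = fake_trajectory(np.zeros((30, 101)), f)
    with pytest.raises(ZeroVarianceError):
        gradient_frequency_slope(flat_map(coords), traj, fake_field(g), 0,
                                 n_perm=100)


# ---------------------------------------------------------------------------
# End-to-end ordering property on the reference simulation
# ---------------------------------------------------------------------------

def test_faster_nodes_lead_in_phase(reference_run):
    """Per-epoch slope of relative phase on intrinsic frequency keeps the
    sign fixed by the two-oscillator closed form (faster leads) in >= 90%
    of epochs."""
    traj = reference_run.traj
    f = traj.sample_freqs
    signs = []
    for s in range(traj.n_samples):
        signs.append(np.sign(ols_slope(f[s], traj.rel_phases[s])))
    assert np.mean(np.array(signs) > 0) >= 0.9


def test_uci_slope_positive_on_reference_run(reference_run):
    from cortexwaves import uci_slopes

    slopes = uci_slopes(reference_run.traj, reference_run.net.delays)
    mean, t, p = slope_t_test(slopes)
    assert mean > 0 and p < 0.01
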