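"""PSD estimation, order parameter, autocorrelations."""

import numpy as np
import pytest

import gpanet as gp
from gpanet.dynamics import Trajectory
from gpanet.spectra import SimSettings, _decay_ratio, empirical_boundary, hash_seed


def _traj_from_series(x, dt=0.02):
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    if x.ndim == 1:
        x = x[:, None]
    return Trajectory(t0=0.0, dt=dt, x=x, a=np.zeros_like(x))


def test_zero_trajectory_has_zero_psd():
    traj = _traj_from_series(np.zeros((4096, 3)))
    est = gp.estimate_psd(traj)
    assert est.max_power == 0.0
    assert np.all(est.psd_mean == 0)


def test_sinusoid_concentrates_at_its_frequency():
    dt = 0.02
    t = np.arange(8192) * dt
    w0 = 2.0  # rad per time unit
    traj = _traj_from_series(np.sin(w0 * t)[:, None], dt=dt)
    est = gp.estimate_psd(traj, nperseg=2048)
    w_peak = est.freqs[np.argmax(est.psd_mean)]
    dw = est.freqs[1] - est.freqs[0]
    assert abs(w_peak - w0) <= dw


def test_psd_mean_is_mean_of_per_neuron():
    rng = np.random.default_rng(0)
    traj = _traj_from_series(rng.standard_normal((4096, 5)))
    est = gp.estimate_psd(traj)
    np.testing.assert_allclose(est.psd_mean, est.psd_per_neuron.mean(axis=0), rtol=1e-12)
    assert np.all(est.psd_per_neuron >= 0)


def test_too_short_trajectory_raises():
    traj = _traj_from_series(np.zeros((100, 2)))
    with pytest.raises(ValueError, match="shorter"):
        gp.estimate_psd(traj, nperseg=1024)


def test_parseval_consistency_white_noise():
    """Integrated PSD approximates the series variance (windowing bias allowed)."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal((2**14, 4))
    traj = _traj_from_series(x, dt=0.02)
    est = gp.estimate_psd(traj, nperseg=2048)
    # est.freqs is angular; Welch returns one-sided density per cycle-frequency
    df = (est.freqs[1] - est.freqs[0]) / (2 * np.pi)
    total = np.sum(est.psd_mean) * df
    assert total == pytest.approx(x.var(), rel=0.1)


def test_driven_linear_neuron_psd_tracks_transfer_gain():
    """White-noise-driven uncoupled neuron: S_x / S_u ≈ G(omega) on the resolved band."""
    from scipy.signal import welch

    gamma, beta = 2.0, 0.5
    pop = gp.NeuronPopulation(gamma=[gamma], beta=[beta], activation="linear")
    m = gp.NetworkModel(population=pop, coupling=gp.CouplingMatrix(J=np.zeros((1, 1)), g=0.0))
    proto = gp.SharedWhiteNoise(sigma_in=0.3, weights=np.ones(1))
    traj = gp.integrate(m, proto, dt=0.02, T_total=1100.0, seed=8, store_every=1)
    post = traj.window(100.0)
    est = gp.estimate_psd(post, nperseg=4096)
    f, su = welch(post.u / post.dt, fs=1 / post.dt, window="hann", nperseg=4096,
                  noverlap=2048, detrend="constant")
    w = 2 * np.pi * f
    band = (w > 0.05) & (w < 2.0)
    ratio = est.psd_mean[band] / (su[band] * gp.transfer_gain(w[band], gamma, beta))
    assert np.all(np.abs(ratio - 1) < 0.1)


def test_order_parameter_invariances(small_gpa_network):
    """Permuting neurons or flipping the sign of x leaves the order parameter unchanged."""
    st = SimSettings(T_transient=20.0, T_measure=120.0)
    traj = gp.free_run(small_gpa_network, st, seed=3)
    op = gp.estimate_psd(traj, nperseg=512, keep_per_neuron=False).max_power
    rng = np.random.default_rng(0)
    perm = rng.permutation(traj.N)
    t_perm = Trajectory(t0=traj.t0, dt=traj.dt, x=traj.x[:, perm], a=traj.a[:, perm])
    t_flip = Trajectory(t0=traj.t0, dt=traj.dt, x=-traj.x, a=-traj.a)
    assert gp.estimate_psd(t_perm, nperseg=512, keep_per_neuron=False).max_power == pytest.approx(op)
    assert gp.estimate_psd(t_flip, nperseg=512, keep_per_neuron=False).max_power == pytest.approx(op)


def test_order_parameter_separates_regimes(small_gpa_network, chaotic_network):
    st = SimSettings(T_transient=50.0, T_measure=150.0)
    eps = gp.calibrate_silence_threshold(
        gp.TwoPoint(p=0.5, low=1.0, high=10.0), gp.Constant(0.5), 200, st, seed=7
    )
    below = gp.max_power_order_parameter(small_gpa_network, st, seed=7)
    above = gp.max_power_order_parameter(chaotic_network, st, seed=7)
    assert above > 1e-2
    assert below < above / 1e4


def test_rate_psd_total_power_bounded_by_activity(chaotic_network):
    """|tanh(x)| <= |x| implies the firing-rate PSD integrates below the activity PSD."""
    st = SimSettings(T_transient=30.0, T_measure=120.0)
    traj = gp.free_run(chaotic_network, st, seed=5)
    est_x = gp.estimate_psd(traj, nperseg=512, keep_per_neuron=False)
    est_phi = gp.estimate_psd(traj, on_phi=True, nperseg=512, keep_per_neuron=False)
    assert np.sum(est_phi.psd_mean) <= np.sum(est_x.psd_mean)
    assert est_phi.settings["on_phi"] is True


def test_autocorrelation_white_noise_short_time():
    rng = np.random.default_rng(4)
    traj = _traj_from_series(rng.standard_normal((8192, 3)), dt=0.02)
    summ = gp.autocorrelation_summary(traj)
    assert np.all(summ.correlation_times <= 2 * traj.dt + 1e-12)
    for ac in summ.mean_autocorrelation.values():
        assert ac[0] == pytest.approx(1.0)


def test_autocorrelation_linear_neuron_matches_slow_mode():
    """Correlation time of a noise-driven linear neuron ~ analytic 1/e time."""
    gamma, beta = 2.0, 0.5
    pop = gp.NeuronPopulation(gamma=[gamma], beta=[beta], activation="linear")
    m = gp.NetworkModel(population=pop, coupling=gp.CouplingMatrix(J=np.zeros((1, 1)), g=0.0))
    proto = gp.SharedWhiteNoise(sigma_in=0.3, weights=np.ones(1))
    traj = gp.integrate(m, proto, dt=0.02, T_total=4100.0, seed=9, store_every=1)
    post = traj.window(100.0)
    summ = gp.autocorrelation_summary(post, max_lag_time=30.0)
    # oracle: stationary autocovariance of the 2x2 OU system, first 1/e crossing
    A = np.array([[-1.0, 1.0], [beta, -gamma]])
    B = np.diag([1.0, 0.0])
    from scipy.linalg import solve_lyapunov, expm

    P = solve_lyapunov(A, -B)  # stationary covariance up to input scale
    lags = np.arange(0, 30.0, 0.01)
    acf = np.array([(expm(A * L) @ P)[0, 0] for L in lags]) / P[0, 0]
    t_e = lags[np.argmax(acf < 1 / np.e)]
    assert summ.correlation_times[0] == pytest.approx(t_e, rel=0.2)


def test_zero_variance_series_flagged():
    traj = _traj_from_series(np.ones((2048, 2)))
    summ = gp.autocorrelation_summary(traj)
    assert np.all(summ.zero_variance)
    assert np.all(summ.correlation_times == 0)


def test_gpa_and_normal_subgroups_behave_alike_in_chaos():
    """In the chaotic regime, mean autocorrelations of slow and fast neurons overlap."""
    m = gp.build_network(gp.TwoPoint(p=0.5, low=1.0, high=10.0), gp.Constant(0.5),
                         300, 2.0, seed=21)
    st = SimSettings(T_transient=50.0, T_measure=250.0, store_every=5)
    traj = gp.free_run(m, st, seed=21)
    slow = np.nonzero(m.population.gamma == 1.0)[0]
    fast = np.nonzero(m.population.gamma == 10.0)[0]
    summ = gp.autocorrelation_summary(traj, {"gpa": slow, "normal": fast}, max_lag_time=20.0)
    gap = np.max(np.abs(summ.mean_autocorrelation["gpa"] - summ.mean_autocorrelation["normal"]))
    assert gap < 0.25  # small relative to the lag-0 value of 1


def test_decay_ratio_discriminates():
    t = np.arange(3000) * 0.1
    decaying = _traj_from_series(np.exp(-0.05 * t)[:, None] * np.sin(t)[:, None], dt=0.1)
    sustained = _traj_from_series(np.sin(t)[:, None], dt=0.1)
    assert _decay_ratio(decaying) < 0.1
    assert _decay_ratio(sustained) > 0.5


def test_phase_diagram_single_cell_reduces_to_order_parameter():
    st = SimSettings(T_transient=30.0, T_measure=120.0, boundary_refine=False)
    dists = lambda p: (gp.TwoPoint(p=p, low=1.0, high=10.0), gp.Constant(0.5))
    tab = gp.phase_diagram([0.5], dists, [1.2], 100, settings=st, seed=2, axis_name="p")
    assert len(tab) == 1
    row = tab.iloc[0]
    m = gp.build_network(*dists(0.5), 100, 1.2, int(row["seed"]))
    op = gp.max_power_order_parameter(m, st, seed=int(row["seed"]))
    assert row["order_parameter"] == pytest.approx(op)
    assert {"p", "g", "order_parameter", "gc_analytic", "seed", "N"} <= set(tab.columns)


def test_empirical_boundary_interpolation():
    import pandas as pd

    tab = pd.DataFrame({
        "p": [0.5] * 4, "g": [0.1, 0.2, 0.4, 0.8],
        "dynamic": [False, False, True, True], "gc_analytic": [0.3] * 4,
    })
    b = empirical_boundary(tab, axis_name="p")
    assert b["g_boundary"].iloc[0] == pytest.approx(np.sqrt(0.2 * 0.4))


def test_hash_seed_stable_and_bounded():
    assert hash_seed(1, 2, 3) == hash_seed(1, 2, 3)
    assert hash_seed(1, 2, 3) != hash_seed(1, 2, 4)
    assert 0 <= hash_seed(2**30, 5) < 2**31
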