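"""Power-spectral diagnostics and the max-power order parameter.

The transition from the quiescent to the chaotic regime is located
numerically through the population-mean power spectral density of the
activity: max_omega S̄_x(omega) is zero (up to the numerical floor) when
the network converges to the fixed point and positive when irregular
activity is sustained.

Estimation is Welch's method (Hann window, 50% overlap) on mean-removed
per-neuron series; frequencies are reported as angular frequencies to
match the theory side.  The silent/dynamic classification combines a
calibrated numerical-floor threshold with a decay-ratio guard that
rejects slowly decaying transients near the boundary (a finite-time
artifact a pure amplitude threshold cannot distinguish from sustained
activity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .distributions import ParamDistribution
from .dynamics import Trajectory, integrate, NoInput
from .network import NetworkModel, build_network, stream_rng
from .theory import critical_coupling

__all__ = [
    "SimSettings",
    "SpectrumEstimate",
    "AutocorrSummary",
    "estimate_psd",
    "free_run",
    "max_power_order_parameter",
    "calibrate_silence_threshold",
    "autocorrelation_summary",
    "phase_diagram",
    "empirical_boundary",
]


@dataclass(frozen=True)
class SimSettings:
    """Numerical settings for free-running (phase-diagram) simulations.

    The first ``T_transient`` time units are discarded before any
    statistic; ``store_every`` thins the stored samples (the PSD only
    needs the low-frequency band).  ``boundary_refine`` doubles both
    durations when an analytic g_c is available and |g-g_c|/g_c < 0.1.
    """

    dt: float = 0.02
    T_transient: float = 150.0
    T_measure: float = 300.0
    store_every: int = 5
    nperseg: int = 1024
    decay_ratio_min: float = 0.5
    boundary_refine: bool = True

    @property
    def fs(self) -> float:
        return 1.0 / (self.dt * self.store_every)


@dataclass(frozen=True)
class SpectrumEstimate:
    """Frequency grid with per-neuron and population-mean PSDs."""

    freqs: np.ndarray          # angular frequency grid (rad / time unit)
    psd_mean: np.ndarray       # population-mean PSD
    psd_per_neuron: np.ndarray | None
    settings: dict

    @property
    def max_power(self) -> float:
        return float(np.max(self.psd_mean))


@dataclass(frozen=True)
class AutocorrSummary:
    lags: np.ndarray
    mean_autocorrelation: dict
    correlation_times: np.ndarray
    zero_variance: np.ndarray


def estimate_psd(
    traj: Trajectory,
    on_phi: bool = False,
    nperseg: int = 1024,
    keep_per_neuron: bool = True,
) -> SpectrumEstimate:
    """Welch PSD per neuron (Hann, 50% overlap, mean removed) and its population mean.

    ``on_phi`` applies tanh to the series first, giving the PSD of the
    firing rates rather than of the activities.
    """
    series = np.tanh(traj.x) if on_phi else traj.x
    n = series.shape[0]
    if n < nperseg:
        raise ValueError(
            f"trajectory has {n} samples, shorter than one Welch segment ({nperseg})"
        )
    fs = 1.0 / traj.dt
    f, pxx = signal.welch(
        series, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", axis=0,
    )
    pxx = pxx.T  # N x F
    psd_mean = pxx.mean(axis=0)
    return SpectrumEstimate(
        freqs=2.0 * np.pi * f,
        psd_mean=psd_mean,
        psd_per_neuron=pxx if keep_per_neuron else None,
        settings={"nperseg": nperseg, "window": "hann", "overlap": 0.5,
                  "fs": fs, "on_phi": on_phi},
    )


def free_run(model: NetworkModel, settings: SimSettings, seed: int) -> Trajectory:
    """Free-running trajectory: x(0) i.i.d. standard normal, a(0)=0, no input.

    Returns only the post-transient window.
    """
    rng = stream_rng(seed, "init")
    x0 = rng.standard_normal(model.N)
    traj = integrate(
        model, NoInput(), x0=x0, a0=np.zeros(model.N),
        dt=settings.dt, T_total=settings.T_transient + settings.T_measure,
        store_every=settings.store_every,
    )
    return traj.window(settings.T_transient)


def max_power_order_parameter(
    model: NetworkModel, settings: SimSettings = SimSettings(), seed: int = 0
) -> float:
    """Max over omega of the population-mean activity PSD of a free run."""
    traj = free_run(model, settings, seed)
    return estimate_psd(traj, nperseg=settings.nperseg, keep_per_neuron=False).max_power


def _decay_ratio(traj: Trajectory) -> float:
    """RMS of the last tenth of the window over RMS of the first tenth.

    Near 1 for stationary (sustained) activity, << 1 for a decaying
    transient.  Zero-activity windows return 0.
    """
    n = traj.x.shape[0]
    k = max(n // 10, 1)
    first = float(np.sqrt(np.mean(traj.x[:k] ** 2)))
    last = float(np.sqrt(np.mean(traj.x[-k:] ** 2)))
    if first == 0.0:
        return 0.0
    return last / first


def calibrate_silence_threshold(
    gamma_dist: ParamDistribution,
    beta_dist: ParamDistribution,
    N: int,
    settings: SimSettings,
    seed: int,
) -> float:
    """Numerical-floor threshold from a matched uncoupled (g=0) network.

    Runs the identical pipeline on a g=0 network with the same parameter
    distributions and seed streams and returns 5x the max PSD of the final
    quarter of its measurement window — a pure numerical floor.
    """
    model = build_network(gamma_dist, beta_dist, N, 0.0, seed)
    traj = free_run(model, settings, seed)
    t_last = traj.t0 + 0.75 * (traj.times[-1] - traj.t0)
    tail = traj.window(t_last)
    nperseg = min(settings.nperseg, tail.x.shape[0])
    est = estimate_psd(tail, nperseg=nperseg, keep_per_neuron=False)
    return max(5.0 * est.max_power, 1e-250)


def autocorrelation_summary(
    traj: Trajectory,
    subgroups: dict[str, np.ndarray] | None = None,
    max_lag_time: float | None = None,
) -> AutocorrSummary:
    """Per-neuron normalized autocorrelations, subgroup means, 1/e correlation times.

    Autocorrelations use the biased (divide-by-n) estimator on mean-removed
    series, normalized to 1 at lag 0.  The correlation time is the first
    lag at which the autocorrelation falls below 1/e, in time units; a
    zero-variance series gets correlation time 0 and a flag.
    """
    x = traj.x - traj.x.mean(axis=0, keepdims=True)
    n, N = x.shape
    max_lag = n - 1 if max_lag_time is None else min(int(max_lag_time / traj.dt), n - 1)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, n=nfft, axis=0)
    ac = np.fft.irfft(np.abs(X) ** 2, n=nfft, axis=0)[: max_lag + 1] / n
    var = ac[0].copy()
    zero_var = var <= 0
    safe = np.where(zero_var, 1.0, var)
    ac_norm = ac / safe
    ac_norm[:, zero_var] = 0.0
    ac_norm[0, zero_var] = 0.0

    below = ac_norm < (1.0 / np.e)
    corr_times = np.empty(N)
    for i in range(N):
        idx = np.nonzero(below[:, i])[0]
        corr_times[i] = 0.0 if zero_var[i] else (idx[0] * traj.dt if idx.size else max_lag * traj.dt)
    corr_times[zero_var] = 0.0

    groups = {"all": np.arange(N)} if subgroups is None else subgroups
    means = {name: ac_norm[:, np.asarray(idx, dtype=int)].mean(axis=1) for name, idx in groups.items()}
    return AutocorrSummary(
        lags=traj.dt * np.arange(max_lag + 1),
        mean_autocorrelation=means,
        correlation_times=corr_times,
        zero_variance=zero_var,
    )


def phase_diagram(
    axis_values: Sequence[float],
    dists_for_axis: Callable[[float], tuple[ParamDistribution, ParamDistribution]],
    g_values: Sequence[float],
    N: int,
    settings: SimSettings = SimSettings(),
    seed: int = 0,
    axis_name: str = "axis",
) -> pd.DataFrame:
    """Order-parameter table over a (heterogeneity axis, g) grid.

    A fresh network is drawn per cell (seed recorded per row).  Each row
    carries the order parameter, the silent/dynamic classification, the
    decay ratio, and the analytic g_c for that axis value.  Failed cells
    (divergence) are recorded with NaN rather than aborting the grid.
    """
    rows = []
    for ia, av in enumerate(axis_values):
        gamma_dist, beta_dist = dists_for_axis(av)
        gc = critical_coupling(gamma_dist, beta_dist).gc
        eps = calibrate_silence_threshold(
            gamma_dist, beta_dist, N, settings, seed=hash_seed(seed, ia, 9999)
        )
        for ig, g in enumerate(g_values):
            cell_seed = hash_seed(seed, ia, ig)
            st = settings
            if settings.boundary_refine and abs(g - gc) / gc < 0.1:
                st = replace(settings, T_transient=2 * settings.T_transient,
                             T_measure=2 * settings.T_measure)
            try:
                model = build_network(gamma_dist, beta_dist, N, g, cell_seed)
                traj = free_run(model, st, cell_seed)
                op = estimate_psd(traj, nperseg=st.nperseg, keep_per_neuron=False).max_power
                ratio = _decay_ratio(traj)
                dynamic = (op > eps) and (ratio >= st.decay_ratio_min)
                rows.append({axis_name: av, "g": g, "order_parameter": op,
                             "decay_ratio": ratio, "dynamic": dynamic,
                             "gc_analytic": gc, "epsilon": eps,
                             "seed": cell_seed, "N": N, "failed": False})
            except Exception:
                rows.append({axis_name: av, "g": g, "order_parameter": np.nan,
                             "decay_ratio": np.nan, "dynamic": False,
                             "gc_analytic": gc, "epsilon": eps,
                             "seed": cell_seed, "N": N, "failed": True})
    return pd.DataFrame(rows)


def empirical_boundary(table: pd.DataFrame, axis_name: str = "axis") -> pd.DataFrame:
    """Silent-to-dynamic boundary per axis value.

    For each axis value, the boundary is the geometric mean of the last
    silent and first dynamic g (NaN if the column never/always switches:
    the grid did not bracket the transition).
    """
    out = []
    for av, sub in table.groupby(axis_name, sort=True):
        sub = sub.sort_values("g")
        dyn = sub["dynamic"].to_numpy()
        gs = sub["g"].to_numpy()
        if dyn.all() or not dyn.any():
            g_emp = np.nan
        else:
            first_dyn = int(np.argmax(dyn))
            if first_dyn == 0:
                g_emp = np.nan
            else:
                g_emp = float(np.sqrt(gs[first_dyn - 1] * gs[first_dyn]))
        out.append({axis_name: av, "g_boundary": g_emp,
                    "gc_analytic": float(sub["gc_analytic"].iloc[0])})
    return pd.DataFrame(out)


def hash_seed(*parts: int) -> int:
    """Deterministic seed from integer parts, kept below 2**31."""
    ss = np.random.SeedSequence(list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2**31))
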