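"""Reservoir-computing memory capacity of a noise-driven network.

The network is driven by one shared scalar Gaussian white-noise signal
u(t) (per-step increments N(0, sigma_in² dt), Euler-Maruyama) fanned out
through fixed random input weights.  Readout samples are taken on a
coarser grid (default every 0.2 time units); the input value attached to
a sample is the accumulated white-noise input over the preceding sample
interval, so targets live at the same resolution as the delays — a
single integrator-step increment is not linearly recoverable from a
state that integrates it, the block increment is.  For each delay k a
linear readout is fitted from the state x(t) to the delayed input
u(t - k) by ridge-regularized least squares on a chronological training
segment, and scored as the squared Pearson correlation on the held-out
segment — the standard linear memory function.  Total capacity is the
sum over delays; in the edge-of-chaos picture it peaks just below the
critical coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ParamDistribution
from .dynamics import SharedWhiteNoise, integrate
from .network import NetworkModel, build_network, stream_rng
from .spectra import hash_seed
from .theory import critical_coupling

__all__ = [
    "MemoryCapacityResult",
    "linear_memory_scores",
    "run_memory_capacity",
    "capacity_curve",
]


@dataclass(frozen=True)
class MemoryCapacityResult:
    delays: np.ndarray          # delay lags in time units
    mc_per_delay: np.ndarray    # squared test correlation per delay, in [0, 1]
    settings: dict
    flags: dict

    @property
    def mc_total(self) -> float:
        return float(np.sum(self.mc_per_delay))


def linear_memory_scores(
    states: np.ndarray,
    inputs: np.ndarray,
    delay_steps: np.ndarray,
    ridge: float = 1e-6,
    split: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Ridge-readout memory scores for arbitrary state/input series.

    ``states`` is (T, N), ``inputs`` is (T,), aligned samples.  For each
    delay d (in samples) a readout w solves
    (X'X + ridge * tr(X'X)/N * I) w = X'y with y_t = inputs[t - d], fitted
    on the first ``split`` fraction of usable rows and scored as the
    squared Pearson correlation on the rest.  Zero-variance state or
    target segments score 0 and are flagged.
    """
    states = np.asarray(states, dtype=float)
    inputs = np.asarray(inputs, dtype=float).ravel()
    T, N = states.shape
    dmax = int(np.max(delay_steps))
    rows = np.arange(dmax, T)
    n_train = int(len(rows) * split)
    if n_train < N + 1 or len(rows) - n_train < 2:
        raise ValueError("not enough samples for the requested delays and split")
    tr, te = rows[:n_train], rows[n_train:]
    Xtr, Xte = states[tr], states[te]
    G = Xtr.T @ Xtr
    lam = ridge * np.trace(G) / N
    G_reg = G + lam * np.eye(N)

    scores = np.empty(len(delay_steps))
    flagged = []
    for j, d in enumerate(delay_steps):
        ytr = inputs[tr - d]
        yte = inputs[te - d]
        if np.std(ytr) == 0 or np.std(yte) == 0 or np.all(Xtr.std(axis=0) == 0):
            scores[j] = 0.0
            flagged.append(int(d))
            continue
        w = np.linalg.solve(G_reg, Xtr.T @ ytr)
        pred = Xte @ w
        if np.std(pred) == 0:
            scores[j] = 0.0
            flagged.append(int(d))
            continue
        r = np.corrcoef(pred, yte)[0, 1]
        scores[j] = r * r
    return scores, {"zero_variance_delays": flagged, "n_train": n_train, "n_test": len(te)}


def run_memory_capacity(
    model: NetworkModel,
    sigma_in: float = 0.1,
    input_weights_seed: int = 0,
    dt: float = 0.02,
    T: float = 500.0,
    T_transient: float = 50.0,
    delays: np.ndarray | None = None,
    ridge: float = 1e-6,
    split: float = 0.5,
    seed: int = 0,
    sample_every: int = 10,
) -> MemoryCapacityResult:
    """Drive the network with shared white noise and measure its memory function.

    Input weights are i.i.d. standard normal (from ``input_weights_seed``).
    Readout samples are taken every ``sample_every`` integrator steps;
    delays default to multiples of ``sample_every * dt`` (0.2 time units at
    the defaults) up to 20 time units.  The input value attached to a
    sample is the accumulated white-noise input over the preceding sample
    interval.
    """
    N = model.N
    wrng = np.random.default_rng(input_weights_seed)
    weights = wrng.standard_normal(N)
    protocol = SharedWhiteNoise(sigma_in=sigma_in, weights=weights)
    init = stream_rng(seed, "init")
    traj = integrate(
        model, protocol,
        x0=init.standard_normal(N) * 0.1, a0=np.zeros(N),
        dt=dt, T_total=T_transient + T, seed=hash_seed(seed, 7),
        store_every=1,
    )
    post = traj.window(T_transient)
    # sample the state every sample_every steps; pair each sample with the
    # summed noise increments of the block that led into it
    n_blocks = (post.x.shape[0] - 1) // sample_every
    states = post.x[sample_every * np.arange(1, n_blocks + 1)]
    inputs = post.u[1 : n_blocks * sample_every + 1].reshape(n_blocks, sample_every).sum(axis=1)

    step_time = dt * sample_every
    if delays is None:
        delays = np.arange(1, int(round(20.0 / step_time)) + 1) * step_time
    delays = np.asarray(delays, dtype=float)
    delay_steps = np.rint(delays / step_time).astype(int)
    if np.any(np.abs(delay_steps * step_time - delays) > 1e-9):
        raise ValueError(f"delays must be multiples of the sample interval {step_time}")

    scores, flags = linear_memory_scores(states, inputs, delay_steps, ridge=ridge, split=split)
    return MemoryCapacityResult(
        delays=delays,
        mc_per_delay=scores,
        settings={
            "sigma_in": sigma_in, "input_weights_seed": input_weights_seed,
            "dt": dt, "T": T, "T_transient": T_transient, "ridge": ridge,
            "split": split, "seed": seed, "sample_every": sample_every,
        },
        flags=flags,
    )


def capacity_curve(
    gamma_dist: ParamDistribution,
    beta_dist: ParamDistribution,
    N: int,
    g_values: np.ndarray,
    seed: int = 0,
    **mc_kwargs,
) -> pd.DataFrame:
    """Total memory capacity over a grid of coupling strengths.

    One network and one capacity measurement per g, with matched seeds
    across the grid; the analytic g_c for the parameter distributions is
    attached to every row.  Failed cells are recorded with NaN.
    """
    gc = critical_coupling(gamma_dist, beta_dist).gc
    rows = []
    for g in np.asarray(g_values, dtype=float):
        try:
            model = build_network(gamma_dist, beta_dist, N, g, seed)
            res = run_memory_capacity(model, seed=seed, **mc_kwargs)
            rows.append({"g": g, "mc_total": res.mc_total, "gc_analytic": gc,
                         "N": N, "seed": seed, "failed": False})
        except Exception:
            rows.append({"g": g, "mc_total": np.nan, "gc_analytic": gc,
                         "N": N, "seed": seed, "failed": True})
    return pd.DataFrame(rows)
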