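"""Integration of the network equations and pulse-response experiments.

Fixed-step explicit Euler (Euler-Maruyama when a shared white-noise input
is present), default dt = 0.02.  The integrator is deliberately simple:
an adaptive stepper would break the white-noise path construction, and
first-order accuracy is verified in the tests by dt-halving against the
closed-form solution of the uncoupled linear neuron.

Input protocols
---------------
* :class:`NoInput` — free-running dynamics.
* :class:`PulseTrain` — piecewise-constant pulses (t_start, t_end,
  amplitude) applied to all neurons or a target subset; used for the
  graded-persistent-activity demonstrations and the shared-impulse
  experiment.
* :class:`SharedWhiteNoise` — one scalar Gaussian white-noise path u(t)
  with per-step increments N(0, sigma_in² dt), fanned out through fixed
  per-neuron weights; used to drive reservoirs for memory-capacity
  measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import NetworkModel, NeuronPopulation, CouplingMatrix

__all__ = [
    "NoInput",
    "PulseTrain",
    "SharedWhiteNoise",
    "Trajectory",
    "ImpulseResponseProfile",
    "DivergenceError",
    "integrate",
    "single_neuron_pulse_response",
    "impulse_response_experiment",
]

DIVERGENCE_LIMIT = 1e6


class DivergenceError(RuntimeError):
    """State left the trusted range; carries the first offending step index."""

    def __init__(self, step: int, t: float):
        self.step = step
        self.t = t
        super().__init__(
            f"trajectory diverged (|state| > {DIVERGENCE_LIMIT:g}) at step {step}, t={t:g}"
        )


@dataclass(frozen=True)
class NoInput:
    kind = "none"


@dataclass(frozen=True)
class PulseTrain:
    """Piecewise-constant pulses; ``targets=None`` applies them to every neuron.

    Events are (t_start, t_end, amplitude) with amplitude added to dx/dt
    while t_start <= t < t_end.  Intervals must not overlap.
    """

    events: Sequence[tuple[float, float, float]]
    targets: Sequence[int] | None = None
    kind = "pulse_train"

    def __post_init__(self):
        ev = sorted((float(a), float(b), float(c)) for a, b, c in self.events)
        for (s0, e0, _), (s1, _, _) in zip(ev, ev[1:]):
            if s1 < e0:
                raise ValueError("pulse intervals must not overlap")
        for s, e, _ in ev:
            if e <= s:
                raise ValueError(f"pulse must have t_end > t_start, got ({s}, {e})")
        object.__setattr__(self, "events", tuple(ev))

    def amplitude_at(self, t: float) -> float:
        for s, e, amp in self.events:
            if s <= t < e:
                return amp
        return 0.0


@dataclass(frozen=True)
class SharedWhiteNoise:
    """Shared scalar white noise u(t) ~ N(0, sigma_in² dt) per step, times weights."""

    sigma_in: float
    weights: np.ndarray
    kind = "shared_white_noise"

    def __post_init__(self):
        if self.sigma_in < 0:
            raise ValueError("sigma_in must be >= 0")
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


@dataclass
class Trajectory:
    """Uniformly sampled time courses of x and a for all neurons.

    ``dt`` is the *sampling* interval of the stored rows (integration
    stride times the integrator step when ``store_every > 1``).  ``u``
    holds the shared noise path (per stored sample) when one was used.
    """

    t0: float
    dt: float
    x: np.ndarray
    a: np.ndarray
    model_ref: dict = field(default_factory=dict)
    u: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.x.shape[0])

    @property
    def N(self) -> int:
        return self.x.shape[1]

    def window(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        """Sub-trajectory on [t_from, t_to] (by sample times, inclusive)."""
        t = self.times
        sel = t >= t_from - 1e-12
        if t_to is not None:
            sel &= t <= t_to + 1e-12
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            raise ValueError("requested window contains no samples")
        return Trajectory(
            t0=float(t[idx[0]]),
            dt=self.dt,
            x=self.x[idx],
            a=self.a[idx],
            model_ref=self.model_ref,
            u=None if self.u is None else self.u[idx],
        )


@dataclass(frozen=True)
class ImpulseResponseProfile:
    """Per-neuron peak |x| after a shared pulse, sortable by an intrinsic parameter."""

    amplitudes: np.ndarray
    sort_key: np.ndarray
    sort_key_name: str = "beta"


def integrate(
    model: NetworkModel,
    input_protocol=NoInput(),
    x0: np.ndarray | None = None,
    a0: np.ndarray | None = None,
    dt: float = 0.02,
    T_total: float = 100.0,
    seed: int = 0,
    store_every: int = 1,
) -> Trajectory:
    """Integrate the network with fixed-step Euler (Euler-Maruyama under noise).

    Rows of the returned trajectory are stored every ``store_every`` steps
    (row 0 is the initial condition).  Any |x| or |a| exceeding 1e6 aborts
    with :class:`DivergenceError` carrying the first bad step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if store_every < 1:
        raise ValueError("store_every must be >= 1")
    N = model.N
    pop = model.population
    J = model.coupling.J
    gamma, beta = pop.gamma, pop.beta

    x = np.zeros(N) if x0 is None else np.array(x0, dtype=float).reshape(N)
    a = np.zeros(N) if a0 is None else np.array(a0, dtype=float).reshape(N)

    n_steps = int(round(T_total / dt))
    n_store = n_steps // store_every + 1
    xs = np.empty((n_store, N))
    as_ = np.empty((n_store, N))
    xs[0], as_[0] = x, a

    noise = isinstance(input_protocol, SharedWhiteNoise)
    pulses = isinstance(input_protocol, PulseTrain)
    us = None
    if noise:
        rng = np.random.default_rng(seed)
        w = input_protocol.weights
        if w.shape != (N,):
            raise ValueError(f"input weights must have shape ({N},)")
        u_path = rng.normal(0.0, input_protocol.sigma_in * np.sqrt(dt), size=n_steps)
        us = np.zeros(n_store)
    if pulses:
        tgt = input_protocol.targets
        mask = np.ones(N) if tgt is None else np.zeros(N)
        if tgt is not None:
            mask[np.asarray(tgt, dtype=int)] = 1.0

    row = 1
    for k in range(n_steps):
        t = k * dt
        drive = J @ pop.phi(x)
        dx = -x + a + drive
        if pulses:
            amp = input_protocol.amplitude_at(t)
            if amp != 0.0:
                dx = dx + amp * mask
        da = -gamma * a + beta * x
        x = x + dt * dx
        a = a + dt * da
        if noise:
            x = x + w * u_path[k]
        if (k + 1) % store_every == 0:
            m = np.max(np.abs(x))
            if not np.isfinite(m) or m > DIVERGENCE_LIMIT or np.max(np.abs(a)) > DIVERGENCE_LIMIT:
                raise DivergenceError(step=k + 1, t=(k + 1) * dt)
            xs[row], as_[row] = x, a
            if noise:
                us[row] = u_path[k]
            row += 1

    return Trajectory(
        t0=0.0,
        dt=dt * store_every,
        x=xs[:row],
        a=as_[:row],
        model_ref=dict(model.metadata),
        u=us[:row] if noise else None,
    )


def _single_neuron_model(gamma: float, beta: float) -> NetworkModel:
    pop = NeuronPopulation(gamma=np.array([gamma]), beta=np.array([beta]))
    coup = CouplingMatrix(J=np.zeros((1, 1)), g=0.0)
    return NetworkModel(population=pop, coupling=coup, metadata={"single_neuron": True})


def single_neuron_pulse_response(
    gamma: float,
    beta: float,
    pulses: Sequence[tuple[float, float, float]],
    dt: float = 0.02,
    T_total: float | None = None,
) -> Trajectory:
    """Convenience wrapper: one isolated neuron (J = 0) driven by a pulse train.

    With a small decay rate gamma (slightly above beta) the neuron shows
    graded persistent activity: its plateau level steps up after each
    depolarizing pulse and down after hyperpolarizing ones.  With large
    gamma the activity decays promptly at pulse offset.
    """
    import warnings

    if gamma <= beta:
        warnings.warn(
            f"gamma={gamma} <= beta={beta}: the isolated neuron diverges", stacklevel=2
        )
    if T_total is None:
        T_total = max(e for _, e, _ in pulses) + 20.0
    model = _single_neuron_model(gamma, beta)
    return integrate(model, PulseTrain(events=pulses), dt=dt, T_total=T_total)


def impulse_response_experiment(
    model: NetworkModel,
    pulse: tuple[float, float, float] = (1.0, 1.5, 1.0),
    dt: float = 0.02,
    T_total: float = 60.0,
    sort_key: str = "beta",
) -> ImpulseResponseProfile:
    """Peak |x_i| of every neuron after a shared transient pulse.

    The same pulse is applied to all neurons of a (recommended subcritical)
    network; the profile records each neuron's maximum absolute response
    after pulse onset together with the chosen intrinsic parameter as the
    sort key, so responses can be ordered by, e.g., feedback strength.
    """
    t_on = pulse[0]
    traj = integrate(model, PulseTrain(events=[pulse]), dt=dt, T_total=T_total)
    after = traj.window(t_on)
    amps = np.max(np.abs(after.x), axis=0)
    key = getattr(model.population, sort_key)
    return ImpulseResponseProfile(amplitudes=amps, sort_key=key, sort_key_name=sort_key)
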