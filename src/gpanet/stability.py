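"""Linear stability of the quiescent state and the Benettin Lyapunov exponent.

Two diagnostics of the same bifurcation:

* the eigenspectrum of the 2N x 2N Jacobian at the trivial fixed point —
  its spectral abscissa (max real part) changes sign when the quiescent
  state loses linear stability;
* the maximum Lyapunov exponent along free-running trajectories,
  estimated with the Benettin tangent-vector method — it changes sign
  when the sustained dynamics become chaotic.

For these networks the two boundaries coincide in the large-N limit, at
the coupling strength predicted by the averaged-gain condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkModel, stream_rng
from .dynamics import DivergenceError, DIVERGENCE_LIMIT

__all__ = [
    "EigenSpectrum",
    "LyapunovEstimate",
    "jacobian_origin",
    "eigenspectrum",
    "max_lyapunov_benettin",
]

_DENSE_EIG_GUARD = 5000


@dataclass(frozen=True)
class EigenSpectrum:
    """Full complex spectrum of the origin Jacobian (2N eigenvalues)."""

    eigenvalues: np.ndarray
    model_ref: dict

    @property
    def spectral_abscissa(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass(frozen=True)
class LyapunovEstimate:
    """Benettin maximum-Lyapunov estimates over random initial conditions."""

    lambdas: np.ndarray
    settings: dict

    @property
    def lambda_max(self) -> float:
        return float(np.mean(self.lambdas))

    @property
    def std(self) -> float:
        return float(np.std(self.lambdas))


def jacobian_origin(model: NetworkModel) -> np.ndarray:
    """Jacobian of the (x, a) vector field at the trivial fixed point.

    Block structure [[phi'(0) J - I, I], [diag(beta), -diag(gamma)]];
    phi'(0) = 1 for both tanh and linear activations.
    """
    N = model.N
    pop = model.population
    slope = float(pop.phi_prime(np.zeros(1))[0])
    top = np.hstack([slope * model.coupling.J - np.eye(N), np.eye(N)])
    bot = np.hstack([np.diag(pop.beta), -np.diag(pop.gamma)])
    return np.vstack([top, bot])


def eigenspectrum(model: NetworkModel) -> EigenSpectrum:
    """Dense eigendecomposition of the origin Jacobian (guarded at N <= 5000)."""
    if model.N > _DENSE_EIG_GUARD:
        raise ValueError(
            f"N={model.N} exceeds the dense-eigendecomposition guard "
            f"({_DENSE_EIG_GUARD}); reduce N"
        )
    vals = np.linalg.eigvals(jacobian_origin(model))
    return EigenSpectrum(eigenvalues=vals, model_ref=dict(model.metadata))


def max_lyapunov_benettin(
    model: NetworkModel,
    dt: float = 0.02,
    T_transient: float = 50.0,
    T_measure: float = 200.0,
    renorm_interval: float = 1.0,
    n_init: int = 10,
    seed: int = 0,
    T_warmup: float = 20.0,
) -> LyapunovEstimate:
    """Maximum Lyapunov exponent by tangent-vector renormalization.

    The full nonlinear system and its exact tangent dynamics (Jacobian
    evaluated along the trajectory applied to a tangent vector) are
    co-integrated with the same Euler step.  The tangent vector starts
    uniformly on the unit sphere and is renormalized every
    ``renorm_interval`` time units; log norms accumulated after a tangent
    warm-up of ``T_warmup`` time units (which lets the vector align with
    the leading direction, removing the initial-misalignment bias),
    divided by the remaining measurement time, give one exponent per
    initial condition.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if renorm_interval <= 0 or T_measure < renorm_interval:
        raise ValueError("require 0 < renorm_interval <= T_measure")
    N = model.N
    pop = model.population
    J = model.coupling.J
    gamma, beta = pop.gamma, pop.beta
    n_trans = int(round(T_transient / dt))
    renorm_steps = max(int(round(renorm_interval / dt)), 1)
    n_renorms = int(round(T_measure / dt)) // renorm_steps
    n_warm = min(int(round(T_warmup / dt)) // renorm_steps, max(n_renorms - 1, 0))
    T_eff = (n_renorms - n_warm) * renorm_steps * dt

    rng = stream_rng(seed, "init")
    lambdas = np.empty(n_init)
    for r in range(n_init):
        x = rng.standard_normal(N)
        a = np.zeros(N)
        for k in range(n_trans):
            dx = -x + a + J @ pop.phi(x)
            da = -gamma * a + beta * x
            x = x + dt * dx
            a = a + dt * da
        if not np.isfinite(x).all() or np.max(np.abs(x)) > DIVERGENCE_LIMIT:
            raise DivergenceError(step=n_trans, t=T_transient)
        v = rng.standard_normal(2 * N)
        v /= np.linalg.norm(v)
        vx, va = v[:N].copy(), v[N:].copy()
        log_sum = 0.0
        for block in range(n_renorms):
            for k in range(renorm_steps):
                phip = pop.phi_prime(x)
                dvx = -vx + va + J @ (phip * vx)
                dva = -gamma * va + beta * vx
                dx = -x + a + J @ pop.phi(x)
                da = -gamma * a + beta * x
                vx = vx + dt * dvx
                va = va + dt * dva
                x = x + dt * dx
                a = a + dt * da
            norm = float(np.sqrt(vx @ vx + va @ va))
            if norm == 0.0 or not np.isfinite(norm):
                raise FloatingPointError("tangent vector norm degenerate during renormalization")
            if block >= n_warm:
                log_sum += np.log(norm)
            vx /= norm
            va /= norm
        lambdas[r] = log_sum / T_eff
    return LyapunovEstimate(
        lambdas=lambdas,
        settings={
            "dt": dt, "T_transient": T_transient, "T_measure": T_eff,
            "renorm_interval": renorm_steps * dt, "n_init": n_init, "seed": seed,
        },
    )
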