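"""Heterogeneous network construction: neuron populations and random coupling.

The network is a random recurrent rate model.  Each neuron carries two
variables, an activity ``x`` and a slow auxiliary variable ``a``:

    dx_i/dt = -x_i + a_i + sum_j J_ij phi(x_j) + I_i(t)
    da_i/dt = -gamma_i a_i + beta_i x_i

Per-neuron decay rates ``gamma_i`` and feedback strengths ``beta_i`` are
drawn from configurable distributions; the coupling matrix ``J`` has zero
diagonal and i.i.d. Gaussian off-diagonal entries with variance ``g^2/N``.

Seeding uses named sub-streams derived from one master seed so that, e.g.,
changing the coupling seed stream leaves the sampled gamma values intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .distributions import ParamDistribution

__all__ = [
    "NeuronPopulation",
    "CouplingMatrix",
    "NetworkModel",
    "sample_params",
    "sample_coupling",
    "build_network",
    "stream_rng",
]

# Fixed registry of named seed streams: the spawn key of each stream is its
# position here, so adding streams at the end never perturbs existing ones.
_STREAMS = ("gamma", "beta", "coupling", "init", "input")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the generator for a named sub-stream of ``seed``."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown seed stream {stream!r}; expected one of {_STREAMS}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stream),))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class NeuronPopulation:
    """Intrinsic parameters of N two-variable neurons.

    ``stable_intrinsic`` is True iff every neuron satisfies gamma_i > beta_i,
    the condition for the isolated neuron not to diverge.
    """

    gamma: np.ndarray
    beta: np.ndarray
    activation: Literal["tanh", "linear"] = "tanh"

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if g.shape != b.shape or g.ndim != 1:
            raise ValueError("gamma and beta must be 1-d sequences of equal length")
        if g.size < 1:
            raise ValueError("population must contain at least one neuron")
        if np.any(g <= 0):
            raise ValueError("all decay rates gamma_i must be > 0")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "beta", b)

    @property
    def N(self) -> int:
        return self.gamma.size

    @property
    def stable_intrinsic(self) -> bool:
        return bool(np.all(self.gamma > self.beta))

    def phi(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x) if self.activation == "tanh" else x

    def phi_prime(self, x: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            return 1.0 / np.cosh(x) ** 2
        return np.ones_like(x)


@dataclass(frozen=True)
class CouplingMatrix:
    """Random Gaussian coupling with zero diagonal, entries ~ N(0, g²/N)."""

    J: np.ndarray
    g: float
    seed: int | None = None

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square matrix")
        if np.any(np.diag(J) != 0):
            raise ValueError("coupling matrix must have zero diagonal")
        if self.g < 0:
            raise ValueError("coupling strength g must be >= 0")
        object.__setattr__(self, "J", J)

    @property
    def N(self) -> int:
        return self.J.shape[0]


@dataclass(frozen=True)
class NetworkModel:
    """Population plus coupling, with provenance metadata."""

    population: NeuronPopulation
    coupling: CouplingMatrix
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.population.N != self.coupling.N:
            raise ValueError(
                f"population size {self.population.N} != coupling size {self.coupling.N}"
            )

    @property
    def N(self) -> int:
        return self.population.N


def sample_params(dist: ParamDistribution, N: int, seed: int) -> np.ndarray:
    """Draw N i.i.d. parameter values; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    return dist.sample(N, rng)


def sample_coupling(N: int, g: float, seed: int) -> CouplingMatrix:
    """Draw an N×N coupling matrix with J_ii = 0 and J_ij ~ N(0, g²/N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if g < 0:
        raise ValueError("coupling strength g must be >= 0")
    rng = np.random.default_rng(seed)
    J = rng.normal(0.0, g / np.sqrt(N), size=(N, N))
    np.fill_diagonal(J, 0.0)
    return CouplingMatrix(J=J, g=float(g), seed=seed)


def build_network(
    gamma_dist: ParamDistribution,
    beta_dist: ParamDistribution,
    N: int,
    g: float,
    seed: int,
    activation: Literal["tanh", "linear"] = "tanh",
    allow_unstable: bool = False,
) -> NetworkModel:
    """Assemble a network from distribution specs, deterministically.

    The master seed is hash-split into named streams (gamma, beta,
    coupling, ...), so the same seed always yields the same model and
    individual streams can be varied independently.

    By default a sampled neuron violating gamma_i > beta_i raises, because
    the isolated neuron diverges in that case; pass ``allow_unstable=True``
    to experiment anyway.
    """
    gamma = gamma_dist.sample(N, stream_rng(seed, "gamma"))
    beta = beta_dist.sample(N, stream_rng(seed, "beta"))
    pop = NeuronPopulation(gamma=gamma, beta=beta, activation=activation)
    if not pop.stable_intrinsic and not allow_unstable:
        bad = int(np.sum(gamma <= beta))
        raise ValueError(
            f"{bad} sampled neurons violate gamma_i > beta_i (intrinsic divergence); "
            "pass allow_unstable=True to override"
        )
    coup = sample_coupling(N, g, stream_rng(seed, "coupling").integers(2**31))
    meta = {
        "seed": int(seed),
        "N": int(N),
        "g": float(g),
        "gamma_dist": gamma_dist.to_dict(),
        "beta_dist": beta_dist.to_dict(),
        "activation": activation,
    }
    return NetworkModel(population=pop, coupling=coup, metadata=meta)
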