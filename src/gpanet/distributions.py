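"""Parameter distributions for heterogeneous neuron populations.

Per-neuron intrinsic parameters (the auxiliary-variable decay rate ``gamma``
and the feedback strength ``beta``) are drawn independently from one of four
distribution families: a degenerate constant, a two-point mixture, a uniform
distribution, or a normal distribution truncated to a finite interval.

Every distribution exposes three things the rest of the package relies on:

* seeded i.i.d. sampling (``sample``),
* exact or quadrature expectations of arbitrary functions (``expect`` /
  ``nodes_weights``), used by the mean-field theory to average the transfer
  gain over the population, and
* the support interval (``support``), used to verify non-divergence
  conditions such as ``gamma > beta`` before any expensive computation.

Truncated-normal sampling goes through the inverse CDF on the truncated
range, so it is exact and rejection-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "ParamDistribution",
    "Constant",
    "TwoPoint",
    "Uniform",
    "TruncatedNormal",
    "distribution_from_dict",
]


class ParamDistribution:
    """Base class for scalar parameter distributions.

    Subclasses implement :meth:`sample`, :meth:`nodes_weights`,
    :meth:`support` and :meth:`to_dict`; :meth:`expect` and :meth:`mean`
    are derived from the nodes/weights representation.
    """

    kind: str = "abstract"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def nodes_weights(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Return nodes and weights such that sum(w_k f(x_k)) approximates
        (or, for discrete families, equals) E[f(X)].

        ``n_nodes`` controls the quadrature order for continuous families
        and is ignored for discrete ones.
        """
        raise NotImplementedError

    def support(self) -> tuple[float, float]:
        """Smallest closed interval containing all probability mass."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    def expect(self, fn: Callable[[np.ndarray], np.ndarray], n_nodes: int = 64) -> float:
        """Expectation of ``fn`` under the distribution.

        Exact for discrete families; fixed-order Gauss-Legendre quadrature
        (against the density) for continuous ones.
        """
        x, w = self.nodes_weights(n_nodes)
        return float(np.sum(w * np.asarray(fn(x), dtype=float)))

    def mean(self) -> float:
        return self.expect(lambda x: x)

    def _check_n(self, n: int) -> None:
        if not (isinstance(n, (int, np.integer)) and n >= 1):
            raise ValueError(f"sample size must be a positive integer, got {n!r}")


@dataclass(frozen=True)
class Constant(ParamDistribution):
    """Degenerate distribution placing all mass at ``value``."""

    value: float
    kind = "constant"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._check_n(n)
        return np.full(n, float(self.value))

    def nodes_weights(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        return np.array([float(self.value)]), np.array([1.0])

    def support(self) -> tuple[float, float]:
        return float(self.value), float(self.value)

    def to_dict(self) -> dict:
        return {"kind": "constant", "value": float(self.value)}


@dataclass(frozen=True)
class TwoPoint(ParamDistribution):
    """Two-point mixture: ``low`` with probability ``p``, else ``high``.

    This is the family used to mix graded-persistent-activity neurons
    (low decay rate of the auxiliary variable) into a population of
    normal neurons (high decay rate): ``p`` is the GPA fraction.
    """

    p: float
    low: float
    high: float
    kind = "two_point"

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"two_point: p must lie in [0, 1], got {self.p}")
        if not self.low < self.high:
            raise ValueError(
                f"two_point: low must be < high, got low={self.low}, high={self.high}"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._check_n(n)
        lows = rng.random(n) < self.p
        return np.where(lows, float(self.low), float(self.high))

    def nodes_weights(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([float(self.low), float(self.high)]),
            np.array([self.p, 1.0 - self.p]),
        )

    def support(self) -> tuple[float, float]:
        if self.p == 0.0:
            return float(self.high), float(self.high)
        if self.p == 1.0:
            return float(self.low), float(self.low)
        return float(self.low), float(self.high)

    def to_dict(self) -> dict:
        return {
            "kind": "two_point",
            "p": float(self.p),
            "low": float(self.low),
            "high": float(self.high),
        }


@dataclass(frozen=True)
class Uniform(ParamDistribution):
    """Uniform distribution on ``[lo, hi]``."""

    lo: float
    hi: float
    kind = "uniform"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"uniform: lo must be < hi, got lo={self.lo}, hi={self.hi}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._check_n(n)
        return rng.uniform(self.lo, self.hi, size=n)

    def nodes_weights(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        # Gauss-Legendre on [lo, hi]; density 1/(hi-lo) folds into the weights.
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        half = 0.5 * (self.hi - self.lo)
        mid = 0.5 * (self.hi + self.lo)
        return mid + half * x, 0.5 * w

    def support(self) -> tuple[float, float]:
        return float(self.lo), float(self.hi)

    def to_dict(self) -> dict:
        return {"kind": "uniform", "lo": float(self.lo), "hi": float(self.hi)}


@dataclass(frozen=True)
class TruncatedNormal(ParamDistribution):
    """Normal(mu, sigma²) truncated to ``[lo, hi]``.

    ``sigma = 0`` degenerates to a constant at ``mu`` (which must then lie
    inside the truncation interval).
    """

    mu: float
    sigma: float
    lo: float
    hi: float
    kind = "truncated_normal"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"truncated_normal: sigma must be >= 0, got {self.sigma}")
        if not self.lo < self.hi:
            raise ValueError(
                f"truncated_normal: lo must be < hi, got lo={self.lo}, hi={self.hi}"
            )
        if self.sigma == 0 and not (self.lo <= self.mu <= self.hi):
            raise ValueError("truncated_normal: sigma=0 requires lo <= mu <= hi")

    def _frozen(self):
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._check_n(n)
        if self.sigma == 0:
            return np.full(n, float(self.mu))
        # Inverse-CDF on the truncated range: exact, no rejection loop.
        u = rng.random(n)
        return self._frozen().ppf(u)

    def nodes_weights(self, n_nodes: int = 64) -> tuple[np.ndarray, np.ndarray]:
        if self.sigma == 0:
            return np.array([float(self.mu)]), np.array([1.0])
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        half = 0.5 * (self.hi - self.lo)
        mid = 0.5 * (self.hi + self.lo)
        xs = mid + half * x
        dens = self._frozen().pdf(xs)
        ws = w * half * dens
        # Quadrature of the truncated density integrates to 1 only in the
        # limit; renormalize so expectations of constants are exact.
        return xs, ws / np.sum(ws)

    def support(self) -> tuple[float, float]:
        if self.sigma == 0:
            return float(self.mu), float(self.mu)
        return float(self.lo), float(self.hi)

    def to_dict(self) -> dict:
        return {
            "kind": "truncated_normal",
            "mu": float(self.mu),
            "sigma": float(self.sigma),
            "lo": float(self.lo),
            "hi": float(self.hi),
        }


_KINDS = {
    "constant": Constant,
    "two_point": TwoPoint,
    "uniform": Uniform,
    "truncated_normal": TruncatedNormal,
}


def distribution_from_dict(d: dict) -> ParamDistribution:
    """Rebuild a distribution from its ``to_dict`` serialization."""
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in _KINDS:
        raise ValueError(f"unknown distribution kind {kind!r}; expected one of {sorted(_KINDS)}")
    return _KINDS[kind](**d)
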