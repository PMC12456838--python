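"""Mean-field transition theory for heterogeneous random rate networks.

In the large-N limit the recurrent input to each neuron becomes a
self-consistent Gaussian mean field.  Because the intrinsic parameters
(gamma_i, beta_i) differ across neurons, the effective description is a
*set* of driven linear filters rather than a single equation; averaging
in Fourier space nevertheless yields one scalar condition for the loss of
stability of the quiescent state.  Each neuron filters the mean field
with the squared-magnitude transfer gain

    G(omega; gamma, beta) = (omega² + gamma²)
        / (omega⁴ + (gamma² + 2 beta + 1) omega² + (gamma - beta)²),

and the critical coupling strength solves

    max_omega  Gbar(omega) * g_c² = 1,      Gbar = E_{gamma,beta}[G],

so that g_c = 1 / sqrt(max_omega Gbar(omega)).  For gamma > beta >= 0
on the whole support the maximum sits at omega = 0 and, for a two-point
mixture of decay rates, g_c has a closed form.  For adaptation
(beta < 0) the gain can peak at a nonzero frequency and the maximum is
located numerically.

The module also implements the earlier "naive" treatment of Gaussian
heterogeneity in beta, which folds the parameter spread into an extra
Gaussian mean field; it predicts a transition point ghat_c that can move
in the *opposite* direction from the correct population average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .distributions import ParamDistribution

__all__ = [
    "transfer_gain",
    "averaged_gain",
    "critical_coupling",
    "critical_coupling_two_point",
    "naive_critical_coupling",
    "CriticalCoupling",
    "SingularGainError",
    "NaiveTheoryBreakdownError",
]


class SingularGainError(ValueError):
    """The transfer gain (or its expectation) diverges: support touches gamma = beta at omega = 0."""


class NaiveTheoryBreakdownError(ValueError):
    """The naive Gaussian-heterogeneity gain has a non-positive denominator on the frequency scan."""


@dataclass(frozen=True)
class CriticalCoupling:
    """Predicted transition point.

    Attributes
    ----------
    gc : critical coupling strength (quiescent state loses stability above it).
    omega_star : angular frequency at which the averaged gain peaks.
    method : which computational path produced the prediction.
    spec : parameter distributions / values the prediction refers to.
    """

    gc: float
    omega_star: float
    method: Literal["closed_form_two_point", "quadrature_general", "naive_gaussian"]
    spec: dict

    def __post_init__(self):
        if not self.gc > 0:
            raise ValueError("critical coupling must be positive")


def transfer_gain(omega, gamma, beta):
    """Squared-magnitude frequency response of the two-variable neuron.

    Relates the activity power spectral density to the mean-field PSD:
    S_x(omega) = g² G(omega; gamma, beta) S_phi_bar(omega).  Even in
    omega and non-negative; diverges at omega = 0 when gamma = beta.
    Broadcasts over array arguments.
    """
    omega = np.asarray(omega, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any((gamma == beta) & (omega == 0.0)):
        raise SingularGainError("transfer gain is singular at omega=0 when gamma == beta")
    w2 = omega**2
    num = w2 + gamma**2
    den = w2**2 + (gamma**2 + 2.0 * beta + 1.0) * w2 + (gamma - beta) ** 2
    return num / den


def averaged_gain(
    omega,
    gamma_dist: ParamDistribution,
    beta_dist: ParamDistribution,
    n_nodes: int = 64,
):
    """Population-averaged gain Gbar(omega) = E_{gamma,beta}[G(omega; gamma, beta)].

    gamma and beta are independent; discrete families enter as exact finite
    mixtures, continuous ones through fixed-order Gauss-Legendre quadrature
    (tensor product when both are continuous).  Vectorized over omega.
    """
    glo, _ = gamma_dist.support()
    _, bhi = beta_dist.support()
    if glo <= bhi and _supports_touch(gamma_dist, beta_dist):
        raise SingularGainError(
            "support allows gamma == beta: the averaged gain diverges at omega=0"
        )
    gx, gw = gamma_dist.nodes_weights(n_nodes)
    bx, bw = beta_dist.nodes_weights(n_nodes)
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    w = np.atleast_1d(omega)
    # tensor product over (gamma, beta) nodes, broadcast over omega
    G = transfer_gain(w[:, None, None], gx[None, :, None], bx[None, None, :])
    out = np.einsum("fgb,g,b->f", G, gw, bw)
    return float(out[0]) if scalar else out


def _supports_touch(gamma_dist: ParamDistribution, beta_dist: ParamDistribution) -> bool:
    """True if gamma == beta has positive probability or sits on the support boundary."""
    glo, ghi = gamma_dist.support()
    blo, bhi = beta_dist.support()
    # Intervals [glo, ghi] and [blo, bhi] intersect -> some mass arbitrarily
    # close to gamma == beta (conservative for discrete families, where we
    # check the actual atoms instead).
    gx, _ = gamma_dist.nodes_weights(2)
    bx, _ = beta_dist.nodes_weights(2)
    discrete_g = gamma_dist.kind in ("constant", "two_point")
    discrete_b = beta_dist.kind in ("constant", "two_point")
    if discrete_g and discrete_b:
        return bool(np.any(np.isclose(gx[:, None], bx[None, :])))
    return (glo <= bhi) and (blo <= ghi)


# Frequency-maximization machinery -------------------------------------------

_OMEGA_GRID = np.concatenate([[0.0], np.logspace(-3, 3, 200)])


def _maximize_averaged(fn) -> tuple[float, float]:
    """Maximize a gain curve over omega >= 0.

    Candidates are omega = 0 plus a log-spaced grid on [1e-3, 1e3]; the best
    candidate is refined with bounded scalar optimization between its grid
    neighbours.  Ties break toward smaller omega.  Returns (omega*, fn(omega*)).
    """
    vals = fn(_OMEGA_GRID)
    best = int(np.argmax(vals))
    # argmax takes the first (smallest-omega) maximizer: the tie-break.
    lo = _OMEGA_GRID[max(best - 1, 0)]
    hi = _OMEGA_GRID[min(best + 1, len(_OMEGA_GRID) - 1)]
    w_star, v_star = _OMEGA_GRID[best], vals[best]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda w: -fn(np.array([w]))[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if -res.fun > v_star * (1 + 1e-15):
            w_star, v_star = float(res.x), float(-res.fun)
    return float(w_star), float(v_star)


def critical_coupling(
    gamma_dist: ParamDistribution,
    beta_dist: ParamDistribution,
    n_nodes: int = 64,
    force_search: bool = False,
) -> CriticalCoupling:
    """Transition point from the averaged-gain condition max_w Gbar(w) gc² = 1.

    When the whole support satisfies gamma > beta >= 0 the gain of every
    neuron peaks at omega = 0, hence so does the average, and the maximum
    is evaluated there directly (``force_search`` runs the numerical scan
    anyway).  Otherwise — notably under adaptation, beta < 0 — the peak can
    sit at a nonzero frequency and is located by a grid scan plus local
    refinement that always includes omega = 0 as a candidate.
    """
    glo, _ = gamma_dist.support()
    blo, bhi = beta_dist.support()
    zero_peak = (blo >= 0.0) and (glo > bhi)
    fn = lambda w: averaged_gain(w, gamma_dist, beta_dist, n_nodes=n_nodes)
    if zero_peak and not force_search:
        omega_star, gmax = 0.0, float(fn(np.array([0.0]))[0])
    else:
        omega_star, gmax = _maximize_averaged(fn)
    if not np.isfinite(gmax) or gmax <= 0:
        raise SingularGainError("averaged gain is not finite and positive at its maximum")
    return CriticalCoupling(
        gc=1.0 / np.sqrt(gmax),
        omega_star=omega_star,
        method="quadrature_general",
        spec={"gamma_dist": gamma_dist.to_dict(), "beta_dist": beta_dist.to_dict()},
    )


def critical_coupling_two_point(
    p: float, gamma_low: float, gamma_high: float, beta: float
) -> CriticalCoupling:
    """Closed-form transition point for a two-point mixture of decay rates.

        gc = ( p (gl/(gl-b))² + (1-p) (gh/(gh-b))² )^(-1/2)

    Requires gamma_high > gamma_low > beta >= 0, under which the averaged
    gain peaks at omega = 0.  At p = 0 this reduces to gc = 1 - beta/gamma_high,
    and further to the classical gc = 1 as beta -> 0 or gamma_high -> inf.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if not (gamma_high > gamma_low > beta >= 0.0):
        raise ValueError(
            "require gamma_high > gamma_low > beta >= 0, got "
            f"gamma_low={gamma_low}, gamma_high={gamma_high}, beta={beta}"
        )
    gmax = p * (gamma_low / (gamma_low - beta)) ** 2 + (1.0 - p) * (
        gamma_high / (gamma_high - beta)
    ) ** 2
    return CriticalCoupling(
        gc=float(gmax ** -0.5),
        omega_star=0.0,
        method="closed_form_two_point",
        spec={"p": p, "gamma_low": gamma_low, "gamma_high": gamma_high, "beta": beta},
    )


def naive_critical_coupling(
    gamma: float, mu_beta: float, sigma_beta: float
) -> CriticalCoupling:
    """Transition point under the naive Gaussian-mean-field treatment of beta spread.

    The earlier approximation absorbs the Gaussian heterogeneity of the
    feedback strength into an additional Gaussian mean field, giving the
    effective gain

        G_beta(w) = G(w; gamma, mu_beta) / (1 - sigma_beta²/(gamma²+w²) · G(w; gamma, mu_beta))

    and ghat_c = 1/sqrt(max_w G_beta).  If the denominator is non-positive
    anywhere on the frequency scan the approximation has broken down and a
    :class:`NaiveTheoryBreakdownError` is raised rather than extrapolating.
    """
    if sigma_beta < 0:
        raise ValueError("sigma_beta must be >= 0")

    def gb(w):
        w = np.asarray(w, dtype=float)
        G = transfer_gain(w, gamma, mu_beta)
        den = 1.0 - sigma_beta**2 / (gamma**2 + w**2) * G
        if np.any(den <= 0):
            raise NaiveTheoryBreakdownError(
                f"naive gain denominator non-positive (gamma={gamma}, mu_beta={mu_beta}, "
                f"sigma_beta={sigma_beta}): approximation invalid in this regime"
            )
        return G / den

    omega_star, gmax = _maximize_averaged(gb)
    return CriticalCoupling(
        gc=1.0 / np.sqrt(gmax),
        omega_star=omega_star,
        method="naive_gaussian",
        spec={"gamma": gamma, "mu_beta": mu_beta, "sigma_beta": sigma_beta},
    )
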