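"""Canned small models and trajectories for tests, docs and examples.

Everything regenerates deterministically from one seed; nothing is stored
on disk.  The pulse protocol is a documented default (three depolarizing
pulses followed by two hyperpolarizing ones): the qualitative contrast —
graded plateaus for the slow-auxiliary neuron versus prompt decay for the
normal one — is what matters, not the exact amplitudes.
"""

from __future__ import annotations


from .distributions import Constant, TwoPoint
from .dynamics import single_neuron_pulse_response
from .network import build_network

__all__ = ["DEFAULT_PULSES", "fixture_suite"]

# (t_start, t_end, amplitude): depolarizing then hyperpolarizing pulses
DEFAULT_PULSES = (
    (5.0, 6.0, 1.0),
    (15.0, 16.0, 1.0),
    (25.0, 26.0, 1.0),
    (35.0, 36.0, -1.0),
    (45.0, 46.0, -1.0),
)


def fixture_suite(seed: int = 0) -> dict:
    """Return the standard small fixtures keyed by name.

    * ``fig1_normal`` / ``fig1_gpa`` — single-neuron pulse trajectories for
      the normal (gamma=10, beta=0.5) and graded-persistent (gamma=0.51,
      beta=0.5) parameter sets.
    * ``linear_g0`` — a 20-neuron uncoupled network (linear oracle target).
    * ``two_point_below`` / ``two_point_above`` — small GPA-mixture
      networks at 0.7x and 1.5x their analytic critical coupling.
    """
    from .theory import critical_coupling_two_point

    gamma_tp = TwoPoint(p=0.5, low=1.0, high=10.0)
    beta_c = Constant(0.5)
    gc = critical_coupling_two_point(0.5, 1.0, 10.0, 0.5).gc
    return {
        "fig1_normal": single_neuron_pulse_response(10.0, 0.5, DEFAULT_PULSES, T_total=60.0),
        "fig1_gpa": single_neuron_pulse_response(0.51, 0.5, DEFAULT_PULSES, T_total=60.0),
        "linear_g0": build_network(TwoPoint(p=0.5, low=2.0, high=6.0), beta_c, 20, 0.0, seed),
        "two_point_below": build_network(gamma_tp, beta_c, 200, 0.7 * gc, seed),
        "two_point_above": build_network(gamma_tp, beta_c, 200, 1.5 * gc, seed),
    }
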