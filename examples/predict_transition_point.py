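"""Predict the order-chaos transition point for heterogeneous populations.

Evaluates the averaged-gain condition max_w Gbar(w) gc^2 = 1 for three
population specs: a GPA mixture of decay rates, a continuous feedback
spread, and an adaptation population where the gain peaks off zero.
"""

import numpy as np

import gpanet as gp

# Two-point mixture of decay rates: p is the fraction of slow (GPA) neurons.
print("GPA fraction p  ->  g_c (gamma_low=1, gamma_high=10, beta=0.5)")
for p in (0.0, 0.25, 0.5, 0.75, 1.0):
    cc = gp.critical_coupling_two_point(p, 1.0, 10.0, 0.5)
    print(f"  p={p:4.2f}   g_c = {cc.gc:.4f}")
# g_c falls from 0.95 toward 0.5 as slow neurons are mixed in: GPA neurons
# expand the dynamical (chaotic) regime.

# Continuous feedback heterogeneity: gamma=3, beta ~ U[0, 2.9].
cc = gp.critical_coupling(gp.Constant(3.0), gp.Uniform(0.0, 2.9))
print(f"\ngamma=3, beta ~ U[0,2.9]: g_c = {cc.gc:.4f} (peak at omega = {cc.omega_star})")

# Adaptation (beta < 0): the averaged gain peaks at a nonzero frequency,
# and parameter spread *raises* g_c, unlike the naive mean-field estimate.
print("\nsigma_beta   averaged-gain g_c   naive g_c   (gamma=0.5, mu_beta=-0.5)")
for s in (0.0, 0.4, 0.8):
    naive = gp.naive_critical_coupling(0.5, -0.5, s).gc
    bd = gp.Constant(-0.5) if s == 0 else gp.TruncatedNormal(-0.5, s, -0.5 - 4 * s, 0.0)
    correct = gp.critical_coupling(gp.Constant(0.5), bd).gc
    print(f"  {s:4.1f}        {correct:.4f}             {naive:.4f}")
# The two predictions move in opposite directions with sigma_beta: the
# population-averaged condition says adaptation heterogeneity stabilizes
# the quiescent state (g_c grows), the naive one says the opposite.
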