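"""Transfer gain, averaged gain, and critical-coupling predictions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gpanet as gp
from gpanet.theory import NaiveTheoryBreakdownError, SingularGainError


class TestTransferGain:
    def test_zero_frequency_closed_form(self):
        # G(0) = gamma^2 / (gamma - beta)^2
        assert gp.transfer_gain(0.0, 10.0, 0.5) == pytest.approx(100 / 90.25)
        assert gp.transfer_gain(0.0, 1.0, 0.5) == pytest.approx(4.0)

    def test_beta_zero_reduces_to_leaky_integrator(self):
        w = np.linspace(0, 5, 11)
        np.testing.assert_allclose(
            gp.transfer_gain(w, 3.0, 0.0), 1.0 / (w**2 + 1.0), rtol=1e-12
        )

    @given(
        w=st.floats(-10, 10),
        gamma=st.floats(0.1, 10),
        beta=st.floats(0.0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_even_and_nonnegative(self, w, gamma, beta):
        if gamma == beta:
            return
        g1 = gp.transfer_gain(w, gamma, beta)
        assert g1 >= 0
        assert g1 == pytest.approx(gp.transfer_gain(-w, gamma, beta))

    def test_zero_frequency_peak_when_gamma_exceeds_beta(self):
        """For gamma > beta > 0 the gain has its unique maximum at omega = 0."""
        w = np.linspace(0, 50, 2001)
        for gamma, beta in [(1.0, 0.5), (10.0, 0.5), (3.0, 2.9), (0.51, 0.5)]:
            g = gp.transfer_gain(w, gamma, beta)
            assert np.argmax(g) == 0
            assert np.all(np.diff(g) <= 1e-15)

    def test_singular_at_gamma_equals_beta(self):
        with pytest.raises(SingularGainError):
            gp.transfer_gain(0.0, 1.0, 1.0)


class TestAveragedGain:
    def test_constant_dists_reduce_to_pointwise_gain(self):
        w = np.linspace(0, 3, 7)
        np.testing.assert_allclose(
            gp.averaged_gain(w, gp.Constant(2.0), gp.Constant(0.5)),
            gp.transfer_gain(w, 2.0, 0.5),
            rtol=1e-12,
        )

    def test_two_point_mixture_closed_form(self):
        got = gp.averaged_gain(0.0, gp.TwoPoint(p=0.5, low=1, high=10), gp.Constant(0.5))
        assert got == pytest.approx(0.5 * 4.0 + 0.5 * (10 / 9.5) ** 2)

    def test_uniform_beta_closed_form_integral(self):
        # E[(3/(3-b))^2], b ~ U[0, 2.9] = (9/2.9)(1/0.1 - 1/3) = 30
        got = gp.averaged_gain(0.0, gp.Constant(3.0), gp.Uniform(0.0, 2.9))
        assert got == pytest.approx(30.0, rel=1e-10)

    def test_quadrature_matches_monte_carlo(self):
        gd, bd = gp.Uniform(1.0, 10.0), gp.TruncatedNormal(-0.5, 0.3, -1.7, 0.0)
        rng = np.random.default_rng(11)
        gs = gd.sample(10**5, rng)
        bs = bd.sample(10**5, rng)
        for w in (0.0, 0.7):
            mc_vals = gp.transfer_gain(w, gs, bs)
            se = mc_vals.std() / np.sqrt(mc_vals.size)
            assert abs(gp.averaged_gain(w, gd, bd) - mc_vals.mean()) < 4 * se

    def test_quadrature_converges_on_node_doubling(self):
        gd, bd = gp.Uniform(1.0, 10.0), gp.Uniform(0.0, 0.9)
        a = gp.averaged_gain(0.3, gd, bd, n_nodes=64)
        b = gp.averaged_gain(0.3, gd, bd, n_nodes=128)
        assert a == pytest.approx(b, rel=1e-10)

    def test_singular_support_raises(self):
        with pytest.raises(SingularGainError):
            gp.averaged_gain(0.0, gp.Uniform(0.5, 2.0), gp.Uniform(0.0, 1.0))


class TestCriticalCoupling:
    def test_conventional_limit_is_one(self):
        assert gp.critical_coupling_two_point(0.0, 1.0, 10.0, 0.0).gc == pytest.approx(1.0)
        # gamma_high -> infinity at fixed beta
        assert gp.critical_coupling_two_point(0.0, 1.0, 1e9, 0.5).gc == pytest.approx(1.0, abs=1e-6)

    def test_homogeneous_simplification(self):
        # p=0: gc = 1 - beta/gamma_high
        assert gp.critical_coupling_two_point(0.0, 1.0, 10.0, 0.5).gc == pytest.approx(0.95)

    def test_single_population_p_one(self):
        assert gp.critical_coupling_two_point(1.0, 1.0, 10.0, 0.5).gc == pytest.approx(0.5)

    def test_monotonically_decreasing_in_p(self):
        ps = np.linspace(0, 1, 21)
        gcs = [gp.critical_coupling_two_point(p, 1.0, 5.0, 0.5).gc for p in ps]
        assert np.all(np.diff(gcs) < 0)

    def test_uniform_beta_printed_value(self):
        cc = gp.critical_coupling(gp.Constant(3.0), gp.Uniform(0.0, 2.9))
        assert cc.gc == pytest.approx(30**-0.5, rel=1e-10)
        assert round(cc.gc, 3) == 0.183
        assert cc.omega_star == 0.0

    def test_self_consistency_gc_squared_times_gain(self):
        for gd, bd in [
            (gp.Constant(3.0), gp.Uniform(0.0, 2.9)),
            (gp.Constant(0.5), gp.TruncatedNormal(-0.5, 0.4, -2.1, 0.0)),
            (gp.TwoPoint(p=0.3, low=1, high=5), gp.Constant(0.5)),
        ]:
            cc = gp.critical_coupling(gd, bd, force_search=True)
            gain = gp.averaged_gain(cc.omega_star, gd, bd)
            assert cc.gc**2 * gain == pytest.approx(1.0, rel=1e-8)

    @given(
        p=st.floats(0.0, 1.0),
        beta=st.floats(0.0, 0.9),
        glow=st.floats(1.0, 3.0),
        dg=st.floats(0.5, 10.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_general_path_matches_closed_form(self, p, beta, glow, dg):
        """Quadrature + frequency search equals the closed-form expression."""
        ghigh = glow + dg
        spec = gp.TwoPoint(p=p, low=glow, high=ghigh) if 0 < p < 1 else (
            gp.Constant(glow) if p == 1 else gp.Constant(ghigh)
        )
        cc_gen = gp.critical_coupling(spec, gp.Constant(beta), force_search=True)
        cc_cf = gp.critical_coupling_two_point(p, glow, ghigh, beta)
        assert cc_gen.gc == pytest.approx(cc_cf.gc, rel=1e-8)
        assert cc_gen.omega_star == pytest.approx(0.0, abs=1e-6)

    def test_two_point_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            gp.critical_coupling_two_point(0.5, 2.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            gp.critical_coupling_two_point(0.5, 1.0, 5.0, 1.5)


class TestNaivePrediction:
    def test_sigma_zero_equals_general_constant_beta(self):
        n = gp.naive_critical_coupling(1.0, -1.0, 0.0)
        c = gp.critical_coupling(gp.Constant(1.0), gp.Constant(-1.0))
        assert n.gc == pytest.approx(c.gc, rel=1e-8)
        assert n.omega_star == pytest.approx(c.omega_star, rel=1e-3)

    def test_adaptation_peak_frequency_is_nonzero(self):
        """Under adaptation (beta < 0) the averaged gain peaks away from omega=0."""
        c = gp.critical_coupling(gp.Constant(1.0), gp.Constant(-1.0))
        assert c.omega_star > 0.1

    def test_naive_nonincreasing_in_sigma(self):
        gcs = [gp.naive_critical_coupling(0.5, -0.5, s).gc for s in (0.0, 0.2, 0.4, 0.6)]
        assert np.all(np.diff(gcs) <= 0)

    def test_predictions_diverge_in_direction(self):
        """Population-averaged gain says spread stabilizes; the naive mean field says the opposite."""
        sigmas = (0.0, 0.4, 0.8)
        correct, naive = [], []
        for s in sigmas:
            naive.append(gp.naive_critical_coupling(0.5, -0.5, s).gc)
            bd = gp.Constant(-0.5) if s == 0 else gp.TruncatedNormal(-0.5, s, -0.5 - 4 * s, min(-0.5 + 4 * s, 0.0))
            correct.append(gp.critical_coupling(gp.Constant(0.5), bd).gc)
        assert np.all(np.diff(correct) > 0)
        assert np.all(np.diff(naive) < 0)

    def test_breakdown_reported_not_clipped(self):
        with pytest.raises(NaiveTheoryBreakdownError):
            gp.naive_critical_coupling(0.2, -0.5, 0.8)
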