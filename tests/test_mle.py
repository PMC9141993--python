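"""Likelihood, profile MLE and EM: hand values, identities, convergence."""

import numpy as np
import pytest

from jpcgied import (
    JPCSample,
    JPCScheme,
    JointGIEDParams,
    NoMLEError,
    estep,
    fit_em,
    fit_profile,
    observed_loglik,
    profile_loglik,
    profile_shapes,
)
from jpcgied.gied import GIEDParams, log1mexp
from jpcgied.mle import truncated_expectation
from jpcgied.scheme import parse_scheme, simulate_jpc

from conftest import make_datasets


class TestObservedLoglik:
    def test_toy_hand_value(self, toy_sample):
        """Term-by-term hand evaluation at (1, 1, 1):
        sum over i of [s_i + t_i] * A_i - sum [2 ln w_i + 1/w_i], A_i = ln(1-e^(-1/w_i))."""
        val = observed_loglik(JointGIEDParams(1.0, 1.0, 1.0), toy_sample)
        a1 = np.log(1 - np.exp(-1.0))
        a2 = np.log(1 - np.exp(-0.5))
        expected = (a1 + a2) - (2 * np.log(1) + 1.0) - (2 * np.log(2) + 0.5)
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(-4.27772, abs=1e-5)

    def test_loglik_ratio_identity(self, toy_sample):
        p = JointGIEDParams(1.0, 1.0, 1.0)
        q = JointGIEDParams(2.0, 0.5, 1.3)
        diff = observed_loglik(p, toy_sample) - observed_loglik(q, toy_sample)
        assert np.exp(diff) == pytest.approx(np.exp(observed_loglik(p, toy_sample))
                                             / np.exp(observed_loglik(q, toy_sample)))

    def test_time_rescaling_invariance(self, sim_sample):
        """Rescaling w -> c w with lam -> c lam shifts the log-likelihood by a
        data-only constant, so the maximizer transforms accordingly."""
        c = 3.7
        d = sim_sample
        scaled = JPCSample(w=d.w * c, z=d.z, s=d.s, t=d.t, scheme=d.scheme)
        f1 = fit_profile(d)
        f2 = fit_profile(scaled)
        assert f2.params.lam == pytest.approx(c * f1.params.lam, rel=1e-5)
        assert f2.params.theta1 == pytest.approx(f1.params.theta1, rel=1e-5)
        assert f2.params.theta2 == pytest.approx(f1.params.theta2, rel=1e-5)


class TestProfileShapes:
    def test_toy_values(self, toy_sample):
        th1, th2 = profile_shapes(1.0, toy_sample)
        assert th1 == pytest.approx(1.090096, abs=1e-5)
        assert th2 == pytest.approx(0.536048, abs=1e-5)

    def test_first_order_conditions(self, toy_sample):
        lam = 1.0
        th1, th2 = profile_shapes(lam, toy_sample)
        eps = 1e-6
        base = observed_loglik(JointGIEDParams(th1, th2, lam), toy_sample)
        g1 = (observed_loglik(JointGIEDParams(th1 + eps, th2, lam), toy_sample) - base) / eps
        g2 = (observed_loglik(JointGIEDParams(th1, th2 + eps, lam), toy_sample) - base) / eps
        assert abs(g1) < 1e-5 and abs(g2) < 1e-5

    def test_no_mle_when_one_line_silent(self):
        # both failures from line 1: k2 = 0
        scheme = JPCScheme(m=2, n=2, k=2, R=(1, 1))
        d = JPCSample(w=[1.0, 2.0], z=[1, 1], s=[0, 0], t=[1, 1], scheme=scheme)
        with pytest.raises(NoMLEError):
            profile_shapes(1.0, d)
        with pytest.raises(NoMLEError):
            fit_profile(d)


class TestProfileLoglik:
    def test_equals_plugged_in_loglik(self, toy_sample):
        lam = 0.7
        th1, th2 = profile_shapes(lam, toy_sample)
        assert profile_loglik(lam, toy_sample) == observed_loglik(
            JointGIEDParams(th1, th2, lam), toy_sample)

    def test_unimodal(self, sim_sample):
        """One sign change of finite differences: single interior maximum."""
        lam = np.geomspace(1e-4, 50, 400)
        vals = np.array([profile_loglik(l, sim_sample) for l in lam])
        sign = np.sign(np.diff(vals))
        changes = np.sum(np.diff(sign[sign != 0]) != 0)
        assert changes == 1

    def test_diverges_at_boundaries(self, sim_sample):
        """The profile falls away from its maximum in both tails (fast on the
        right where -lam*sum(1/w) dominates, slowly ~ -k1 lnln(1/lam) on the
        left)."""
        peak = fit_profile(sim_sample).loglik
        assert profile_loglik(1e-10, sim_sample) < peak - 5
        assert profile_loglik(1e4, sim_sample) < peak - 100


class TestFitProfile:
    def test_jute_joint_common_rate(self, jute):
        """Pooled complete-data fit with one shared rate parameter."""
        from jpcgied.studies import _complete_jpc_sample
        fr = fit_profile(_complete_jpc_sample(*jute))
        assert fr.params.theta1 == pytest.approx(1.454, abs=1e-3)
        assert fr.params.theta2 == pytest.approx(1.596, abs=1e-3)
        assert fr.params.lam == pytest.approx(0.228, abs=1e-3)

    def test_consistency_large_sample(self, std_params):
        scheme = JPCScheme(m=2250, n=2250, k=4500, R=(0,) * 4500)
        d = simulate_jpc(std_params, scheme, seed=10)
        fr = fit_profile(d)
        assert abs(fr.params.theta1 - 1.0) < 0.1
        assert abs(fr.params.theta2 - 1.0) < 0.1
        assert abs(fr.params.lam - 0.5) < 0.1

    def test_multistart_uniqueness(self, sim_sample):
        """Dispersed starting brackets converge to one maximizer (unimodality)."""
        lams = [fit_profile(sim_sample, bracket=(lo, hi)).params.lam
                for lo, hi in [(1e-4, 0.01), (0.005, 0.1), (0.05, 1.0),
                               (0.5, 10.0), (5.0, 100.0)]]
        assert np.ptp(lams) < 1e-6


class TestEStep:
    @pytest.mark.parametrize("theta,lam,w", [
        (2.0, 1.0, 1.0), (0.5, 0.3, 0.2), (1.84, 0.29, 0.5), (5.0, 2.0, 3.0)])
    def test_log1mexp_closed_form(self, theta, lam, w):
        """E[ln(1-e^(-lam/U)) | U>w] = ln(1-e^(-lam/w)) - 1/theta at the
        conditioning rate (probability-integral-transform argument)."""
        p = GIEDParams(theta, lam)
        got = truncated_expectation(lambda u: log1mexp(lam / u), p, w)
        assert got == pytest.approx(float(log1mexp(lam / w)) - 1.0 / theta, abs=1e-8)

    def test_inverse_moment_closed_form(self):
        """theta=1, lam=1, w=1: substitution y=1/u gives (1-2/e)/(1-1/e)."""
        got = truncated_expectation(lambda u: 1.0 / u, GIEDParams(1.0, 1.0), 1.0)
        assert got == pytest.approx((1 - 2 / np.e) / (1 - 1 / np.e), abs=1e-10)

    def test_survivor_bounds(self, sim_sample, std_params):
        e = estep(std_params, sim_sample)
        for i in range(sim_sample.k):
            if sim_sample.s[i] > 0:
                assert e.e_inv_u[i] < 1.0 / sim_sample.w[i]
                assert e.e_log1mexp_u[i] < float(log1mexp(std_params.lam / sim_sample.w[i]))
            if sim_sample.t[i] > 0:
                assert e.e_inv_v[i] < 1.0 / sim_sample.w[i]


class TestFitEM:
    def test_monotone_loglik_trace(self, std_params, table1_scheme):
        for seed in (1, 2, 3):
            d = simulate_jpc(std_params, table1_scheme, seed)
            if d.k1 == 0 or d.k2 == 0:
                continue
            fr = fit_em(d)
            ll = [observed_loglik(p, d) for p in fr.trace]
            assert np.all(np.diff(ll) > -1e-6)

    def test_fixed_point_is_stationary(self, sim_sample):
        fr = fit_em(sim_sample)
        p = fr.params
        eps = 1e-6
        base = observed_loglik(p, sim_sample)
        grads = []
        for dth1, dth2, dlam in np.eye(3) * eps:
            q = JointGIEDParams(p.theta1 + dth1, p.theta2 + dth2, p.lam + dlam)
            grads.append((observed_loglik(q, sim_sample) - base) / eps)
        assert np.all(np.abs(grads) < 1e-2)

    def test_agrees_with_profile(self, std_params, table1_scheme):
        schemes = [table1_scheme, parse_scheme("(2(12),1,0(7))", 20, 25, 20)]
        for d in make_datasets(std_params, schemes, 3, seed0=50):
            fp, fe = fit_profile(d), fit_em(d)
            assert fe.params.theta1 == pytest.approx(fp.params.theta1, abs=1e-3)
            assert fe.params.theta2 == pytest.approx(fp.params.theta2, abs=1e-3)
            assert fe.params.lam == pytest.approx(fp.params.lam, abs=1e-3)

    def test_complete_data_jute(self, jute):
        """No censored units: EM reduces to direct maximization."""
        from jpcgied.studies import _complete_jpc_sample
        fr = fit_em(_complete_jpc_sample(*jute))
        assert fr.converged
        assert fr.params.theta1 == pytest.approx(1.454, abs=2e-3)
        assert fr.params.theta2 == pytest.approx(1.596, abs=2e-3)
        assert fr.params.lam == pytest.approx(0.228, abs=2e-3)


def test_parameter_recovery(std_params, table1_scheme):
    """Median estimates over seeded replicates sit close to the truth."""
    rng = np.random.default_rng(123)
    ests = []
    while len(ests) < 200:
        d = simulate_jpc(std_params, table1_scheme, rng)
        if d.k1 == 0 or d.k2 == 0:
            continue
        p = fit_profile(d).params
        ests.append([p.theta1, p.theta2, p.lam])
    ests = np.array(ests)
    med = np.median(ests, axis=0)
    truth = np.array([1.0, 1.0, 0.5])
    se_med = 1.2533 * ests.std(axis=0) / np.sqrt(len(ests))
    assert np.all(np.abs(med - truth) < 3 * se_med + 0.05)
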