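"""Reconstructed-process probabilities and duplication-time densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from duplifate import (
    MechanismParams,
    Timeline,
    conditional_density,
    conditional_log_density,
    eta,
    joint_log_density,
    lineage_count_prob,
    survival_prob,
    u_prob,
)
from duplifate.time_model import _reconstructed_quantities
from duplifate.hazards import loss_rate


def const_rate_survival(lam, mu, tau, T):
    """Classic closed form for P(tau, T) under constant birth/death rates."""
    return (lam - mu) / (lam - mu * np.exp((mu - lam) * (T - tau)))


class TestTimeline:
    def test_validation(self):
        with pytest.raises(ValueError):
            Timeline(T=10.0, n0=2, nT=4, times=np.array([5.0]))  # wrong count
        with pytest.raises(ValueError):
            Timeline(T=10.0, n0=2, nT=3, times=np.array([10.5]))  # beyond T
        with pytest.raises(ValueError):
            Timeline(T=10.0, n0=2, nT=4, times=np.array([5.0, 5.0]))  # ties

    def test_from_times_roundtrip(self):
        tl = Timeline.from_times([3.0, 1.0, 2.0], T=5.0)
        assert tl.nT == 5
        assert np.all(np.diff(tl.times) > 0)
        df = tl.to_dataframe(replicate_id=7)
        assert list(df["event_index"]) == [3, 4, 5]
        assert set(df["replicate_id"]) == {7}


class TestSurvivalProb:
    def test_empty_interval_certain(self, neo):
        assert survival_prob(neo, tau=4.0, T=4.0) == 1.0

    @pytest.mark.parametrize("lam", [0.1, 0.2, 0.7])
    @pytest.mark.parametrize("mu", [0.3, 0.8, 1.5])
    @pytest.mark.parametrize("tau", [0.0, 2.5, 8.0])
    def test_matches_constant_rate_closed_form(self, lam, mu, tau):
        params = MechanismParams.nonfunctionalization(lam, mu)
        oracle = const_rate_survival(lam, mu, tau, 10.0)
        assert survival_prob(params, tau=tau, T=10.0) == pytest.approx(oracle, rel=1e-8)

    def test_near_pure_birth_survival_certain(self):
        params = MechanismParams.nonfunctionalization(0.2, 1e-14)
        assert survival_prob(params, tau=0.0, T=10.0) == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_agrees_with_quadrature(self, neo):
        det = survival_prob(neo, tau=0.0, T=10.0)
        mc = survival_prob(
            neo, tau=0.0, T=10.0, method="monte-carlo",
            rng=np.random.default_rng(0), n_mc=400_000,
        )
        assert mc == pytest.approx(det, rel=5e-3)

    def test_vectorized_core_matches_scalar(self, sub):
        taus = np.array([0.0, 1.0, 4.0, 9.0, 10.0])
        log_p, _ = _reconstructed_quantities(sub.lam, loss_rate(sub), taus, 10.0)
        for tau, lp in zip(taus, log_p):
            assert np.exp(lp) == pytest.approx(
                survival_prob(sub, tau=tau, T=10.0), rel=1e-8
            )

    def test_bad_interval_rejected(self, neo):
        with pytest.raises(ValueError):
            survival_prob(neo, tau=5.0, T=4.0)


class TestUEta:
    def test_u_at_equal_times_zero(self, neo):
        assert u_prob(neo, ti=3.0, tj=3.0) == 0.0

    def test_u_nonfunc_from_closed_form(self, nonfunc):
        # 1 - P(0,10) e^{rho(0,10)} with both pieces from the constant-rate oracle
        oracle = 1 - const_rate_survival(0.2, 0.8, 0, 10) * np.exp(6.0)
        assert u_prob(nonfunc, ti=0.0, tj=10.0) == pytest.approx(oracle, rel=1e-8)
        assert oracle == pytest.approx(0.2495, abs=2e-4)

    def test_u_pure_birth_reduction(self):
        # with no loss, u is the probability of at least one birth
        params = MechanismParams.nonfunctionalization(0.2, 1e-14)
        assert u_prob(params, ti=0.0, tj=10.0) == pytest.approx(1 - np.exp(-2), rel=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(
        ti=st.floats(0, 10), tj=st.floats(0, 10),
        key=st.sampled_from(["nonfunc", "neo", "sub"]),
    )
    def test_u_in_unit_interval(self, trio, ti, tj, key):
        ti, tj = sorted([ti, tj])
        u = u_prob(trio[key], ti=ti, tj=tj)
        assert 0.0 <= u < 1.0

    def test_eta_identities(self, nonfunc):
        assert eta(nonfunc, ti=2.0, tj=2.0, T=10.0) == 0.0
        # with tj = T, u_{jT} = 0 and eta reduces to u_{iT}
        assert eta(nonfunc, ti=0.0, tj=10.0, T=10.0) == pytest.approx(
            u_prob(nonfunc, ti=0.0, tj=10.0), rel=1e-10
        )

    def test_eta_composes_u_values(self, nonfunc):
        u_0T = u_prob(nonfunc, ti=0.0, tj=10.0)
        u_5T = u_prob(nonfunc, ti=5.0, tj=10.0)
        oracle = 1 - (1 - u_0T) / (1 - u_5T)
        assert eta(nonfunc, ti=0.0, tj=5.0, T=10.0) == pytest.approx(oracle, rel=1e-8)


class TestLineageCountProb:
    def test_no_growth_case(self):
        assert lineage_count_prob(3, 3, 0.25) == pytest.approx(0.75**3)

    def test_geometric_normalization(self):
        eta_val = 0.6
        total = sum(lineage_count_prob(1, n, eta_val) for n in range(1, 2000))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_binomial_normalization_truncated(self, nonfunc):
        eta_val = eta(nonfunc, ti=0.0, tj=10.0, T=10.0)
        total = sum(lineage_count_prob(2, n, eta_val) for n in range(2, 10_000))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lineage_count_prob(3, 2, 0.5)
        with pytest.raises(ValueError):
            lineage_count_prob(1, 2, 1.0)


class TestConditionalDensity:
    def test_support_enforced(self, nonfunc):
        with pytest.raises(ValueError):
            conditional_density(nonfunc, None, 0.5, 1.0, 3, 32, 10.0)
        with pytest.raises(ValueError):
            conditional_density(nonfunc, None, 10.0, 1.0, 3, 32, 10.0)

    @pytest.mark.parametrize("key", ["nonfunc", "neo", "sub"])
    def test_integrates_to_one(self, trio, key):
        params = trio[key]
        val, _ = integrate.quad(
            lambda t: conditional_density(params, None, t, 0.0, 3, 32, 10.0),
            1e-12, 10.0 - 1e-12, limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_composition(self, trio):
        """Dual route: compose Eq.-style P, u, eta and negative-binomial pieces."""
        for key in ("nonfunc", "neo", "sub"):
            params = trio[key]
            t, s, i, nT, T = 2.5, 0.0, 3, 32, 10.0
            P_t = survival_prob(params, tau=t, T=T)
            f_base = (i - 1) * params.lam * P_t * (1 - eta(params, ti=s, tj=t, T=T)) ** (i - 1)
            ratio = lineage_count_prob(i, nT, eta(params, ti=t, tj=T, T=T)) / \
                lineage_count_prob(i - 1, nT, eta(params, ti=s, tj=T, T=T))
            oracle = f_base * ratio
            assert conditional_density(params, None, t, s, i, nT, T) == pytest.approx(
                oracle, rel=1e-8
            )


class TestJointLogDensity:
    def test_no_events_is_certain(self, nonfunc):
        tl = Timeline(T=10.0, n0=2, nT=2, times=np.empty(0))
        assert joint_log_density(nonfunc, None, tl) == 0.0

    def test_single_event_matches_conditional(self, nonfunc):
        tl = Timeline.from_times([5.0], T=10.0, n0=2)
        expected = conditional_log_density(nonfunc, None, 5.0, 0.0, 3, 3, 10.0)
        assert joint_log_density(nonfunc, None, tl) == pytest.approx(expected, rel=1e-10)

    def test_telescopes_into_conditionals(self, trio, small_timeline):
        """The joint density factorizes into the sequential conditionals."""
        tl = small_timeline
        for params in trio.values():
            total = 0.0
            prev = 0.0
            for k, t in enumerate(tl.times):
                total += conditional_log_density(
                    params, None, t, prev, tl.n0 + 1 + k, tl.nT, tl.T
                )
                prev = t
            assert joint_log_density(params, None, tl) == pytest.approx(
                total, rel=1e-8
            )

    def test_deterministic_re_evaluation(self, sub, small_timeline):
        a = joint_log_density(sub, None, small_timeline)
        b = joint_log_density(sub, None, small_timeline)
        assert a == b
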