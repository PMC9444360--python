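"""Bayes estimators: posterior mapping, the three loss rules, their
quadrature oracles, limits and orderings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from lomaxshape import (
    GammaPosterior,
    Loss,
    LossSpec,
    PriorFamily,
    PriorSpec,
    SufficientStat,
    bayes_estimate,
    estimate_composite_linex,
    estimate_linex,
    estimate_self,
    mle,
    posterior,
)

STAT = SufficientStat(20, 10.0)


class TestPosteriorMapping:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (PriorSpec(PriorFamily.EXTENDED_JEFFREYS, c=0.5), (20.0, 10.0)),
            (PriorSpec(PriorFamily.GAMMA, k=0.6, d=0.2), (20.6, 10.2)),
            (PriorSpec(PriorFamily.INVERTED_LEVY, d=0.2), (20.5, 10.1)),
            (PriorSpec(PriorFamily.CHI_SQUARE, k=0.6, d=0.2), (20.3, 10.1)),
        ],
    )
    def test_mapping_table(self, spec, expected):
        post = posterior(spec, STAT)
        assert (post.shape_A, post.rate_B) == pytest.approx(expected, abs=1e-12)

    def test_posterior_integrates_to_one(self):
        post = posterior(PriorSpec(PriorFamily.GAMMA), STAT)
        total, _ = integrate.quad(
            lambda t: stats.gamma.pdf(t, a=post.shape_A, scale=1.0 / post.rate_B), 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_improper_posterior_rejected(self):
        # extended Jeffreys needs n > 2c - 1
        with pytest.raises(ValueError):
            posterior(PriorSpec(PriorFamily.EXTENDED_JEFFREYS, c=2.0), SufficientStat(2, 1.0))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(PriorFamily.GAMMA, k=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(PriorFamily.EXTENDED_JEFFREYS, c=0.0)


class TestLossRules:
    def test_self_is_posterior_mean(self):
        assert estimate_self(GammaPosterior(20.0, 10.0)) == pytest.approx(2.0, abs=1e-14)
        assert estimate_self(GammaPosterior(20.6, 10.2)) == pytest.approx(2.019608, abs=1e-6)

    def test_linex_closed_form(self):
        assert estimate_linex(GammaPosterior(20.6, 10.2), 1.0) == pytest.approx(
            20.6 * math.log(11.2 / 10.2), rel=1e-12
        )

    def test_composite_linex_closed_form(self):
        assert estimate_composite_linex(GammaPosterior(20.6, 10.2), 1.0) == pytest.approx(
            10.3 * math.log(11.2 / 9.2), rel=1e-12
        )

    @given(
        A=st.floats(1.0, 200.0),
        B=st.floats(0.5, 100.0),
        a=st.floats(0.05, 2.0),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_closed_forms_match_quadrature(self, A, B, a):
        """All three rules equal their defining posterior expectations."""
        post = GammaPosterior(A, B)
        dens = stats.gamma(a=A, scale=1.0 / B)
        # split at quantiles (widened so a tilt by e^{+-a t} stays covered)
        lo = 0.0
        hi = 4.0 * float(dens.ppf(1.0 - 1e-14))
        pts = [float(dens.ppf(q)) for q in (0.01, 0.5, 0.99)]

        def integrate_piecewise(f):
            total = 0.0
            for seg_lo, seg_hi in zip([lo] + pts, pts + [hi]):
                part, _ = integrate.quad(f, seg_lo, seg_hi, epsabs=0.0, epsrel=1e-11,
                                         limit=200)
                total += part
            return total

        def expect_mean():
            return integrate_piecewise(lambda t: t * dens.pdf(t))

        def mgf(sign):
            # integrate in log space so e^{a t} * pdf never overflows
            return integrate_piecewise(
                lambda t: float(np.exp(sign * a * t + dens.logpdf(t)))
            )

        assert estimate_self(post) == pytest.approx(expect_mean(), abs=1e-8, rel=1e-8)
        assert estimate_linex(post, a) == pytest.approx(
            -(1.0 / a) * math.log(mgf(-1)), abs=1e-8, rel=1e-8
        )
        if a < B / 2:  # keep E[e^{a theta}] numerically comfortable
            cllf = (1.0 / (2 * a)) * math.log(mgf(+1) / mgf(-1))
            assert estimate_composite_linex(post, a) == pytest.approx(cllf, abs=1e-8, rel=1e-8)

    @given(A=st.floats(1.0, 100.0), B=st.floats(1.0, 50.0), a=st.floats(1e-3, 0.9))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_ordering_linex_below_self_below_composite(self, A, B, a):
        post = GammaPosterior(A, B)
        a = a * B  # valid asymmetry in (0, B)
        assert estimate_linex(post, a) < estimate_self(post) < estimate_composite_linex(post, a)

    def test_small_a_limits_recover_posterior_mean(self):
        post = GammaPosterior(20.6, 10.2)
        mean = estimate_self(post)
        assert abs(estimate_linex(post, 1e-8) - mean) < 1e-7
        assert abs(estimate_composite_linex(post, 1e-8) - mean) < 1e-7

    def test_monotonicity_in_asymmetry(self):
        post = GammaPosterior(20.6, 10.2)
        grid = np.linspace(0.05, 5.0, 50)
        linex = [estimate_linex(post, a) for a in grid]
        cllf = [estimate_composite_linex(post, a) for a in grid]
        assert np.all(np.diff(linex) < 0)
        assert np.all(np.diff(cllf) > 0)

    def test_existence_preconditions(self):
        post = GammaPosterior(5.0, 2.0)
        with pytest.raises(ValueError):
            estimate_linex(post, -2.0)
        with pytest.raises(ValueError):
            estimate_linex(post, 0.0)
        with pytest.raises(ValueError):
            estimate_composite_linex(post, 2.0)
        with pytest.raises(ValueError):
            estimate_composite_linex(post, -1.0)


class TestDispatch:
    def test_jeffreys_self_equals_mle_at_half_c(self):
        spec = PriorSpec(PriorFamily.EXTENDED_JEFFREYS, c=0.5)
        est = bayes_estimate(spec, LossSpec(Loss.SELF), STAT)
        assert est == mle(STAT) == pytest.approx(2.0, abs=1e-14)

    def test_gamma_linex_instance(self):
        spec = PriorSpec(PriorFamily.GAMMA, k=0.6, d=0.2)
        est = bayes_estimate(spec, LossSpec(Loss.LINEX, a=1.5), STAT)
        assert est == pytest.approx((20.6 / 1.5) * math.log(1 + 1.5 / 10.2), rel=1e-12)
        assert est == pytest.approx(1.8842287, abs=1e-6)

    def test_inverted_levy_composite_instance(self):
        spec = PriorSpec(PriorFamily.INVERTED_LEVY, d=0.2)
        est = bayes_estimate(spec, LossSpec(Loss.COMPOSITE_LINEX, a=0.5), STAT)
        assert est == pytest.approx(20.5 * math.log(10.6 / 9.6), rel=1e-12)
        assert est == pytest.approx(2.0313635, abs=1e-6)

    def test_inverted_levy_mean_matches_gamma_ratio(self):
        """Posterior mean (n+1/2)/(T+d/2) equals the Gamma-function ratio
        Gamma(n+3/2)/Gamma(n+1/2)/(T+d/2), via log-gamma."""
        n, T, d = 20, 10.0, 0.2
        spec = PriorSpec(PriorFamily.INVERTED_LEVY, d=d)
        est = bayes_estimate(spec, LossSpec(Loss.SELF), SufficientStat(n, T))
        ratio = math.exp(special.gammaln(n + 1.5) - special.gammaln(n + 0.5)) / (T + d / 2)
        assert est == pytest.approx(ratio, rel=1e-12)
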