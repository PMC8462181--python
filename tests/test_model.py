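"""Probability functions of the N-mixture model against hand and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hiddendiv as hd
from hiddendiv.model import (
    CommunityHyperparams,
    DetectionHistory,
    RandomEffects,
    SiteDesign,
    SpeciesParams,
)


def single_site_design(strata=0, temp=0.0, date=0.0, temp_obs=0.0, n_occ=1):
    return SiteDesign(
        strata=[strata], temp_site=[temp], group_su=[0], group_sm=[0],
        date_obs=np.full((1, n_occ), date), temp_obs=np.full((1, n_occ), temp_obs),
        n_su=1, n_sm=1,
    )


def params_with(**kw):
    p = {name: np.zeros(1) for name in hd.model.PARAM_NAMES}
    for k, v in kw.items():
        p[k] = np.array([float(v)])
    return SpeciesParams(**p)


re0 = RandomEffects.zeros(1, 1)


class TestExpectedAbundance:
    @pytest.mark.parametrize(
        "kw, strata, temp, expected",
        [
            ({}, 0, 0.0, 1.0),                                            # exp(0)
            ({"beta_can": math.log(2), "beta1": math.log(1.5)}, 0, 1.0, 3.0),
            ({"beta_und": math.log(4)}, 1, 0.0, 4.0),
        ],
    )
    def test_hand_values(self, kw, strata, temp, expected):
        design = single_site_design(strata=strata, temp=temp)
        lam = hd.expected_abundance(params_with(**kw), re0, design, 0, 0)
        assert lam == pytest.approx(expected)

    def test_canopy_ignores_understory_intercept(self):
        design = single_site_design(strata=0)
        a = hd.expected_abundance(params_with(beta_can=0.7, beta_und=-3.0), re0, design, 0, 0)
        b = hd.expected_abundance(params_with(beta_can=0.7, beta_und=9.0), re0, design, 0, 0)
        assert a == b == pytest.approx(math.exp(0.7))

    def test_random_effects_enter_additively(self):
        design = single_site_design()
        re = RandomEffects(np.array([0.5]), np.array([-0.2]), 1.0, 1.0)
        assert hd.expected_abundance(params_with(), re, design, 0, 0) == pytest.approx(
            math.exp(0.3)
        )

    def test_index_out_of_range(self):
        design = single_site_design()
        with pytest.raises(IndexError):
            hd.expected_abundance(params_with(), re0, design, 1, 0)

    @given(bc=st.floats(-2, 2), bu=st.floats(-2, 2), strata=st.integers(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_strata_flip_symmetry(self, bc, bu, strata):
        """Swapping the two intercepts while flipping strata leaves lambda unchanged."""
        design = single_site_design(strata=strata)
        lam = hd.expected_abundance(params_with(beta_can=bc, beta_und=bu), re0, design, 0, 0)
        lam_flip = hd.expected_abundance(
            params_with(beta_can=bu, beta_und=bc), re0, design.flipped(), 0, 0
        )
        assert lam == pytest.approx(lam_flip)


class TestDetectionProb:
    @pytest.mark.parametrize(
        "kw, strata, date, expected",
        [
            ({}, 0, 0.0, 0.5),
            ({"alpha_und": math.log(0.8 / 0.2)}, 1, 0.0, 0.8),
            ({"alpha1": 1.0}, 0, -1.0, 1.0 / (1.0 + math.e)),
        ],
    )
    def test_hand_values(self, kw, strata, date, expected):
        design = single_site_design(strata=strata, date=date)
        p = hd.detection_prob(params_with(**kw), design, 0, 0, 0)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_strictly_inside_unit_interval(self):
        design = single_site_design()
        p = hd.detection_prob(params_with(alpha_can=30.0), design, 0, 0, 0)
        assert 0.0 < p < 1.0


class TestJointLoglik:
    def test_empty_counts_reduce_to_poisson(self):
        design = single_site_design()
        y = DetectionHistory(np.zeros((1, 1, 1), dtype=int))
        lam = 1.0  # all coefficients zero
        ll = hd.joint_loglik(y, np.zeros((1, 1), dtype=int), params_with(), re0, design)
        # N=0: Poisson(0; 1) = e^-1 and the Binomial(0; 0, p) term is 1
        assert ll == pytest.approx(-lam)

    def test_count_above_abundance_is_impossible(self):
        design = single_site_design()
        y = DetectionHistory(np.array([[[3]]]))
        ll = hd.joint_loglik(y, np.array([[2]]), params_with(), re0, design)
        assert ll == -np.inf

    def test_two_occasion_hand_case(self):
        design = single_site_design(n_occ=2)
        params = params_with(beta_can=math.log(2.0))  # lambda = 2, p = 0.5
        y = DetectionHistory(np.array([[[2], [1]]]))
        ll = hd.joint_loglik(y, np.array([[3]]), params, re0, design)
        expected = (
            stats.poisson.logpmf(3, 2.0)
            + stats.binom.logpmf(2, 3, 0.5)
            + stats.binom.logpmf(1, 3, 0.5)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_masked_occasions_are_excluded(self):
        design = single_site_design(n_occ=2)
        y_full = DetectionHistory(np.array([[[1], [1]]]))
        y_masked = DetectionHistory(np.array([[[1], [5]]]), mask=[[True, False]])
        N = np.array([[2]])
        ll_masked = hd.joint_loglik(y_masked, N, params_with(), re0, design)
        ll_one = hd.joint_loglik(
            DetectionHistory(np.array([[[1]]])), N, params_with(), re0, single_site_design()
        )
        assert ll_masked == pytest.approx(ll_one)
        assert ll_masked != hd.joint_loglik(y_full, N, params_with(), re0, design)


class TestMarginalLoglik:
    def _tiny(self):
        design = single_site_design(n_occ=2)
        params = params_with(beta_can=math.log(2.0))
        y = DetectionHistory(np.array([[[1], [0]]]))
        return y, params, design

    def test_matches_direct_enumeration(self):
        y, params, design = self._tiny()
        got = hd.marginal_loglik_truncated(y, params, re0, design, Nmax=100)
        total = 0.0
        for n in range(1, 101):
            total += math.exp(
                stats.poisson.logpmf(n, 2.0)
                + stats.binom.logpmf(1, n, 0.5)
                + stats.binom.logpmf(0, n, 0.5)
            )
        assert got == pytest.approx(math.log(total), abs=1e-10)

    def test_truncation_converged(self):
        y, params, design = self._tiny()
        a = hd.marginal_loglik_truncated(y, params, re0, design, Nmax=60)
        b = hd.marginal_loglik_truncated(y, params, re0, design, Nmax=110)
        assert a <= b + 1e-12
        assert b - a < 1e-10

    def test_perfect_detection_collapses_to_poisson(self):
        design = single_site_design(n_occ=2)
        params = params_with(beta_can=math.log(2.0), alpha_can=40.0)  # p ~ 1
        y = DetectionHistory(np.array([[[3], [3]]]))
        got = hd.marginal_loglik_truncated(y, params, re0, design, Nmax=150)
        assert got == pytest.approx(float(stats.poisson.logpmf(3, 2.0)), abs=1e-8)

    def test_nmax_below_observed_max_rejected(self):
        y, params, design = self._tiny()
        with pytest.raises(ValueError):
            hd.marginal_loglik_truncated(y, params, re0, design, Nmax=0)


class TestLogPrior:
    def base(self, **kw):
        return CommunityHyperparams(**kw)

    def test_sd_outside_uniform_support(self):
        with pytest.raises(ValueError):
            self.base(sd_beta_can=11.0)
        with pytest.raises(ValueError):
            self.base(sd_beta1=0.0)

    def test_sigma_above_ten_is_impossible(self):
        re_bad = RandomEffects(np.zeros(2), np.zeros(2), sigma_s=12.0, sigma_m=1.0)
        lp = hd.log_prior(SpeciesParams.zeros(3), re_bad, self.base())
        assert lp == -np.inf

    def test_species_at_community_mean_maximises_prior(self):
        hyper = self.base(mu_beta_can=0.4)
        at_mean = SpeciesParams(**{
            n: np.full(3, hyper.mu(n)) for n in hd.model.PARAM_NAMES
        })
        off_mean = SpeciesParams(**{
            n: np.full(3, hyper.mu(n) + 0.5) for n in hd.model.PARAM_NAMES
        })
        re = RandomEffects.zeros(2, 2)
        assert hd.log_prior(at_mean, re, hyper) > hd.log_prior(off_mean, re, hyper)

    @given(
        mu=st.floats(-3, 3), sd=st.floats(0.1, 9.9),
        sig=st.floats(0.1, 9.9), seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_finite_on_valid_states(self, mu, sd, sig, seed):
        """Joint loglik + log prior is finite on any state satisfying the invariants."""
        rng = np.random.default_rng(seed)
        hyper = CommunityHyperparams(
            **{f"mu_{n}": mu for n in hd.model.PARAM_NAMES},
            **{f"sd_{n}": sd for n in hd.model.PARAM_NAMES},
        )
        params = SpeciesParams(**{
            n: rng.normal(mu, sd, size=2) for n in hd.model.PARAM_NAMES
        })
        re = RandomEffects(rng.normal(0, sig, 1), rng.normal(0, sig, 1), sig, sig)
        design = single_site_design(n_occ=2)
        y = DetectionHistory(rng.integers(0, 3, size=(1, 2, 2)))
        N = y.max_counts() + rng.integers(0, 4, size=(1, 2))
        total = hd.joint_loglik(y, N, params, re, design) + hd.log_prior(params, re, hyper)
        assert np.isfinite(total)

    def test_detection_mean_prior_is_logistic(self):
        # density of logit(U), U~Uniform(0,1), at 0 is 1/4
        assert hd.model.logistic_logpdf(0.0) == pytest.approx(math.log(0.25))
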