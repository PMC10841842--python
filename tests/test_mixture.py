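"""Unit and property tests for the zero-truncated binomial mixture model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simpull import PopulationSpec, simulate_counts
from simpull.mixture import (FitConfig, MixtureFit, aic, corrected_distribution,
                             fit_fixed_g, log_likelihood, mixture_pmf,
                             select_model, ztb_pmf)

from oracles import brute_force_fit, ztb_pmf_enumerated


def make_fit(sizes, weights, p, ll=-1.0):
    return MixtureFit(g=len(sizes), component_sizes=tuple(sizes),
                      weights=tuple(weights), p=p, log_likelihood=ll,
                      aic=aic(ll, len(sizes)), aic_variant="paper",
                      n_obs=1, converged=True, n_iterations=1)


class TestZtbPmf:
    @pytest.mark.parametrize("x,m,p,expected", [
        (1, 1, 0.74, 1.0),            # truncation forces the only molecule on
        (2, 2, 0.5, 1.0 / 3.0),       # 0.25 / 0.75
        (3, 2, 0.9, 0.0),             # outside support
        (5, 4, 0.5, 0.0),
    ])
    def test_closed_form_values(self, x, m, p, expected):
        assert ztb_pmf(x, m, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    @pytest.mark.parametrize("p", [0.3, 0.74, 0.9])
    def test_matches_outcome_enumeration(self, m, p):
        for x in range(1, m + 1):
            assert ztb_pmf(x, m, p) == pytest.approx(
                ztb_pmf_enumerated(x, m, p), abs=1e-12)

    def test_p_one_limit_is_point_mass(self):
        assert ztb_pmf(3, 3, 1.0) == 1.0
        assert ztb_pmf(2, 3, 1.0) == 0.0

    @given(m=st.integers(1, 100),
           p=st.sampled_from([0.05, 0.25, 0.5, 0.74, 0.78, 0.95]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_normalizes_over_support(self, m, p):
        total = ztb_pmf(np.arange(1, m + 1), m, p).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            ztb_pmf(0, 3, 0.5)
        with pytest.raises(ValueError):
            ztb_pmf(1, 0, 0.5)
        with pytest.raises(ValueError):
            ztb_pmf(1, 3, 0.0)


class TestMixturePmf:
    def test_single_component_reduces_to_ztb(self):
        fit = make_fit([3], [1.0], 0.74)
        x = np.arange(1, 4)
        assert np.allclose(mixture_pmf(x, fit), ztb_pmf(x, 3, 0.74))

    def test_hand_computed_two_component_value(self):
        # m=(1,2), pi=(.5,.5), p=.5: P(X=1) = .5*1 + .5*(2/3) = 5/6
        fit = make_fit([1, 2], [0.5, 0.5], 0.5)
        assert mixture_pmf(1, fit) == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_normalizes_over_support(self):
        fit = make_fit([2, 5, 9], [0.2, 0.5, 0.3], 0.63)
        assert mixture_pmf(np.arange(1, 10), fit).sum() == pytest.approx(
            1.0, abs=1e-12)


class TestLogLikelihood:
    def test_certain_observation_gives_zero(self):
        assert log_likelihood([1], make_fit([1], [1.0], 0.74)) == 0.0

    def test_closed_form_two_counts(self):
        fit = make_fit([2], [1.0], 0.5)
        expected = math.log(2.0 / 3.0) + math.log(1.0 / 3.0)
        assert log_likelihood([1, 2], fit) == pytest.approx(expected, abs=1e-12)

    def test_count_beyond_support_is_minus_inf(self):
        assert log_likelihood([1, 5], make_fit([2], [1.0], 0.5)) == -math.inf

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], make_fit([2], [1.0], 0.5))


class TestAic:
    @pytest.mark.parametrize("ll,k,variant,expected", [
        (0.0, 1, "paper", 2.0),
        (-10.0, 2, "paper", 16.0),
        (-10.0, 2, "standard", 26.0),
    ])
    def test_formula(self, ll, k, variant, expected):
        assert aic(ll, k, variant) == expected


class TestFitFixedG:
    def test_all_ones_recovers_monomer(self):
        fit = fit_fixed_g(np.ones(50, int), 0.74, 1, FitConfig(seed=0))
        assert fit.component_sizes == (1,)
        assert fit.weights == (1.0,)

    def test_recovers_dimer_from_simulation(self, dimer_spec):
        counts = simulate_counts(dimer_spec, 2000, seed=7).counts
        fit = fit_fixed_g(counts, 0.78, 1, FitConfig(m_max=10, seed=0))
        assert fit.component_sizes == (2,)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Alternating maximization finds the global optimum found by
        exhaustive subset enumeration with scalar weight optimization."""
        rng = np.random.default_rng(seed)
        sizes = sorted(rng.choice(np.arange(1, 7), size=2, replace=False))
        w1 = rng.uniform(0.2, 0.8)
        p = rng.uniform(0.5, 0.9)
        spec = PopulationSpec(components=((int(sizes[0]), w1),
                                          (int(sizes[1]), 1 - w1)),
                              activity=p)
        counts = simulate_counts(spec, int(rng.integers(100, 300)),
                                 seed=seed + 1000).counts
        cfg = FitConfig(m_max=8, seed=seed)
        fit = fit_fixed_g(counts, p, 2, cfg)
        ll_oracle, _, _ = brute_force_fit(counts, p, 2, m_max=8)
        assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)

    def test_loglik_trace_is_monotone(self, monomer_dimer_sample):
        fit = fit_fixed_g(monomer_dimer_sample.counts, 0.74, 2,
                          FitConfig(m_max=10, seed=3))
        trace = np.array(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_infeasible_support_raises(self):
        counts = np.array([1, 2, 7])
        with pytest.raises(ValueError, match="m_max"):
            fit_fixed_g(counts, 0.74, 1, FitConfig(m_max=5))
        with pytest.raises(ValueError, match="support|m_max"):
            fit_fixed_g(np.array([1, 2, 21]), 0.74, 1,
                        FitConfig(m_max=20, support="even-only"))

    def test_even_only_support_yields_even_sizes(self):
        spec = PopulationSpec(components=((2, 0.7), (4, 0.3)), activity=0.78)
        counts = simulate_counts(spec, 1500, seed=5).counts
        cfg = FitConfig(m_max=10, support="even-only", seed=0)
        fit = fit_fixed_g(counts, 0.78, 2, cfg)
        assert all(m % 2 == 0 for m in fit.component_sizes)


class TestSelectModel:
    def test_single_valued_data_selects_one_component(self):
        fits, best = select_model(np.ones(100, int), 0.74,
                                  FitConfig(k_max=3, seed=0))
        assert best.g == 1

    def test_recovers_two_subpopulations(self):
        """Counts from a 50/50 monomer/tetramer mixture select g=2 with the
        right sizes in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            spec = PopulationSpec(components=((1, 0.5), (4, 0.5)),
                                  activity=0.78)
            counts = simulate_counts(spec, 5000, seed=seed).counts
            _, best = select_model(counts, 0.78,
                                   FitConfig(k_max=4, m_max=10, seed=0))
            if best.g == 2 and best.component_sizes == (1, 4):
                hits += 1
        assert hits >= 9

    def test_aic_tie_broken_toward_smaller_k(self):
        # duplicated-support data: every k >= 1 achieves the same likelihood,
        # so AIC strictly favors k=1 and larger k must never win a tie
        fits, best = select_model(np.ones(30, int), 0.74,
                                  FitConfig(k_max=2, seed=0))
        assert best.g == 1


class TestCorrectedDistribution:
    def test_single_dimer_component(self):
        stoich, implied = corrected_distribution(make_fit([2], [1.0], 0.74))
        assert stoich == {2: 1.0}
        assert implied[1] == pytest.approx(ztb_pmf(1, 2, 0.74))
        assert implied[2] == pytest.approx(ztb_pmf(2, 2, 0.74))

    def test_snu13_scenario_concentrates_on_two(self, dimer_spec):
        """A single sub-population of copy number 2 at mNG activity is fully
        recovered: all corrected weight at 2 copies."""
        counts = simulate_counts(dimer_spec, 2000, seed=21).counts
        _, best = select_model(counts, 0.74,
                               FitConfig(k_max=4, m_max=10, seed=0))
        stoich, _ = corrected_distribution(best)
        assert stoich.get(2, 0.0) > 0.99

    def test_implied_distribution_matches_mixture_pmf(self):
        fit = make_fit([1, 3], [0.4, 0.6], 0.6)
        _, implied = corrected_distribution(fit)
        for x, q in implied.items():
            assert q == pytest.approx(float(mixture_pmf(x, fit)), abs=1e-12)

    def test_high_activity_limit_matches_empirical(self):
        """As p -> 1 detection is certain, so the corrected distribution
        converges to the empirical count distribution."""
        rng = np.random.default_rng(8)
        counts = rng.choice([1, 2, 3], size=3000, p=[0.5, 0.3, 0.2])
        _, best = select_model(counts, 0.999,
                               FitConfig(k_max=4, m_max=6, seed=0))
        stoich, _ = corrected_distribution(best)
        emp = {v: (counts == v).mean() for v in (1, 2, 3)}
        for v in emp:
            assert stoich.get(v, 0.0) == pytest.approx(emp[v], abs=0.02)


def test_fit_serialization_roundtrip(monomer_dimer_sample):
    fit = fit_fixed_g(monomer_dimer_sample.counts, 0.74, 2,
                      FitConfig(m_max=10, seed=1))
    back = MixtureFit.from_json(fit.to_json())
    assert back.component_sizes == fit.component_sizes
    assert back.log_likelihood == fit.log_likelihood
    assert back.aic == fit.aic
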