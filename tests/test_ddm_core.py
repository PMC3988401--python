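"""Core diffusion process: parameter domains, simulator, exact density.

Oracles: the closed-form absorption probability and the optional-stopping
mean first-passage time of a drifted Wiener process between two absorbing
boundaries, both derived independently of the series-expansion density.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from satddm import ddm
from satddm.ddm import DDMParams, ParameterDomainError, TrialOutcome


class TestParamDomains:
    @pytest.mark.parametrize("kwargs", [
        dict(a=0.0, v=1.0),
        dict(a=-1.0, v=1.0),
        dict(a=1.0, v=1.0, z=0.0),
        dict(a=1.0, v=1.0, z=1.0),
        dict(a=1.0, v=1.0, ter=-0.1),
        dict(a=1.0, v=1.0, sv=-0.5),
        dict(a=1.0, v=1.0, z=0.1, sz=0.3),     # z - sz/2 <= 0
        dict(a=1.0, v=1.0, ter=0.02, st=0.1),  # Ter - st/2 < 0
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterDomainError):
            DDMParams(**kwargs)

    def test_valid_parameters_accepted(self):
        p = DDMParams(a=1.5, v=2.0, z=0.45, ter=0.3, sv=1.0, sz=0.05, st=0.1)
        assert p.a == 1.5 and p.st == 0.1


class TestSimulator:
    def test_zero_trials_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            ddm.simulate_dataset(DDMParams(a=1, v=1), 0)

    def test_dt_not_smaller_than_max_t_rejected(self):
        with pytest.raises(ValueError):
            ddm.simulate_dataset(DDMParams(a=1, v=1), 5, max_t=1.0, dt=1.0)

    def test_same_seed_reproduces_identical_trials(self):
        p = DDMParams(a=1.5, v=1.0, ter=0.3, sv=0.5)
        one = ddm.simulate_dataset(p, 50, dt=1e-3, seed=5)
        two = ddm.simulate_dataset(p, 50, dt=1e-3, seed=5)
        assert one == two

    def test_different_seeds_differ(self):
        p = DDMParams(a=1.5, v=1.0)
        one = ddm.simulate_dataset(p, 50, dt=1e-3, seed=1)
        two = ddm.simulate_dataset(p, 50, dt=1e-3, seed=2)
        assert one != two

    def test_symmetric_process_splits_evenly(self):
        p = DDMParams(a=1.5, v=0.0, z=0.5)
        _, up, out = ddm.simulate_arrays(p, 20_000, dt=1e-3, seed=3)
        assert abs(up[~out].mean() - 0.5) < 0.012  # ~3.5 binomial SEs

    @pytest.mark.parametrize("a,v,z", [
        (1.5, 2.0, 0.5), (2.0, -1.0, 0.4), (1.0, 0.5, 0.6),
    ])
    def test_hit_rate_matches_absorption_probability(self, a, v, z):
        p = DDMParams(a=a, v=v, z=z)
        _, up, out = ddm.simulate_arrays(p, 20_000, max_t=20, dt=1e-3, seed=11)
        expected = ddm.choice_probability(a, v, z)
        se = math.sqrt(expected * (1 - expected) / 20_000)
        assert abs(up.mean() - expected) < 4 * se + 1e-3

    def test_mean_rt_matches_first_passage_oracle(self):
        # E[T] = (a P_upper - z a) / v by optional stopping, plus Ter
        p = DDMParams(a=2.0, v=1.0, z=0.5, ter=0.3)
        rt, _, out = ddm.simulate_arrays(p, 100_000, max_t=30, dt=1e-3, seed=7)
        expected = ddm.mean_decision_time(2.0, 1.0, 0.5) + 0.3
        assert abs(rt[~out].mean() - expected) < 0.01

    def test_rt_not_below_minimum_nondecision_time(self):
        p = DDMParams(a=1.0, v=2.0, ter=0.3, st=0.1)
        outcomes = ddm.simulate_dataset(p, 200, dt=1e-3, seed=9)
        assert all(o.rt >= 0.25 for o in outcomes if not o.timed_out)

    def test_monotonicity_in_boundary_and_drift(self):
        # wider boundaries: more accurate and slower; stronger drift: more
        # upper-boundary hits
        acc, mrt = [], []
        for a in (0.8, 1.6, 2.4):
            rt, up, out = ddm.simulate_arrays(
                DDMParams(a=a, v=1.5), 8000, max_t=30, dt=1e-3, seed=21)
            acc.append(up[~out].mean())
            mrt.append(rt[~out].mean())
        assert acc == sorted(acc) and mrt == sorted(mrt)
        pu = [ddm.simulate_arrays(DDMParams(a=1.5, v=v), 8000, max_t=30,
                                  dt=1e-3, seed=22)[1].mean()
              for v in (0.5, 1.5, 3.0)]
        assert pu == sorted(pu)


class TestWfptDensity:
    @pytest.mark.parametrize("a,v,z", [
        (1.5, 2.0, 0.5), (2.0, -1.0, 0.4), (1.0, 0.0, 0.6), (2.3, 2.5, 0.55),
    ])
    def test_reflection_symmetry(self, a, v, z):
        for t in (0.05, 0.2, 0.5, 1.5):
            lo = ddm.wfpt_density(t, "lower", a, v, z)
            up = ddm.wfpt_density(t, "upper", a, -v, 1 - z)
            assert lo == pytest.approx(up, rel=1e-12)

    @pytest.mark.parametrize("a,v,z", [
        (1.5, 2.0, 0.5), (2.0, -1.0, 0.4), (1.0, 0.0, 0.6),
    ])
    def test_total_probability_is_one(self, a, v, z):
        total = sum(
            quad(lambda t: ddm.wfpt_density(t, b, a, v, z), 0, 60,
                 limit=200)[0]
            for b in ("upper", "lower"))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_time_gives_zero_density(self):
        assert ddm.wfpt_density(0.0, "upper", 1.5, 1.0, 0.5) == 0.0
        assert ddm.wfpt_density(-1.0, "lower", 1.5, 1.0, 0.5) == 0.0

    def test_density_nonnegative_on_grid(self):
        ts = np.linspace(1e-4, 5, 500)
        d = ddm.wfpt_density(ts, "upper", 1.2, -2.0, 0.3)
        assert np.all(d >= 0)

    @pytest.mark.parametrize("a,v,z,ter", [
        (1.5, 2.0, 0.5, 0.3), (2.0, 1.0, 0.4, 0.35), (1.0, 3.0, 0.55, 0.25),
        (2.4, 1.2, 0.5, 0.4), (0.8, 2.5, 0.45, 0.3),
    ])
    def test_simulator_matches_density_cdf(self, a, v, z, ter):
        # KS distance between simulated upper-boundary RTs and the CDF
        # implied by the density, over sets spanning the fitted range
        p = DDMParams(a=a, v=v, z=z, ter=ter)
        rt, up, out = ddm.simulate_arrays(p, 30_000, max_t=20, dt=1e-3,
                                          seed=31)
        sel = up & ~out
        grid = np.linspace(1e-4, 20, 4001)
        dens = np.array([ddm.wfpt_density(t, "upper", a, v, z) for t in grid])
        cdf_grid = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x - ter, grid, cdf_grid)

        res = kstest(rt[sel], cdf)
        assert res.statistic < 0.01


class TestChoiceProbability:
    def test_symmetric_case_is_half(self):
        assert ddm.choice_probability(1.7, 0.0, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("a,v,z", [(1.5, 2.0, 0.5), (2.0, -1.0, 0.35)])
    def test_complementary_boundaries_sum_to_one(self, a, v, z):
        assert ddm.choice_probability(a, v, z) + \
            ddm.choice_probability(a, -v, 1 - z) == pytest.approx(1.0)

    @pytest.mark.parametrize("a,v,z", [
        (1.5, 2.0, 0.5), (2.0, -1.0, 0.4), (1.0, 0.0, 0.6),
    ])
    def test_matches_integral_of_density(self, a, v, z):
        integral = quad(lambda t: ddm.wfpt_density(t, "upper", a, v, z),
                        0, 80, limit=300)[0]
        assert ddm.choice_probability(a, v, z) == pytest.approx(
            integral, abs=1e-5)


class TestTrialLoglik:
    def test_degenerate_variability_equals_pure_density(self):
        p = DDMParams(a=1.5, v=2.0, z=0.45, ter=0.3)
        out = TrialOutcome("upper", 0.8)
        expected = math.log(ddm.wfpt_density(0.5, "upper", 1.5, 2.0, 0.45))
        assert ddm.trial_loglik(out, p) == pytest.approx(expected, rel=1e-9)

    def test_impossible_rt_returns_floor(self):
        p = DDMParams(a=1.5, v=2.0, ter=0.4, st=0.1)
        out = TrialOutcome("upper", 0.3)  # rt < Ter - st/2
        assert ddm.trial_loglik(out, p) == pytest.approx(
            math.log(ddm.LOGLIK_FLOOR))

    def test_timed_out_trial_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            ddm.trial_loglik(TrialOutcome("upper", 2.4, timed_out=True),
                             DDMParams(a=1, v=1))

    def test_full_model_density_matches_simulation_histogram(self):
        # exp(trial_loglik) integrated over RT bins vs binned frequencies
        # from the stochastic process
        p = DDMParams(a=1.4, v=2.0, z=0.5, ter=0.35, sv=1.0, sz=0.05, st=0.1)
        n = 200_000
        rt, up, out = ddm.simulate_arrays(p, n, max_t=6, dt=1e-3, seed=41)
        edges = np.arange(0.3, 2.5, 0.1)
        grid = np.linspace(0.3, 2.4, 4201)
        for boundary, sel in (("upper", up & ~out), ("lower", ~up & ~out)):
            cnt, _ = np.histogram(rt[sel], bins=edges)
            dens = np.array([ddm.trial_density(t, boundary, p) for t in grid])
            cdf = np.concatenate(
                [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
            probs = np.diff(np.interp(edges, grid, cdf))
            se = np.sqrt(np.maximum(probs * n, 1.0))
            big = probs * n > 50
            assert np.all(np.abs(cnt[big] - probs[big] * n)
                          < 5 * se[big] + 0.002 * n * 0.1)
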