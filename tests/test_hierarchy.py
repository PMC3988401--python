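"""Hierarchical model, sampler, convergence diagnostics and DIC.

Oracles: direct summed trial log-likelihoods for the degenerate hierarchy,
the analytic posterior of the conjugate normal-means model, and the known
effective-parameter count pD = k for k free means under flat priors.
"""

import math

import numpy as np
import pandas as pd
import pytest

from satddm import ddm, variants
from satddm.hierarchy import (GaussianMeansModel, GroupPrior,
                              InitializationError, PosteriorSamples,
                              build_model, compute_dic, geweke_diagnostic,
                              sample_posterior)


@pytest.fixture(scope="module")
def fitted_small(filtered_small):
    """A short reduced-scale fit of the full variant, reused across tests."""
    truth, filtered, _ = filtered_small
    model = build_model(filtered, variants.get_variant("model 1"),
                        quad_nodes=5)
    samples = sample_posterior(model, n_samples=900, burn_in=400, seed=15)
    return truth, model, samples


class TestBuildModel:
    def test_empty_design_cell_is_named_in_error(self, filtered_small):
        _, filtered, _ = filtered_small
        broken = filtered[~((filtered.subject == 2) & (filtered.session == 2)
                            & (filtered.condition == "speed"))]
        with pytest.raises(ValueError, match="subject=2.*session=2.*speed"):
            build_model(broken, variants.get_variant("model 1"))

    def test_loglik_reduces_to_summed_trial_logliks(self, filtered_small):
        # degenerate hierarchy: with all variability at 0 and no censoring
        # the model likelihood is exactly the sum of per-trial logliks
        _, filtered, _ = filtered_small
        one = filtered[(filtered.subject == 1) & (filtered.session == 1)]
        model = build_model(one, variants.get_variant("model 1"),
                            fix={"sv": 0.0, "sz": 0.0, "st": 0.0},
                            censor_s=None, quad_nodes=5)
        x = model.init_state()
        direct = 0.0
        for k, (i, s, c) in enumerate(model.cells):
            ia, iv, iz, it = model.cell_slots[k]
            p = ddm.DDMParams(a=x[ia], v=x[iv], z=x[iz], ter=x[it])
            rt, upper, sign = model.cell_data[k]
            for t in range(len(rt)):
                out = ddm.TrialOutcome("upper" if upper[t] else "lower", rt[t])
                q = ddm.DDMParams(a=p.a, v=p.v * sign[t], z=p.z, ter=p.ter)
                direct += ddm.trial_loglik(out, q, quad_nodes=5)
        assert model.loglik(x) == pytest.approx(direct, rel=1e-9)

    def test_log_posterior_is_deterministic(self, fitted_small):
        _, model, _ = fitted_small
        x = model.init_state()
        assert model.log_posterior(x) == model.log_posterior(x)

    def test_truth_beats_heavily_perturbed_parameters(self, filtered_small):
        truth, filtered, _ = filtered_small
        model = build_model(filtered, variants.get_variant("model 1"),
                            quad_nodes=5)
        x = model.init_state().copy()
        for k, key in enumerate(model.cells):
            ia, iv, iz, it = model.cell_slots[k]
            p = truth.params[key]
            x[ia], x[iv], x[iz], x[it] = p.a, p.v, p.z, p.ter
        x[model.slot["sv"]] = truth.config.sv
        x[model.slot["sz"]] = truth.config.sz
        x[model.slot["st"]] = truth.config.st
        y = x.copy()
        for k in range(len(model.cells)):
            ia, iv, _, it = model.cell_slots[k]
            y[ia] *= 1.5
            y[iv] *= 0.5
            y[it] *= 0.5
        assert model.loglik(x) > model.loglik(y)

    def test_variant_constraints_shape_the_parameter_index(self, filtered_small):
        _, filtered, _ = filtered_small
        full = build_model(filtered, variants.get_variant("model 1"))
        constrained = build_model(filtered, variants.get_variant("model 6"))
        # full: one a slot per subject x session x condition; constrained:
        # a shared between conditions
        a_full = [n for n in full.slot_names if n.startswith("a[")]
        a_con = [n for n in constrained.slot_names if n.startswith("a[")]
        assert len(a_full) == 2 * len(a_con)
        # z never varies between conditions
        assert all(n.count(",") == 1 for n in full.slot_names
                   if n.startswith("z["))


class TestSampler:
    def test_same_seed_gives_bit_identical_chains(self, filtered_small):
        _, filtered, _ = filtered_small
        one = filtered[(filtered.subject == 1) & (filtered.session == 1)]
        model = build_model(one, variants.get_variant("model 3"),
                            quad_nodes=5, fix={"sz": 0.0, "st": 0.0})
        s1 = sample_posterior(model, n_samples=120, burn_in=40, seed=8)
        model2 = build_model(one, variants.get_variant("model 3"),
                             quad_nodes=5, fix={"sz": 0.0, "st": 0.0})
        s2 = sample_posterior(model2, n_samples=120, burn_in=40, seed=8)
        assert s1.draws.equals(s2.draws)
        assert np.array_equal(s1.deviance, s2.deviance)

    def test_retained_draw_count(self, fitted_small):
        _, _, samples = fitted_small
        assert samples.n_retained == 900 - 400
        assert len(samples.deviance) == 500

    def test_invalid_sample_counts_rejected(self):
        model = GaussianMeansModel([np.zeros(5) + 1.0])
        with pytest.raises(ValueError):
            sample_posterior(model, n_samples=100, burn_in=100)

    def test_initialization_error_names_block(self):
        class Broken(GaussianMeansModel):
            def block_logp(self, bi, x):
                return -math.inf

        with pytest.raises(InitializationError, match="theta"):
            sample_posterior(Broken([np.ones(5)]), n_samples=10, burn_in=2)

    def test_conjugate_posterior_recovered(self, rng):
        # normal likelihood, flat prior: posterior is N(ybar, sigma^2/n)
        data = [rng.standard_normal(40) + 2.0, rng.standard_normal(40) - 1.0]
        model = GaussianMeansModel(data, sigma=1.0)
        s = sample_posterior(model, n_samples=8000, burn_in=2000, seed=3)
        for j, d in enumerate(data):
            post_mean = s.draws[f"theta[{j}]"].mean()
            post_sd = s.draws[f"theta[{j}]"].std()
            assert post_mean == pytest.approx(d.mean(), abs=0.05)
            assert post_sd == pytest.approx(1.0 / math.sqrt(40), rel=0.15)

    def test_draws_respect_parameter_domains(self, fitted_small):
        _, model, samples = fitted_small
        for name in model.slot_names:
            col = samples.draws[name]
            if name.startswith(("a[", "ter[", "sigma_", "sv", "st")):
                assert (col > 0).all() or name.startswith(("sv", "st"))
                assert (col >= 0).all()
            if name.startswith("z["):
                assert ((col > 0) & (col < 1)).all()

    def test_subject_level_recovery_short_chain(self, filtered_small):
        # posterior means of a, v, Ter land within 3 posterior SDs of truth
        truth, filtered, _ = filtered_small
        one = filtered[filtered.subject == 1]
        model = build_model(one, variants.get_variant("model 1"),
                            quad_nodes=5)
        s = sample_posterior(model, n_samples=1500, burn_in=600, seed=5)
        mean, sd = s.draws.mean(), s.draws.std()
        n_ok, n_tot = 0, 0
        for (i, sess, c), p in truth.params.items():
            if i != 1:
                continue
            for pname, true in (("a", p.a), ("v", p.v), ("ter", p.ter)):
                slot = f"{pname}[{i},s{sess},{c}]"
                n_tot += 1
                n_ok += abs(mean[slot] - true) <= 3.5 * sd[slot]
        assert n_ok / n_tot >= 0.8


class TestGeweke:
    def test_iid_chain_rarely_flagged(self, rng):
        zs = [geweke_diagnostic(rng.standard_normal(5000)) for _ in range(300)]
        assert np.mean(np.abs(zs) < 2) >= 0.93

    def test_trending_chain_flagged(self, rng):
        chain = rng.standard_normal(2000) + np.linspace(0, 3, 2000)
        assert abs(geweke_diagnostic(chain)) > 5

    def test_constant_chain_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert geweke_diagnostic(np.ones(500)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50))


class TestDic:
    def test_effective_parameters_equal_free_means(self, rng):
        k = 4
        data = [rng.standard_normal(30) + j for j in range(k)]
        model = GaussianMeansModel(data)
        s = sample_posterior(model, n_samples=6000, burn_in=1000, seed=2)
        dic = compute_dic(s, model)
        assert dic["pD"] == pytest.approx(k, abs=0.5)
        assert dic["dic"] == pytest.approx(
            dic["mean_deviance"] + dic["pD"])

    def test_constant_deviance_shift_moves_dic_by_same_amount(self, rng):
        data = [rng.standard_normal(30)]
        model = GaussianMeansModel(data)
        s = sample_posterior(model, n_samples=2000, burn_in=500, seed=4)
        base = compute_dic(s, model)

        class Shifted:
            def deviance(self, x):
                return model.deviance(x) + 7.0

        shifted_samples = PosteriorSamples(
            draws=s.draws, deviance=s.deviance + 7.0, burn_in=s.burn_in,
            seed=s.seed, acceptance=s.acceptance)
        moved = compute_dic(shifted_samples, Shifted())
        assert moved["dic"] == pytest.approx(base["dic"] + 7.0, abs=1e-9)

    def test_half_variance_alternative_is_positive(self, rng):
        data = [rng.standard_normal(30)]
        model = GaussianMeansModel(data)
        s = sample_posterior(model, n_samples=2000, burn_in=500, seed=4)
        assert compute_dic(s, model, method="pv")["pD"] > 0


class TestSerialization:
    def test_roundtrip_preserves_draws_and_metadata(self, fitted_small,
                                                    tmp_path):
        _, _, samples = fitted_small
        prefix = tmp_path / "post"
        samples.save(prefix)
        back = PosteriorSamples.load(prefix)
        pd.testing.assert_frame_equal(back.draws, samples.draws)
        assert np.allclose(back.deviance, samples.deviance)
        assert back.burn_in == samples.burn_in
        assert back.variant == samples.variant

    def test_priors_serializable(self):
        d = GroupPrior().to_dict()
        assert d["mu_a"][0] == 1.5 and d["sv_scale"] == 2.0
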