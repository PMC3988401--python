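"""Reusable study drivers: the simulation experiments that validate the
pipeline end to end.

Each function generates its own synthetic inputs from a seed, runs the
relevant part of the pipeline, and returns measured quantities. The
analysis scripts, the test suite and the acceptance script all call these,
so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, ddm, generate, hierarchy, posterior, variants

__all__ = [
    "likelihood_simulator_agreement",
    "recovery_study",
    "identification_study",
    "permutation_calibration",
    "toy_pd_study",
]

#: parameter sets spanning the range relevant for motion discrimination on
#: the s = 1 scale: slow/careful to fast/liberal, with and without
#: trial-to-trial variability.
AGREEMENT_SETS = (
    ddm.DDMParams(a=1.5, v=2.0, z=0.5, ter=0.30),
    ddm.DDMParams(a=2.0, v=1.0, z=0.4, ter=0.35),
    ddm.DDMParams(a=1.0, v=3.0, z=0.55, ter=0.25),
    ddm.DDMParams(a=1.2, v=2.5, z=0.45, ter=0.35, sv=1.0, sz=0.05, st=0.10),
    ddm.DDMParams(a=1.8, v=1.5, z=0.5, ter=0.40, sv=1.0, sz=0.05, st=0.10),
)


def likelihood_simulator_agreement(seed=0, param_sets=AGREEMENT_SETS,
                                   n_trials=1_000_000, dt=1e-3,
                                   bin_width=0.1, horizon=3.0):
    """Chi-square goodness of fit of simulated trials to the exact density.

    For each parameter set, n_trials trials are simulated and binned by
    (boundary, RT); expected bin probabilities come from integrating
    exp(trial_loglik) over each bin. Returns one row per set with the
    chi-square statistic, df and p-value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    rows = []
    edges = np.arange(0.0, horizon + 1e-9, bin_width)
    grid = np.linspace(1e-4, horizon, int(horizon / 5e-4) + 1)
    for p in param_sets:
        rt, up, out = ddm.simulate_arrays(
            p, n_trials, max_t=horizon * 2, dt=dt,
            seed=int(rng.integers(2 ** 31)))
        obs, probs = [], []
        for boundary, sel in (("upper", up & ~out), ("lower", (~up) & ~out)):
            dens = np.array([ddm.trial_density(t, boundary, p) for t in grid])
            cdf = np.concatenate(
                [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
            pe = np.interp(edges, grid, cdf)
            probs.append(np.diff(pe))
            cnt, _ = np.histogram(rt[sel], bins=edges)
            obs.append(cnt)
        obs = np.concatenate(obs).astype(float)
        probs = np.concatenate(probs)
        keep = probs * n_trials >= 5  # merge sparse bins into the remainder
        o = np.append(obs[keep], n_trials - obs[keep].sum())
        e = np.append(probs[keep] * n_trials, n_trials * (1 - probs[keep].sum()))
        chi2 = float(((o - e) ** 2 / e).sum())
        df = len(o) - 1
        rows.append({"a": p.a, "v": p.v, "z": p.z, "sv": p.sv,
                     "chi2": chi2, "df": df,
                     "pvalue": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def recovery_study(seed=0, n_subjects=2, n_sessions=2, n_samples=3000,
                   burn_in=1000, quad_nodes=5, dt=1e-3):
    """Generate-and-refit parameter recovery under the full variant.

    Fits the all-free model to a synthetic experiment and scores, over all
    subject-level a / v / Ter slots, how many posterior means fall within 3
    posterior SDs of the generating truth, plus the truth/estimate
    correlation across cells.
    """
    design = generate.ExperimentDesign(n_subjects=n_subjects,
                                       n_sessions=n_sessions)
    truth = generate.sample_ground_truth(design, seed=seed)
    trials = generate.generate_experiment(design, truth, seed=seed, dt=dt)
    filtered, discarded = behavior.filter_trials(trials)
    model = hierarchy.build_model(filtered, variants.get_variant("model 1"),
                                  quad_nodes=quad_nodes)
    samples = hierarchy.sample_posterior(model, n_samples=n_samples,
                                         burn_in=burn_in, seed=seed)
    mean = samples.draws.mean(axis=0)
    sd = samples.draws.std(axis=0, ddof=0)
    rows = []
    for (i, s, c), p in truth.params.items():
        for pname, true in (("a", p.a), ("v", p.v), ("ter", p.ter)):
            g = c if getattr(model.variant, f"free_{pname}") else "both"
            slot = f"{pname}[{i},s{s},{g}]"
            z = (mean[slot] - true) / sd[slot]
            rows.append({"slot": slot, "param": pname, "truth": true,
                         "post_mean": float(mean[slot]),
                         "post_sd": float(sd[slot]), "zscore": float(z)})
    tab = pd.DataFrame(rows).drop_duplicates("slot")
    frac = float((tab.zscore.abs() <= 3).mean())
    r = float(np.corrcoef(tab.truth, tab.post_mean)[0, 1])
    return {"table": tab, "frac_within_3sd": frac, "truth_corr": r,
            "samples": samples, "model": model, "truth": truth,
            "discarded_fraction": discarded}


def _identification_config(effects):
    if effects == "all":
        return generate.GeneratorConfig(sz=0.0, st=0.0)
    if effects == "a_only":
        return generate.GeneratorConfig(sz=0.0, st=0.0, v_cond_effect0=0.0,
                                        ter_cond_effect0=0.0)
    raise ValueError("effects must be 'all' or 'a_only'")


def identification_study(seed=0, n_reps=10, effects="all", n_subjects=3,
                         n_samples=1200, burn_in=400, dt=1e-3):
    """Which variant wins the DIC comparison on data with known effects.

    Reduced scale: n_subjects x 1 session x 672 trials per replicate, with
    the uniform variability components switched off in both the generator
    and the fitted models (sv remains free), so each replicate fits all
    seven variants quickly. Returns one row per replicate with the winning
    label and each variant's DIC rank.
    """
    cfg = _identification_config(effects)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    design = generate.ExperimentDesign(n_subjects=n_subjects, n_sessions=1)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        truth = generate.sample_ground_truth(design, cfg, seed=rep_seed)
        trials = generate.generate_experiment(design, truth, seed=rep_seed,
                                              dt=dt)
        filtered, _ = behavior.filter_trials(trials)
        fits = []
        for k, spec in enumerate(variants.enumerate_variants()):
            model = hierarchy.build_model(filtered, spec,
                                          fix={"sz": 0.0, "st": 0.0})
            samples = hierarchy.sample_posterior(
                model, n_samples=n_samples, burn_in=burn_in,
                seed=(rep_seed + k) % (2 ** 31))
            fits.append({"variant": spec,
                         **hierarchy.compute_dic(samples, model)})
        tab = variants.compare_models(fits)
        row = {"rep": rep, "winner": tab.iloc[0]["label"]}
        for rank, lbl in enumerate(tab.label):
            row[f"rank_{lbl.replace(' ', '_')}"] = rank
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_calibration(seed=0, n_tests=2000, n_perm=2000, n_blocks=36,
                            alpha=0.05):
    """Type-I error of the one-sided randomization test under the null."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    rej = 0
    for i in range(n_tests):
        g1 = rng.standard_normal(n_blocks)
        g2 = rng.standard_normal(n_blocks)
        res = behavior.randomization_test(
            g1, g2, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rej += res["p"] < alpha
    return rej / n_tests


def toy_pd_study(seed=0, k=5, n_obs=50, n_samples=6000, burn_in=1000):
    """Effective number of parameters on the conjugate reference model.

    With k free means and flat priors, Spiegelhalter's pD should equal k.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    data = [rng.standard_normal(n_obs) + j for j in range(k)]
    model = hierarchy.GaussianMeansModel(data, sigma=1.0)
    samples = hierarchy.sample_posterior(model, n_samples=n_samples,
                                         burn_in=burn_in, seed=seed)
    return hierarchy.compute_dic(samples, model)
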