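"""Posterior predictive simulation, posterior summaries, and Bayesian
hypothesis probabilities.

The predictive check mirrors the fitting pipeline: whole rows of the draw
matrix are sampled per participant (preserving posterior correlations),
each sampled parameter set simulates exactly the observed number of trials
per design cell, and the per-draw signed-RT histograms (errors on the
negative axis, correct responses on the positive) are averaged into the
model prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ddm
from ._kernels import simulate_cell
from .hierarchy import CONDITIONS, PosteriorSamples

__all__ = [
    "posterior_predictive",
    "predictive_histograms",
    "hypothesis_probability",
    "summarize_posterior",
    "PredictiveDistribution",
    "DEFAULT_BINS",
]

#: signed-RT histogram bins: 0.1 s width over the 2.4 s response window.
DEFAULT_BINS = np.round(np.arange(-2.4, 2.4001, 0.1), 10)


def posterior_predictive(samples: PosteriorSamples, data: pd.DataFrame,
                         model, n_draws: int = 500, seed: int = 0,
                         dt: float = 1e-3) -> pd.DataFrame:
    """Simulate the experiment from joint posterior draws.

    For each participant, n_draws rows of the draw matrix are sampled; each
    simulates the same number of trials per session x condition cell as
    observed. Returns a long table with a `draw` column; rt_ms is NaN for
    simulated timeouts.
    """
    if n_draws > samples.n_retained:
        raise ValueError(
            f"n_draws={n_draws} exceeds the {samples.n_retained} retained draws")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    if "valid" in data.columns:
        data = data[data["valid"]]
    counts = data.groupby(["subject", "session", "condition"],
                          observed=True).size()
    draws_mat = samples.draws
    rows = []
    for subj in model.subjects:
        take = rng.choice(samples.n_retained, size=n_draws, replace=False)
        for d_i, row_idx in enumerate(take):
            x = draws_mat.iloc[int(row_idx)].to_numpy()
            cellpars = model.point(x)
            for sess in model.sessions:
                for cond in CONDITIONS:
                    n_cell = int(counts.get((subj, sess, cond), 0))
                    if n_cell == 0:
                        continue
                    p = cellpars[(subj, sess, cond)]
                    # drift sign balanced as in the task (50/50 stimuli)
                    n_r = n_cell - n_cell // 2
                    for sign, n_side in ((1.0, n_r), (-1.0, n_cell - n_r)):
                        if n_side == 0:
                            continue
                        rt, up, out = simulate_cell(
                            n_side, p.a, p.v * sign, p.z, p.ter,
                            p.sv, p.sz, p.st, dt, 2.4,
                            int(rng.integers(2 ** 31)))
                        for t in range(n_side):
                            correct = bool(up[t]) == (sign > 0)
                            rows.append({
                                "draw": d_i, "subject": subj,
                                "session": sess, "condition": cond,
                                "correct": correct and not out[t],
                                "rt_ms": np.nan if out[t] else rt[t] * 1000.0,
                                "timed_out": bool(out[t]),
                            })
    return pd.DataFrame(rows)


@dataclass
class PredictiveDistribution:
    """Signed-RT histograms per session x condition cell, pooled across
    participants: observed density and the draw-averaged predicted curve."""

    bin_edges: np.ndarray
    observed: dict     # (session, condition) -> density array
    predicted: dict    # (session, condition) -> density array

    def frame(self) -> pd.DataFrame:
        mids = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        rows = []
        for key in self.observed:
            for m, o, p in zip(mids, self.observed[key], self.predicted[key]):
                rows.append({"session": key[0], "condition": key[1],
                             "bin_mid_s": m, "observed": o, "predicted": p})
        return pd.DataFrame(rows)


def _signed_hist(rt_ms, correct, edges):
    signed = np.where(correct, 1.0, -1.0) * rt_ms / 1000.0
    h, _ = np.histogram(signed, bins=edges)
    total = h.sum()
    if total == 0:
        return None
    return h / (total * np.diff(edges))


def predictive_histograms(observed: pd.DataFrame, ensemble: pd.DataFrame,
                          bins=DEFAULT_BINS) -> PredictiveDistribution:
    """Observed vs draw-averaged predicted signed-RT densities.

    Error responses fall on the negative axis, correct ones on the positive;
    each histogram integrates to 1 so the positive-axis area equals the
    proportion correct. Cells with no observed trials are skipped with a
    warning.
    """
    edges = np.asarray(bins, dtype=float)
    if "valid" in observed.columns:
        observed = observed[observed["valid"]]
    ens = ensemble[~ensemble["rt_ms"].isna()]
    obs_out, pred_out = {}, {}
    for (sess, cond), sub in observed.groupby(["session", "condition"],
                                              observed=True):
        sub = sub[~sub["rt_ms"].isna()]
        h = _signed_hist(sub["rt_ms"].to_numpy(),
                         sub["correct"].to_numpy(bool), edges)
        if h is None:
            warnings.warn(f"empty observed cell (session {sess}, {cond}); skipped")
            continue
        cell = ens[(ens["session"] == sess) & (ens["condition"] == cond)]
        per_draw = []
        for _, d in cell.groupby("draw"):
            hd = _signed_hist(d["rt_ms"].to_numpy(),
                              d["correct"].to_numpy(bool), edges)
            if hd is not None:
                per_draw.append(hd)
        if not per_draw:
            warnings.warn(f"no predictive draws for (session {sess}, {cond})")
            continue
        obs_out[(sess, cond)] = h
        pred_out[(sess, cond)] = np.mean(per_draw, axis=0)
    return PredictiveDistribution(bin_edges=edges, observed=obs_out,
                                  predicted=pred_out)


def hypothesis_probability(samples: PosteriorSamples, contrast) -> float:
    """Posterior probability that a signed combination of group-level slots
    exceeds zero: P_P|D(contrast > 0).

    `contrast` is either a dict {slot name: coefficient} or a pair
    (slot_plus, slot_minus) meaning slot_plus - slot_minus. Ties at exactly
    zero count as not exceeding (strict inequality); a degenerate contrast
    (identically zero) returns 0 with a warning.
    """
    if isinstance(contrast, (tuple, list)) and len(contrast) == 2 \
            and all(isinstance(c, str) for c in contrast):
        pairs = [(contrast[0], 1.0), (contrast[1], -1.0)]
    else:
        pairs = list(contrast.items())
    vals = np.zeros(samples.n_retained)
    for name, coef in pairs:
        if name not in samples.draws.columns:
            raise KeyError(f"unknown parameter slot {name!r}")
        vals += coef * samples.draws[name].to_numpy()
    if np.all(vals == 0):
        warnings.warn("degenerate contrast: identically zero difference")
        return 0.0
    return float(np.mean(vals > 0))


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean and SD per parameter slot (draw-order invariant)."""
    if samples.n_retained < 2:
        raise ValueError("need at least 2 retained draws")
    return pd.DataFrame({
        "slot": samples.draws.columns,
        "mean": samples.draws.mean(axis=0).to_numpy(),
        "sd": samples.draws.std(axis=0, ddof=0).to_numpy(),
    })
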