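"""Hierarchical Bayesian estimation of the drift-diffusion model.

Subject-level parameters (a, v, Ter per session x instruction condition, z
per session) are modelled as draws from session/condition-specific group
distributions; the trial-to-trial variability parameters (sv, sz, st) are
single group-level scalars shared by all subjects, sessions and conditions.
Which of a, v, Ter may differ between the speed and accuracy conditions is
controlled by a :class:`~satddm.variants.VariantSpec`.

Sampling is adaptive Metropolis-within-Gibbs over parameter blocks:

* per subject x session, a joint random-walk update of that cell pair's
  a / v / Ter slots (their posteriors are strongly correlated);
* per subject x session, a scalar update of the shared starting point z;
* one joint update of the free variability parameters;
* per group, a joint update of (group mean, group SD).

Proposal scales are adapted toward target acceptance rates only during
burn-in and frozen afterwards, preserving detailed balance of the retained
draws. Chains are exactly reproducible from (data, variant, priors, seed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddm
from ._kernels import cell_loglik, cell_loglik_censored
from .variants import VariantSpec

__all__ = [
    "GroupPrior",
    "PosteriorSamples",
    "HierarchicalDDM",
    "GaussianMeansModel",
    "build_model",
    "sample_posterior",
    "geweke_diagnostic",
    "compute_dic",
    "ez_init",
]

CONDITIONS = ("accuracy", "speed")

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(x, mu, sd):
    u = (x - mu) / sd
    return -0.5 * u * u - math.log(sd) - _LOG_SQRT_2PI


def _log_phi_bar(x):
    """log P(Z > x) for standard normal Z (used by truncation constants)."""
    return math.log(max(0.5 * math.erfc(x / _SQRT2), 1e-300))


def _trunc_norm_logpdf(x, mu, sd, lo=0.0, hi=math.inf):
    """Normal(mu, sd) truncated to (lo, hi)."""
    if not (lo < x < hi):
        return -math.inf
    logz = _log_phi_bar((lo - mu) / sd)
    if math.isfinite(hi):
        logz = math.log(max(
            math.exp(logz) - math.exp(_log_phi_bar((hi - mu) / sd)), 1e-300))
    return _norm_logpdf(x, mu, sd) - logz


def _half_norm_logpdf(x, scale):
    if x < 0:
        return -math.inf
    return _norm_logpdf(x, 0.0, scale) + math.log(2.0)


def _logit(p):
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class GroupPrior:
    """Hyperpriors of the hierarchy (weakly informative on the s = 1 scale).

    Group means: a ~ Normal(1.5, 1) truncated to (0, 5]; v ~ Normal(2, 3);
    Ter ~ Normal(0.4, 0.25) truncated to (0, 1]; z on the logit scale with a
    Normal(0, 1) mean. Group SDs ~ Half-Normal(0.5). Variability:
    sv ~ Half-Normal(2); sz ~ Uniform(0, sz_max) subject to the joint
    constraint that every z +- sz/2 stays inside (0, 1); st ~ Half-Normal(0.3)
    subject to Ter - st/2 >= 0 for every subject-level Ter.
    """

    mu_a: tuple = (1.5, 1.0, 0.0, 5.0)     # (mean, sd, lo, hi)
    mu_v: tuple = (2.0, 3.0)
    mu_ter: tuple = (0.4, 0.25, 0.0, 1.0)
    mu_z_logit: tuple = (0.0, 1.0)
    sigma_scale: float = 0.5
    sv_scale: float = 2.0
    sz_max: float = 0.5
    st_scale: float = 0.3

    def to_dict(self):
        return {
            "mu_a": list(self.mu_a), "mu_v": list(self.mu_v),
            "mu_ter": list(self.mu_ter), "mu_z_logit": list(self.mu_z_logit),
            "sigma_scale": self.sigma_scale, "sv_scale": self.sv_scale,
            "sz_max": self.sz_max, "st_scale": self.st_scale,
        }


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus chain metadata."""

    draws: pd.DataFrame          # one column per slot, one row per retained draw
    deviance: np.ndarray         # -2 log-likelihood per retained draw
    burn_in: int
    seed: int
    acceptance: dict             # block label -> acceptance rate
    variant: str = ""
    priors: dict = field(default_factory=dict)

    @property
    def n_retained(self):
        return len(self.draws)

    def save(self, prefix):
        """Write draws as flat CSV plus a JSON metadata sidecar."""
        self.draws.assign(deviance=self.deviance).to_csv(
            f"{prefix}.csv", index=False)
        meta = {
            "burn_in": self.burn_in, "seed": self.seed,
            "variant": self.variant, "priors": self.priors,
            "acceptance": self.acceptance,
        }
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, prefix):
        df = pd.read_csv(f"{prefix}.csv")
        with open(f"{prefix}.meta.json") as fh:
            meta = json.load(fh)
        dev = df.pop("deviance").to_numpy()
        return cls(draws=df, deviance=dev, burn_in=meta["burn_in"],
                   seed=meta["seed"], acceptance=meta["acceptance"],
                   variant=meta["variant"], priors=meta["priors"])


class InitializationError(RuntimeError):
    pass


def ez_init(p_correct, mean_rt, var_rt, n=None):
    """Closed-form moment-based starting values (a, v, Ter) on the s = 1 scale.

    Derived from accuracy, RT mean and RT variance of correct+error trials;
    edge-corrected and clamped to a plausible range, since these are only
    chain starting points, not estimates.
    """
    pc = min(max(p_correct, 0.55), 0.995)
    if n:
        pc = min(pc, 1.0 - 1.0 / (2.0 * n))
    vr = max(var_rt, 1e-4)
    L = _logit(pc)
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vr
    v = max(min(abs(x) ** 0.25, 5.0), 0.3)
    a = max(min(L / v, 4.0), 0.5)
    ev = math.exp(-v * a)
    mdt = (a / (2.0 * v)) * (1.0 - ev) / (1.0 + ev)
    ter = min(max(mean_rt - mdt, 0.06), 1.0)
    return a, v, ter


class _Block:
    __slots__ = ("label", "idx", "scales", "log_scale", "target",
                 "n_prop", "n_acc", "cells", "kind", "meta", "repeats")

    def __init__(self, label, idx, scales, target, kind, cells=(), meta=None,
                 repeats=1):
        self.label = label
        self.idx = np.asarray(idx, dtype=np.intp)
        self.scales = np.asarray(scales, dtype=float)
        self.log_scale = 0.0
        self.target = target
        self.n_prop = 0
        self.n_acc = 0
        self.cells = tuple(cells)
        self.kind = kind
        self.meta = meta or {}
        self.repeats = repeats


class HierarchicalDDM:
    """Joint log-posterior over all parameter slots defined by the variant.

    Exposes the block/conditional interface consumed by
    :func:`sample_posterior`, plus ``deviance(x)`` for DIC.
    """

    def __init__(self, data, variant, priors=None, eps=ddm.DEFAULT_EPS,
                 quad_nodes=ddm.DEFAULT_QUAD_NODES, fix=None,
                 censor_s=2.2):
        """`fix` optionally pins variability parameters, e.g. {"sz": 0, "st": 0}
        (a reduced model used for fast fits when the generating process has no
        uniform variability).

        `censor_s` conditions each trial's likelihood on a response within
        that many seconds, matching the preprocessing that removes overtime
        responses; pass None for the plain (uncorrected) likelihood.
        """
        self.variant = variant
        self.priors = priors or GroupPrior()
        self.eps = eps
        self.gl_x, self.gl_w = ddm.gauss_legendre(quad_nodes)
        self.gh_x, self.gh_w = np.polynomial.hermite.hermgauss(15)
        self.censor_s = censor_s
        self.fix = dict(fix or {})

        df = data.copy()
        if "valid" in df.columns:
            df = df[df["valid"]]
        self.subjects = sorted(df["subject"].unique().tolist())
        self.sessions = sorted(df["session"].unique().tolist())

        # design cells with trial arrays (stimulus-coded drift sign)
        self.cells = []        # (subj, sess, cond)
        self.cell_data = []    # (rt_s, upper, sign)
        for subj in self.subjects:
            for sess in self.sessions:
                for cond in CONDITIONS:
                    sub = df[(df.subject == subj) & (df.session == sess)
                             & (df.condition == cond)]
                    if len(sub) == 0:
                        raise ValueError(
                            f"no trials for subject={subj} session={sess} "
                            f"condition={cond}; every design cell must be populated")
                    rt = (sub["rt_ms"].to_numpy(float) / 1000.0)
                    upper = (sub["response"] == "right").to_numpy(bool)
                    sign = np.where(
                        sub["direction_deg"].isin((30, 330)), 1.0, -1.0)
                    self.cell_data.append((np.ascontiguousarray(rt),
                                           np.ascontiguousarray(upper),
                                           np.ascontiguousarray(sign)))
                    self.cells.append((subj, sess, cond))
        self._build_index()
        self._build_blocks()
        self._init = self._initial_values(df)

    # ----- parameter index ------------------------------------------------
    def groups_for(self, param):
        free = getattr(self.variant, f"free_{param}")
        return CONDITIONS if free else ("both",)

    def group_of(self, param, cond):
        return cond if getattr(self.variant, f"free_{param}") else "both"

    def _build_index(self):
        names = []
        self.slot = {}

        def add(name):
            self.slot[name] = len(names)
            names.append(name)

        for p in ("a", "v", "ter"):
            for s in self.sessions:
                for g in self.groups_for(p):
                    add(f"mu_{p}[s{s},{g}]")
                    add(f"sigma_{p}[s{s},{g}]")
        for s in self.sessions:
            add(f"mu_z[s{s}]")
            add(f"sigma_z[s{s}]")
        for p in ("a", "v", "ter"):
            for i in self.subjects:
                for s in self.sessions:
                    for g in self.groups_for(p):
                        add(f"{p}[{i},s{s},{g}]")
        for i in self.subjects:
            for s in self.sessions:
                add(f"z[{i},s{s}]")
        for p in ("sv", "sz", "st"):
            if p not in self.fix:
                add(p)
        self.slot_names = names
        self.n_slots = len(names)
        # subspace for global adaptive-covariance moves: the subject-level
        # and variability slots, whose joint posterior carries the strongly
        # correlated ridges; group-level slots mix well on their own. The
        # ridge is driven by free starting-point variability, so models with
        # sz pinned skip the global moves entirely.
        if "sz" in self.fix:
            self.global_slot_idx = np.array([], dtype=np.intp)
        else:
            self.global_slot_idx = np.array(
                [j for j, n in enumerate(names)
                 if not n.startswith(("mu_", "sigma_"))], dtype=np.intp)

        # per-cell slot indices (a, v, z, ter)
        self.cell_slots = []
        for (i, s, c) in self.cells:
            self.cell_slots.append((
                self.slot[f"a[{i},s{s},{self.group_of('a', c)}]"],
                self.slot[f"v[{i},s{s},{self.group_of('v', c)}]"],
                self.slot[f"z[{i},s{s}]"],
                self.slot[f"ter[{i},s{s},{self.group_of('ter', c)}]"],
            ))

    def _build_blocks(self):
        base = {"a": 0.08, "v": 0.15, "ter": 0.015, "z": 0.02,
                "sv": 0.08, "sz": 0.008, "st": 0.012,
                "mu": {"a": 0.08, "v": 0.15, "ter": 0.015, "z": 0.08},
                "sigma": 0.05}
        self.blocks = []
        cell_index = {key: k for k, key in enumerate(self.cells)}
        free = [p for p in ("a", "v", "ter") if getattr(self.variant, f"free_{p}")]
        shared = [p for p in ("a", "v", "ter") if p not in free]
        for i in self.subjects:
            for s in self.sessions:
                both = tuple(cell_index[(i, s, c)] for c in CONDITIONS)
                # condition-specific slots update against their own cell only
                for c in CONDITIONS:
                    if not free:
                        break
                    idx = [self.slot[f"{p}[{i},s{s},{c}]"] for p in free]
                    self.blocks.append(_Block(
                        f"avt[{i},s{s},{c}]", idx, [base[p] for p in free],
                        0.44 if len(idx) == 1 else 0.3, "avt",
                        (cell_index[(i, s, c)],)))
                if shared:
                    idx = [self.slot[f"{p}[{i},s{s},both]"] for p in shared]
                    self.blocks.append(_Block(
                        f"avt[{i},s{s},both]", idx, [base[p] for p in shared],
                        0.44 if len(idx) == 1 else 0.3, "avt", both))
                self.blocks.append(_Block(
                    f"z[{i},s{s}]", [self.slot[f"z[{i},s{s}]"]], [base["z"]],
                    0.44, "z", both, meta={"subj": i, "sess": s}))
        var_idx = [self.slot[p] for p in ("sv", "sz", "st") if p not in self.fix]
        if var_idx:
            scales = [base[p] for p in ("sv", "sz", "st") if p not in self.fix]
            self.blocks.append(_Block(
                "variability", var_idx, scales,
                0.3 if len(var_idx) > 1 else 0.44, "var",
                tuple(range(len(self.cells))),
                repeats=3 if "sz" not in self.fix else 1))
        for p in ("a", "v", "ter", "z"):
            for s in self.sessions:
                for g in (self.groups_for(p) if p != "z" else ("",)):
                    tag = f"[s{s},{g}]" if p != "z" else f"[s{s}]"
                    idx = [self.slot[f"mu_{p}{tag}"], self.slot[f"sigma_{p}{tag}"]]
                    self.blocks.append(_Block(
                        f"group_{p}{tag}", idx, [base["mu"][p], base["sigma"]],
                        0.3, "group", (),
                        meta={"param": p, "sess": s, "group": g}, repeats=2))

    # ----- initial values -------------------------------------------------
    def _initial_values(self, df):
        x = np.zeros(self.n_slots)
        cellinit = {}
        for k, (i, s, c) in enumerate(self.cells):
            rt, upper, sign = self.cell_data[k]
            correct = (upper == (sign > 0))
            a0, v0, t0 = ez_init(correct.mean(), rt.mean(), rt.var(), len(rt))
            cellinit[(i, s, c)] = (a0, v0, t0)
        for p_i, p in enumerate(("a", "v", "ter")):
            for i in self.subjects:
                for s in self.sessions:
                    for g in self.groups_for(p):
                        conds = CONDITIONS if g == "both" else (g,)
                        val = float(np.mean([cellinit[(i, s, c)][p_i]
                                             for c in conds]))
                        x[self.slot[f"{p}[{i},s{s},{g}]"]] = val
        for p in ("a", "v", "ter"):
            for s in self.sessions:
                for g in self.groups_for(p):
                    vals = [x[self.slot[f"{p}[{i},s{s},{g}]"]]
                            for i in self.subjects]
                    x[self.slot[f"mu_{p}[s{s},{g}]"]] = float(np.mean(vals))
                    x[self.slot[f"sigma_{p}[s{s},{g}]"]] = float(
                        max(np.std(vals), 0.08))
        for s in self.sessions:
            x[self.slot[f"mu_z[s{s}]"]] = 0.0
            x[self.slot[f"sigma_z[s{s}]"]] = 0.3
        for i in self.subjects:
            for s in self.sessions:
                x[self.slot[f"z[{i},s{s}]"]] = 0.5
        defaults = {"sv": 0.5, "sz": 0.02, "st": 0.05}
        for p in ("sv", "sz", "st"):
            if p not in self.fix:
                x[self.slot[p]] = defaults[p]
        return x

    def init_state(self, refine=True):
        """Chain starting point: moment-based estimates, optionally refined
        to approximate conditional posterior modes.

        Refinement runs a short blockwise Nelder-Mead pass over the
        subject-level and variability blocks (group-level slots are then
        re-derived from the refined subject values). Starting near the mode
        removes the long burn-in transient of cold-started chains.
        """
        x = self._init.copy()
        if not refine:
            return x
        from scipy.optimize import minimize

        subj_blocks = [bi for bi, b in enumerate(self.blocks)
                       if b.kind in ("avt", "z")]
        var_blocks = [bi for bi, b in enumerate(self.blocks)
                      if b.kind == "var"]
        for _sweep in range(2):
            for bi in subj_blocks + var_blocks:
                b = self.blocks[bi]

                def neg(vals, bi=bi, b=b):
                    y = x.copy()
                    y[b.idx] = vals
                    lp = self.block_logp(bi, y)
                    return -lp if math.isfinite(lp) else 1e12

                res = minimize(neg, x[b.idx], method="Nelder-Mead",
                               options={"maxiter": 60 * len(b.idx),
                                        "xatol": 1e-3, "fatol": 1e-3})
                if math.isfinite(res.fun) and res.fun < 1e11:
                    x[b.idx] = res.x
        # group-level slots consistent with the refined subject values
        for p in ("a", "v", "ter"):
            for s in self.sessions:
                for g in self.groups_for(p):
                    vals = [x[self.slot[f"{p}[{i},s{s},{g}]"]]
                            for i in self.subjects]
                    x[self.slot[f"mu_{p}[s{s},{g}]"]] = float(np.mean(vals))
                    x[self.slot[f"sigma_{p}[s{s},{g}]"]] = float(
                        max(np.std(vals), 0.05))
        for s in self.sessions:
            zv = [x[self.slot[f"z[{i},s{s}]"]] for i in self.subjects]
            lz = [_logit(min(max(z, 1e-4), 1 - 1e-4)) for z in zv]
            x[self.slot[f"mu_z[s{s}]"]] = float(np.mean(lz))
            x[self.slot[f"sigma_z[s{s}]"]] = float(max(np.std(lz), 0.1))
        return x

    # ----- log-posterior pieces -------------------------------------------
    def _var(self, x, p):
        return self.fix[p] if p in self.fix else x[self.slot[p]]

    def _cell_loglik(self, x, k):
        ia, iv, iz, it = self.cell_slots[k]
        rt, upper, sign = self.cell_data[k]
        a, v, z, ter = x[ia], x[iv], x[iz], x[it]
        sv = self._var(x, "sv")
        sz = self._var(x, "sz")
        st = self._var(x, "st")
        if not (a > 0 and 0 < z - sz / 2 and z + sz / 2 < 1
                and ter >= st / 2 and sv >= 0):
            return -math.inf
        if self.censor_s:
            return cell_loglik_censored(
                rt, upper, sign, a, v, z, ter, sv, sz, st,
                self.gl_x, self.gl_w, self.gh_x, self.gh_w,
                self.censor_s, self.eps, ddm.LOGLIK_FLOOR)
        return cell_loglik(rt, upper, sign, a, v, z, ter, sv, sz, st,
                           self.gl_x, self.gl_w, self.eps, ddm.LOGLIK_FLOOR)

    def _subject_prior(self, x, p, i, s, g):
        val = x[self.slot[f"{p}[{i},s{s},{g}]"]]
        tag = f"[s{s},{g}]"
        mu = x[self.slot[f"mu_{p}{tag}"]]
        sd = x[self.slot[f"sigma_{p}{tag}"]]
        if sd <= 0:
            return -math.inf
        if p == "v":
            return _norm_logpdf(val, mu, sd)
        return _trunc_norm_logpdf(val, mu, sd, 0.0)

    def _z_prior(self, x, i, s):
        z = x[self.slot[f"z[{i},s{s}]"]]
        if not (0 < z < 1):
            return -math.inf
        mu = x[self.slot[f"mu_z[s{s}]"]]
        sd = x[self.slot[f"sigma_z[s{s}]"]]
        if sd <= 0:
            return -math.inf
        return _norm_logpdf(_logit(z), mu, sd) - math.log(z * (1.0 - z))

    def _hyper_prior(self, x, p, s, g):
        pr = self.priors
        tag = f"[s{s},{g}]" if p != "z" else f"[s{s}]"
        mu = x[self.slot[f"mu_{p}{tag}"]]
        sd = x[self.slot[f"sigma_{p}{tag}"]]
        if p == "a":
            lp = _trunc_norm_logpdf(mu, pr.mu_a[0], pr.mu_a[1],
                                    pr.mu_a[2], pr.mu_a[3])
        elif p == "v":
            lp = _norm_logpdf(mu, pr.mu_v[0], pr.mu_v[1])
        elif p == "ter":
            lp = _trunc_norm_logpdf(mu, pr.mu_ter[0], pr.mu_ter[1],
                                    pr.mu_ter[2], pr.mu_ter[3])
        else:
            lp = _norm_logpdf(mu, pr.mu_z_logit[0], pr.mu_z_logit[1])
        return lp + _half_norm_logpdf(sd, pr.sigma_scale)

    def _var_prior(self, x):
        pr = self.priors
        lp = 0.0
        if "sv" not in self.fix:
            lp += _half_norm_logpdf(x[self.slot["sv"]], pr.sv_scale)
        if "sz" not in self.fix:
            sz = x[self.slot["sz"]]
            if not (0 <= sz <= pr.sz_max):
                return -math.inf
            lp += -math.log(pr.sz_max)
        if "st" not in self.fix:
            st = x[self.slot["st"]]
            if st < 0:
                return -math.inf
            lp += _half_norm_logpdf(st, pr.st_scale)
        return lp

    def _block_priors(self, bi, x):
        """Prior/hierarchy terms of block bi (everything except trial
        likelihoods)."""
        b = self.blocks[bi]
        lp = 0.0
        if b.kind == "avt":
            i, s = self.cells[b.cells[0]][0], self.cells[b.cells[0]][1]
            for p in ("a", "v", "ter"):
                for g in self.groups_for(p):
                    lp += self._subject_prior(x, p, i, s, g)
        elif b.kind == "z":
            lp = self._z_prior(x, b.meta["subj"], b.meta["sess"])
        elif b.kind == "var":
            lp = self._var_prior(x)
            if not math.isfinite(lp):
                return -math.inf
        elif b.kind == "group":
            p, s, g = b.meta["param"], b.meta["sess"], b.meta["group"]
            lp = self._hyper_prior(x, p, s, g)
            if not math.isfinite(lp):
                return -math.inf
            if p == "z":
                for i in self.subjects:
                    lp += self._z_prior(x, i, s)
            else:
                for i in self.subjects:
                    lp += self._subject_prior(x, p, i, s, g)
            return lp
        return lp

    def block_logp(self, bi, x):
        """All log-posterior terms that depend on block bi's slots."""
        lp = self._block_priors(bi, x)
        if not math.isfinite(lp):
            return -math.inf
        for k in self.blocks[bi].cells:
            lp += self._cell_loglik(x, k)
            if not math.isfinite(lp):
                return -math.inf
        return lp

    # cached-conditional protocol used by the sampler: cell log-likelihoods
    # are cached and updated only when a block's proposal is accepted
    def begin(self, x):
        self._cell_ll = np.array(
            [self._cell_loglik(x, k) for k in range(len(self.cells))])

    def block_logp_current(self, bi, x):
        lp = self._block_priors(bi, x)
        if not math.isfinite(lp):
            return -math.inf
        return lp + float(np.sum(self._cell_ll[list(self.blocks[bi].cells)]))

    def block_logp_prop(self, bi, x):
        lp = self._block_priors(bi, x)
        if not math.isfinite(lp):
            return -math.inf, None
        new_lls = {}
        for k in self.blocks[bi].cells:
            ll = self._cell_loglik(x, k)
            if not math.isfinite(ll):
                return -math.inf, None
            new_lls[k] = ll
            lp += ll
        return lp, new_lls

    def commit(self, bi, x, aux):
        if aux:
            for k, ll in aux.items():
                self._cell_ll[k] = ll

    def deviance_current(self):
        return -2.0 * float(np.sum(self._cell_ll))

    def _all_priors(self, x):
        lp = 0.0
        for p in ("a", "v", "ter"):
            for s in self.sessions:
                for g in self.groups_for(p):
                    lp += self._hyper_prior(x, p, s, g)
                    if not math.isfinite(lp):
                        return -math.inf
                    for i in self.subjects:
                        lp += self._subject_prior(x, p, i, s, g)
        for s in self.sessions:
            lp += self._hyper_prior(x, "z", s, "")
            for i in self.subjects:
                lp += self._z_prior(x, i, s)
        lp += self._var_prior(x)
        return lp

    def full_logp_current(self, x):
        lp = self._all_priors(x)
        if not math.isfinite(lp):
            return -math.inf
        return lp + float(np.sum(self._cell_ll))

    def full_logp_prop(self, x):
        lp = self._all_priors(x)
        if not math.isfinite(lp):
            return -math.inf, None
        lls = np.empty(len(self.cells))
        for k in range(len(self.cells)):
            lls[k] = self._cell_loglik(x, k)
            if not math.isfinite(lls[k]):
                return -math.inf, None
        return lp + float(lls.sum()), lls

    def commit_full(self, aux):
        self._cell_ll = aux

    def loglik(self, x):
        return sum(self._cell_loglik(x, k) for k in range(len(self.cells)))

    def deviance(self, x):
        return -2.0 * self.loglik(x)

    def log_posterior(self, x):
        """Full joint log-posterior (used for direct checks; the sampler uses
        the blockwise conditionals)."""
        lp = self.loglik(x)
        for p in ("a", "v", "ter"):
            for s in self.sessions:
                for g in self.groups_for(p):
                    lp += self._hyper_prior(x, p, s, g)
                    for i in self.subjects:
                        lp += self._subject_prior(x, p, i, s, g)
        for s in self.sessions:
            lp += self._hyper_prior(x, "z", s, "")
            for i in self.subjects:
                lp += self._z_prior(x, i, s)
        lp += self._var_prior(x)
        return lp

    def point(self, x):
        """Subject-level DDMParams per design cell at slot vector x."""
        out = {}
        for k, key in enumerate(self.cells):
            ia, iv, iz, it = self.cell_slots[k]
            out[key] = ddm.DDMParams(
                a=x[ia], v=x[iv], z=x[iz], ter=x[it],
                sv=self._var(x, "sv"), sz=self._var(x, "sz"),
                st=self._var(x, "st"))
        return out


def build_model(data, variant, priors=None, **kwargs):
    """Assemble the joint posterior for one constraint variant.

    `data` must already be filtered (no timed-out or sub-100-ms trials) and
    every subject must have trials in every session x condition cell.
    """
    return HierarchicalDDM(data, variant, priors=priors, **kwargs)


class GaussianMeansModel:
    """k independent normal means with known noise SD and flat priors.

    The posterior is available in closed form (mean = sample mean,
    SD = sigma/sqrt(n)), which makes this the reference model for validating
    the sampler and the DIC machinery (pD should equal k).
    """

    def __init__(self, data, sigma=1.0):
        self.data = [np.asarray(d, dtype=float) for d in data]
        self.sigma = float(sigma)
        self.slot_names = [f"theta[{j}]" for j in range(len(self.data))]
        self.n_slots = len(self.data)
        self.blocks = [
            _Block(f"theta[{j}]", [j], [sigma / math.sqrt(len(self.data[j]))],
                   0.44, "toy")
            for j in range(self.n_slots)
        ]

    def init_state(self):
        return np.array([d.mean() for d in self.data])

    def loglik(self, x):
        s2 = self.sigma ** 2
        lp = 0.0
        for j, d in enumerate(self.data):
            lp += (-0.5 * np.sum((d - x[j]) ** 2) / s2
                   - len(d) * (math.log(self.sigma) + _LOG_SQRT_2PI))
        return lp

    def deviance(self, x):
        return -2.0 * self.loglik(x)

    def block_logp(self, bi, x):
        j = self.blocks[bi].idx[0]
        d = self.data[j]
        return -0.5 * np.sum((d - x[j]) ** 2) / self.sigma ** 2


def sample_posterior(model, n_samples=15000, burn_in=5000, seed=0,
                     n_chains=1) -> PosteriorSamples:
    """Adaptive Metropolis-within-Gibbs over the model's parameter blocks.

    Proposal scales adapt toward each block's target acceptance rate during
    burn-in only. Deviance is recorded for every retained iteration.
    Multiple chains (for Gelman-Rubin style checks) are run sequentially with
    derived seeds and concatenated; the default single chain mirrors a
    Geweke-checked workflow.
    """
    if not (n_samples > burn_in >= 0):
        raise ValueError("need n_samples > burn_in >= 0")
    all_draws, all_dev = [], []
    acc = {}
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        x = model.init_state().astype(float).copy()
        blocks = model.blocks
        for bi, b in enumerate(blocks):
            b.log_scale = 0.0
            b.n_prop = 0
            b.n_acc = 0
            lp0 = model.block_logp(bi, x)
            if not math.isfinite(lp0):
                raise InitializationError(
                    f"non-finite log-posterior at initialization in block "
                    f"{b.label}")
        n_keep = n_samples - burn_in
        draws = np.empty((n_keep, model.n_slots))
        dev = np.empty(n_keep)
        cached = hasattr(model, "begin")
        if cached:
            model.begin(x)
        # global adaptive-covariance (Haario-style) moves traverse the
        # correlated ridges (e.g. starting-point variability vs drift) that
        # componentwise sweeps cross only slowly
        gidx = np.asarray(getattr(model, "global_slot_idx",
                                  np.arange(model.n_slots)), dtype=np.intp)
        dg = len(gidx)
        use_global = (hasattr(model, "full_logp_prop")
                      and model.n_slots > 3 and dg > 0)
        hist = np.empty((burn_in, dg)) if use_global else None
        chol = None
        glob_log_scale = 0.0
        glob_start = min(200, burn_in // 2)
        n_glob_acc = 0
        n_glob_prop = 0
        for it in range(n_samples):
            for bi, b in enumerate(blocks):
                # slowly-mixing blocks (variability ridge, group level) are
                # swept several times per iteration
                for _rep in range(getattr(b, "repeats", 1)):
                    prop = x.copy()
                    step = math.exp(b.log_scale) * b.scales
                    prop[b.idx] = x[b.idx] + step * rng.standard_normal(
                        len(b.idx))
                    if cached:
                        cur = model.block_logp_current(bi, x)
                        new, aux = model.block_logp_prop(bi, prop)
                    else:
                        cur = model.block_logp(bi, x)
                        new = model.block_logp(bi, prop)
                    alpha = 0.0 if not math.isfinite(new) \
                        else min(1.0, math.exp(min(new - cur, 0.0)))
                    if rng.random() < alpha:
                        if cached:
                            model.commit(bi, prop, aux)
                        x = prop
                        b.n_acc += 1
                    b.n_prop += 1
                    if it < burn_in:
                        gamma = (it + 1) ** -0.6
                        b.log_scale += gamma * (alpha - b.target)
            if use_global:
                if it < burn_in:
                    hist[it] = x[gidx]
                    if it >= glob_start and (it - glob_start) % 25 == 0:
                        win = hist[max(0, it - 1500):it + 1]
                        cov = np.cov(win.T) + 1e-8 * np.eye(dg)
                        try:
                            chol = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            chol = np.diag(np.sqrt(np.diag(cov)))
                if chol is not None:
                    for _g in range(3):
                        step = math.exp(glob_log_scale) * 2.38 / math.sqrt(dg)
                        prop = x.copy()
                        prop[gidx] = x[gidx] + step * (
                            chol @ rng.standard_normal(dg))
                        cur = model.full_logp_current(x)
                        new, aux = model.full_logp_prop(prop)
                        alpha = 0.0 if not math.isfinite(new) \
                            else min(1.0, math.exp(min(new - cur, 0.0)))
                        if rng.random() < alpha:
                            model.commit_full(aux)
                            x = prop
                            n_glob_acc += 1
                        n_glob_prop += 1
                        if it < burn_in:
                            glob_log_scale += (it + 1) ** -0.6 * (alpha - 0.25)
            if it >= burn_in:
                draws[it - burn_in] = x
                dev[it - burn_in] = (model.deviance_current() if cached
                                     else model.deviance(x))
        all_draws.append(draws)
        all_dev.append(dev)
        for b in blocks:
            acc[f"chain{chain}:{b.label}"] = b.n_acc / max(b.n_prop, 1)
        if n_glob_prop:
            acc[f"chain{chain}:global"] = n_glob_acc / n_glob_prop
    return PosteriorSamples(
        draws=pd.DataFrame(np.vstack(all_draws), columns=model.slot_names),
        deviance=np.concatenate(all_dev),
        burn_in=burn_in, seed=seed, acceptance=acc,
        variant=getattr(getattr(model, "variant", None), "label", ""),
        priors=getattr(model, "priors", None).to_dict()
        if getattr(model, "priors", None) else {})


def _spectral_density_zero(x):
    """Spectral density at frequency zero: Bartlett-windowed autocovariances
    with the Andrews AR(1) plug-in bandwidth (lag 0 for white-noise-like
    segments, long windows for strongly autocorrelated chains)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    g0 = np.dot(xc, xc) / n
    if g0 <= 0:
        return 0.0
    r1 = float(np.dot(xc[1:], xc[:-1]) / n) / g0
    r1 = min(max(r1, -0.97), 0.97)
    if abs(r1) > 1e-3:
        lags = int(math.ceil(
            1.1447 * (4 * r1 * r1 * n / (1 - r1 * r1) ** 2) ** (1.0 / 3.0)))
        lags = min(lags, n // 3)
    else:
        lags = 0
    s = g0
    for l in range(1, lags + 1):
        g = np.dot(xc[l:], xc[:-l]) / n
        s += 2.0 * (1.0 - l / (lags + 1.0)) * g
    return max(s, 0.0)


def geweke_diagnostic(chain, first_frac=0.1, last_frac=0.5):
    """Geweke convergence z-score of a single chain.

    Compares the mean of the first `first_frac` of the chain against the mean
    of the last `last_frac`, with spectral-density variance estimates. A
    constant chain returns 0 with a warning.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain must contain at least 100 draws")
    if np.ptp(x) == 0:
        warnings.warn("constant chain passed to geweke_diagnostic")
        return 0.0
    n = len(x)
    a = x[: int(n * first_frac)]
    b = x[n - int(n * last_frac):]
    va = _spectral_density_zero(a) / len(a)
    vb = _spectral_density_zero(b) / len(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        warnings.warn("degenerate variance in geweke_diagnostic")
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def compute_dic(samples: PosteriorSamples, model, method="pd"):
    """Deviance information criterion from recorded deviances.

    pD = mean deviance - deviance at the posterior mean (Spiegelhalter);
    method="pv" uses half the deviance variance instead. DIC = Dbar + pD.
    """
    dbar = float(np.mean(samples.deviance))
    if method == "pv":
        pd_ = 0.5 * float(np.var(samples.deviance))
    else:
        xbar = samples.draws.mean(axis=0).to_numpy()
        dhat = float(model.deviance(xbar))
        if not math.isfinite(dhat):
            raise ValueError("deviance at the posterior mean is not finite")
        pd_ = dbar - dhat
    return {"dic": dbar + pd_, "pD": pd_, "mean_deviance": dbar}
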