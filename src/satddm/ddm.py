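"""Core drift-diffusion process: exact likelihood and stochastic simulator.

The model describes a binary decision as a Wiener process with drift v
between absorbing boundaries 0 and a, started at z * a. Absorption at the
upper boundary codes a "rightward" response, at the lower a "leftward" one.
The observed response time is the absorption time plus a non-decision time
Ter. Trial-to-trial variability: drift ~ Normal(v, sv), relative start
~ Uniform(z - sz/2, z + sz/2), non-decision time ~ Uniform(Ter - st/2,
Ter + st/2).

Conventions (documented prominently because they fix all parameter scales):

* intra-trial noise s = 1, not the historical s = 0.1 scaling;
* time in seconds internally; file I/O uses milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import (cell_loglik, full_density, simulate_cell, wfpt_lower,
                       wfpt_lower_sv)

__all__ = [
    "DDMParams",
    "TrialOutcome",
    "simulate_trial",
    "simulate_dataset",
    "wfpt_density",
    "trial_loglik",
    "choice_probability",
    "mean_decision_time",
    "DEFAULT_DT",
    "DEFAULT_EPS",
    "DEFAULT_QUAD_NODES",
    "LOGLIK_FLOOR",
]

#: Euler-Maruyama step for the simulator (seconds).
DEFAULT_DT = 1e-4
#: absolute truncation error of the first-passage series.
DEFAULT_EPS = 1e-7
#: Gauss-Legendre nodes per dimension for the sz / st integrals.
DEFAULT_QUAD_NODES = 11
#: density clamp applied before taking logs, keeps MCMC finite for outliers.
LOGLIK_FLOOR = 1e-15


class ParameterDomainError(ValueError):
    """Raised when DDM parameters violate their domain constraints."""


@dataclass(frozen=True)
class DDMParams:
    """One design cell's seven diffusion parameters (s = 1 scale).

    a : boundary separation, > 0
    v : mean drift rate (signed, evidence units / s)
    z : mean relative starting point in (0, 1); > 0.5 biases the upper bound
    ter : mean non-decision time (s), >= 0
    sv : SD of normal trial-to-trial drift variability, >= 0
    sz : range of uniform starting-point variability, >= 0
    st : range of uniform non-decision-time variability (s), >= 0
    """

    a: float
    v: float
    z: float = 0.5
    ter: float = 0.0
    sv: float = 0.0
    sz: float = 0.0
    st: float = 0.0

    def __post_init__(self):
        if not (self.a > 0):
            raise ParameterDomainError(f"a must be > 0, got {self.a}")
        if not (0 < self.z < 1):
            raise ParameterDomainError(f"z must lie in (0, 1), got {self.z}")
        if self.ter < 0:
            raise ParameterDomainError(f"Ter must be >= 0, got {self.ter}")
        for name in ("sv", "sz", "st"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be >= 0")
        if self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= 1:
            raise ParameterDomainError(
                "starting-point range z +- sz/2 must stay strictly inside (0, 1)")
        if self.ter - self.st / 2 < 0:
            raise ParameterDomainError("Ter - st/2 must be >= 0")


@dataclass(frozen=True)
class TrialOutcome:
    """Simulated trial: absorbed boundary, response time (s), timeout flag."""

    boundary: str  # "upper" | "lower"
    rt: float
    timed_out: bool = False


def _check_sim_config(dt, max_t, params):
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt >= max_t:
        raise ValueError(f"dt ({dt}) must be smaller than max_t ({max_t})")
    if max_t <= params.ter:
        raise ValueError("max_t must exceed the non-decision time")


def simulate_trial(params: DDMParams, max_t: float = 2.4,
                   dt: float = DEFAULT_DT, seed: int = 0) -> TrialOutcome:
    """Simulate a single trial by Euler-Maruyama integration."""
    return simulate_dataset(params, 1, max_t=max_t, dt=dt, seed=seed)[0]


def simulate_dataset(params: DDMParams, n_trials: int, max_t: float = 2.4,
                     dt: float = DEFAULT_DT, seed: int = 0) -> list[TrialOutcome]:
    """Simulate n_trials independent trials; reproducible for a given seed."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    _check_sim_config(dt, max_t, params)
    rt, upper, out = simulate_cell(
        n_trials, params.a, params.v, params.z, params.ter,
        params.sv, params.sz, params.st, dt, max_t, seed)
    return [
        TrialOutcome("upper" if upper[i] else "lower", float(rt[i]), bool(out[i]))
        for i in range(n_trials)
    ]


def simulate_arrays(params: DDMParams, n_trials: int, max_t: float = 2.4,
                    dt: float = DEFAULT_DT, seed: int = 0):
    """Array-valued variant of :func:`simulate_dataset` (rt, upper, timed_out)."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    _check_sim_config(dt, max_t, params)
    return simulate_cell(n_trials, params.a, params.v, params.z, params.ter,
                         params.sv, params.sz, params.st, dt, max_t, seed)


def wfpt_density(t, boundary: str, a: float, v: float, z: float,
                 eps: float = DEFAULT_EPS):
    """First-passage-time density of the pure 4-parameter process.

    t is the decision time (response time minus non-decision time); the
    density at the upper boundary is obtained from the lower-boundary series
    by the reflection (v, z) -> (-v, 1 - z). Non-positive t returns 0.
    Accepts scalars or arrays of t.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if not (a > 0 and 0 < z < 1):
        raise ParameterDomainError("require a > 0 and 0 < z < 1")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if boundary == "upper":
        v, z = -v, 1.0 - z
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([wfpt_lower(ti, a, v, z, eps) for ti in tarr])
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached Gauss-Legendre nodes/weights on [-1, 1]."""
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def trial_density(rt: float, boundary: str, params: DDMParams,
                  eps: float = DEFAULT_EPS,
                  quad_nodes: int = DEFAULT_QUAD_NODES) -> float:
    """Defective density of (boundary, rt) under the full 7-parameter model."""
    gl_x, gl_w = gauss_legendre(quad_nodes)
    return float(full_density(rt, boundary == "upper", params.a, params.v,
                              params.z, params.ter, params.sv, params.sz,
                              params.st, gl_x, gl_w, eps))


def trial_loglik(outcome: TrialOutcome, params: DDMParams,
                 eps: float = DEFAULT_EPS,
                 quad_nodes: int = DEFAULT_QUAD_NODES) -> float:
    """Log-likelihood of one trial under the full model.

    sv enters in closed form; sz and st through fixed-node Gauss-Legendre
    quadrature. The density is clamped at LOGLIK_FLOOR so the result is
    always finite (e.g. for rt < Ter - st/2 the floor's log is returned).
    """
    if outcome.timed_out:
        raise ValueError("timed-out trials carry no likelihood; filter them first")
    d = trial_density(outcome.rt, outcome.boundary, params,
                      eps=eps, quad_nodes=quad_nodes)
    return math.log(max(d, LOGLIK_FLOOR))


def loglik_trials(rt: np.ndarray, upper: np.ndarray, drift_sign: np.ndarray,
                  params: DDMParams, eps: float = DEFAULT_EPS,
                  quad_nodes: int = DEFAULT_QUAD_NODES) -> float:
    """Summed log-likelihood of a cell of trials (stimulus-coded drift)."""
    gl_x, gl_w = gauss_legendre(quad_nodes)
    return float(cell_loglik(
        np.ascontiguousarray(rt, dtype=float),
        np.ascontiguousarray(upper, dtype=bool),
        np.ascontiguousarray(drift_sign, dtype=float),
        params.a, params.v, params.z, params.ter,
        params.sv, params.sz, params.st, gl_x, gl_w, eps, LOGLIK_FLOOR))


def choice_probability(a: float, v: float, z: float) -> float:
    """Probability of absorption at the upper boundary (pure process, s = 1).

    P(upper) = (1 - exp(-2 v a z)) / (1 - exp(-2 v a)), with the continuous
    limit P(upper) = z at v = 0.
    """
    if not (a > 0 and 0 < z < 1):
        raise ParameterDomainError("require a > 0 and 0 < z < 1")
    if abs(v) * a < 1e-10:
        return float(z)
    return float(math.expm1(-2.0 * v * a * z) / math.expm1(-2.0 * v * a))


def mean_decision_time(a: float, v: float, z: float) -> float:
    """Mean first-passage time of the pure process (either boundary).

    From the optional-stopping identity E[X_T] - x0 = v E[T]:
    E[T] = (a P_upper - z a) / v for v != 0, and z a (a - z a) at v = 0.
    """
    x0 = z * a
    if abs(v) * a < 1e-10:
        return float(x0 * (a - x0))
    return float((a * choice_probability(a, v, z) - x0) / v)
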