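"""Numba kernels for the Wiener first-passage-time density and trial simulator.

All kernels work on the s = 1 intra-trial noise scale and in seconds.
The normalized first-passage density switches between the small-time and
large-time series expansions, picking whichever needs fewer terms at the
requested truncation error.
"""

import math

import numpy as np
from numba import njit

PI = math.pi


@njit(cache=True)
def _fpt_lower_norm(tt, w, eps):
    """First-passage density at the LOWER bound of a zero-drift, unit-diffusion
    process on (0, 1) started at w, evaluated at normalized time tt = t / a**2.

    Series truncation chosen so the absolute error is <= eps.
    """
    if tt <= 0.0:
        return 0.0
    # number of terms needed by each representation
    if 2.0 * math.sqrt(2.0 * PI * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * PI * tt)))
        sq = math.sqrt(tt) + 1.0
        if sq > ks:
            ks = sq
    else:
        ks = 2.0
    if PI * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(PI * tt * eps) / (PI * PI * tt))
        bound = 1.0 / (PI * math.sqrt(tt))
        if bound > kl:
            kl = bound
    else:
        kl = 1.0 / (PI * math.sqrt(tt))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -int(math.floor((K - 1) / 2.0))
        hi = int(math.ceil((K - 1) / 2.0))
        s = 0.0
        for k in range(lo, hi + 1):
            u = w + 2.0 * k
            s += u * math.exp(-u * u / (2.0 * tt))
        return s / math.sqrt(2.0 * PI * tt * tt * tt)
    # large-time expansion
    K = int(math.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * PI * PI * tt / 2.0) * math.sin(k * PI * w)
    return PI * s


@njit(cache=True)
def wfpt_lower(t, a, v, w, eps):
    """Density of absorption at the lower bound at decision time t, pure
    4-parameter process (drift v, separation a, relative start w, s = 1)."""
    if t <= 0.0:
        return 0.0
    p = _fpt_lower_norm(t / (a * a), w, eps)
    if p <= 0.0:
        return 0.0
    return p / (a * a) * math.exp(-v * a * w - v * v * t / 2.0)


@njit(cache=True)
def wfpt_lower_sv(t, a, v, w, sv, eps):
    """Lower-bound density with normal trial-to-trial drift variability sv
    integrated out in closed form (sv = 0 falls back to the pure density)."""
    if t <= 0.0:
        return 0.0
    p = _fpt_lower_norm(t / (a * a), w, eps)
    if p <= 0.0:
        return 0.0
    if sv <= 0.0:
        return p / (a * a) * math.exp(-v * a * w - v * v * t / 2.0)
    g = 1.0 + sv * sv * t
    expo = (sv * sv * a * a * w * w - 2.0 * v * a * w - v * v * t) / (2.0 * g)
    return p / (a * a) * math.exp(expo) / math.sqrt(g)


@njit(cache=True)
def _cdf_lower(t, a, v, w, eps):
    """P(absorption at the LOWER bound by decision time t), pure process.

    Large-time series: F(t) = P_lower - (pi/a^2) e^{-vaw}
    sum_k k sin(pi k w) e^{-lam_k t} / lam_k with lam_k = (v^2 + k^2 pi^2/a^2)/2.
    """
    if t <= 0.0:
        return 0.0
    va = v * a
    if abs(va) < 1e-10:
        p_lower = 1.0 - w
    else:
        p_lower = 1.0 - math.expm1(-2.0 * va * w) / math.expm1(-2.0 * va)
    pref = PI / (a * a) * math.exp(-v * a * w)
    s = 0.0
    for k in range(1, 200):
        lam = 0.5 * (v * v + k * k * PI * PI / (a * a))
        term = k * math.sin(PI * k * w) * math.exp(-lam * t) / lam
        s += term
        if abs(term) < eps / max(pref, 1e-10) and k > 2:
            break
    f = p_lower - pref * s
    if f < 0.0:
        f = 0.0
    elif f > 1.0:
        f = 1.0
    return f


@njit(cache=True)
def prob_response_by(c, a, v, z, ter, sv, sz, st, gh_x, gh_w, gl_x, gl_w, eps):
    """P(T_decision + T_nondecision <= c) under the full 7-parameter model.

    sv is integrated by Gauss-Hermite (gh_x, gh_w for weight e^{-x^2}),
    sz / st by Gauss-Legendre. Used to renormalize the likelihood when
    responses beyond a cutoff are censored out of the data.
    """
    nh = gh_x.shape[0]
    ngl = gl_x.shape[0]
    total = 0.0
    # non-decision-time nodes
    for i in range(ngl if st > 0.0 else 1):
        tprime = ter + 0.5 * st * gl_x[i] if st > 0.0 else ter
        wt = gl_w[i] * 0.5 if st > 0.0 else 1.0
        t0 = c - tprime
        if t0 <= 0.0:
            continue
        for j in range(ngl if sz > 0.0 else 1):
            zp = z + 0.5 * sz * gl_x[j] if sz > 0.0 else z
            wz = gl_w[j] * 0.5 if sz > 0.0 else 1.0
            if sv > 0.0:
                acc = 0.0
                for h in range(nh):
                    u = v + math.sqrt(2.0) * sv * gh_x[h]
                    fl = _cdf_lower(t0, a, u, zp, eps)
                    fu = _cdf_lower(t0, a, -u, 1.0 - zp, eps)
                    acc += gh_w[h] * (fl + fu)
                acc /= math.sqrt(PI)
            else:
                acc = (_cdf_lower(t0, a, v, zp, eps)
                       + _cdf_lower(t0, a, -v, 1.0 - zp, eps))
            total += wt * wz * acc
    if total < 1e-12:
        total = 1e-12
    elif total > 1.0:
        total = 1.0
    return total


@njit(cache=True)
def full_density(rt, upper, a, v, z, ter, sv, sz, st, gl_x, gl_w, eps):
    """Defective density of (boundary, rt) under the full 7-parameter model.

    sv is integrated analytically; sz and st by Gauss-Legendre quadrature with
    the nodes/weights (gl_x on [-1, 1], gl_w summing to 2) supplied.
    For the upper boundary the reflection (v, z) -> (-v, 1 - z) is applied.
    """
    if upper:
        v = -v
        z = 1.0 - z
    # st quadrature over ter' in [ter - st/2, ter + st/2]
    n = gl_x.shape[0]
    total = 0.0
    if st > 0.0:
        for i in range(n):
            tprime = ter + 0.5 * st * gl_x[i]
            tdec = rt - tprime
            if tdec <= 0.0:
                continue
            if sz > 0.0:
                inner = 0.0
                for j in range(n):
                    zp = z + 0.5 * sz * gl_x[j]
                    inner += gl_w[j] * wfpt_lower_sv(tdec, a, v, zp, sv, eps)
                total += gl_w[i] * inner * 0.5
            else:
                total += gl_w[i] * wfpt_lower_sv(tdec, a, v, z, sv, eps)
        total *= 0.5
    else:
        tdec = rt - ter
        if tdec <= 0.0:
            return 0.0
        if sz > 0.0:
            for j in range(n):
                zp = z + 0.5 * sz * gl_x[j]
                total += gl_w[j] * wfpt_lower_sv(tdec, a, v, zp, sv, eps)
            total *= 0.5
        else:
            total = wfpt_lower_sv(tdec, a, v, z, sv, eps)
    if total < 0.0:
        total = 0.0
    return total


@njit(cache=True)
def cell_loglik(rt, upper, drift_sign, a, v, z, ter, sv, sz, st,
                gl_x, gl_w, eps, floor):
    """Summed log-likelihood of one design cell's trials.

    drift_sign flips v per trial for stimulus coding (+1 rightward stimulus,
    -1 leftward). Density clamped at `floor` before taking logs.
    """
    s = 0.0
    for i in range(rt.shape[0]):
        d = full_density(rt[i], upper[i], a, drift_sign[i] * v, z, ter,
                         sv, sz, st, gl_x, gl_w, eps)
        if d < floor:
            d = floor
        s += math.log(d)
    return s


@njit(cache=True)
def cell_loglik_censored(rt, upper, drift_sign, a, v, z, ter, sv, sz, st,
                         gl_x, gl_w, gh_x, gh_w, censor, eps, floor):
    """Cell log-likelihood conditioned on a response before `censor` seconds.

    Each trial's density is renormalized by P(RT <= censor) at that trial's
    (signed) drift, matching data from which overtime responses were removed.
    """
    lp_pos = math.log(prob_response_by(
        censor, a, v, z, ter, sv, sz, st, gh_x, gh_w, gl_x, gl_w, eps))
    lp_neg = math.log(prob_response_by(
        censor, a, -v, z, ter, sv, sz, st, gh_x, gh_w, gl_x, gl_w, eps))
    s = 0.0
    for i in range(rt.shape[0]):
        d = full_density(rt[i], upper[i], a, drift_sign[i] * v, z, ter,
                         sv, sz, st, gl_x, gl_w, eps)
        if d < floor:
            d = floor
        s += math.log(d) - (lp_pos if drift_sign[i] > 0 else lp_neg)
    return s


@njit(cache=True)
def simulate_cell(n, a, v, z, ter, sv, sz, st, dt, max_t, seed):
    """Euler-Maruyama simulation of n independent trials.

    Between grid points a Brownian-bridge crossing test is applied, which
    removes the leading-order first-passage bias of the plain Euler scheme
    (crossings inside a step would otherwise be missed systematically).
    Crossing times are recorded at the step midpoint.

    Returns (rt, upper, timed_out); rt includes the drawn non-decision time.
    A trial is timed out when decision + non-decision time exceeds max_t.
    """
    np.random.seed(seed)
    rt = np.empty(n)
    upper = np.zeros(n, dtype=np.bool_)
    timed_out = np.zeros(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    for i in range(n):
        vi = v if sv <= 0.0 else v + sv * np.random.standard_normal()
        zi = z if sz <= 0.0 else z + sz * (np.random.random() - 0.5)
        ti = ter if st <= 0.0 else ter + st * (np.random.random() - 0.5)
        x = zi * a
        t = 0.0
        hit_upper = False
        out = True
        # cap the walk at the response window: anything longer is a timeout
        while t + ti < max_t:
            xn = x + vi * dt + sqdt * np.random.standard_normal()
            t += dt
            if xn >= a:
                hit_upper = True
                out = False
            elif xn <= 0.0:
                out = False
            else:
                # bridge crossing probabilities within the elapsed step
                pu = math.exp(-2.0 * (a - x) * (a - xn) / dt)
                if np.random.random() < pu:
                    hit_upper = True
                    out = False
                else:
                    pl = math.exp(-2.0 * x * xn / dt)
                    if np.random.random() < pl:
                        out = False
            x = xn
            if not out:
                break
        if out:
            rt[i] = max_t
            timed_out[i] = True
        else:
            rt[i] = t - 0.5 * dt + ti
            upper[i] = hit_upper
    return rt, upper, timed_out


@njit(cache=True)
def perm_t_null(values, n1, n_perm, seed):
    """Null distribution of the Welch t statistic under label shuffling.

    values holds group 1 then group 2; each permutation reassigns n1 of the
    pooled values to group 1.
    """
    np.random.seed(seed)
    n = values.shape[0]
    n2 = n - n1
    out = np.empty(n_perm)
    idx = np.arange(n)
    for p in range(n_perm):
        # Fisher-Yates shuffle
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = idx[i]
            idx[i] = idx[j]
            idx[j] = tmp
        s1 = 0.0
        q1 = 0.0
        for i in range(n1):
            x = values[idx[i]]
            s1 += x
            q1 += x * x
        s2 = 0.0
        q2 = 0.0
        for i in range(n1, n):
            x = values[idx[i]]
            s2 += x
            q2 += x * x
        m1 = s1 / n1
        m2 = s2 / n2
        var1 = (q1 - n1 * m1 * m1) / (n1 - 1)
        var2 = (q2 - n2 * m2 * m2) / (n2 - 1)
        se = math.sqrt(var1 / n1 + var2 / n2)
        out[p] = (m1 - m2) / se if se > 0.0 else 0.0
    return out
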