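"""Trial-table I/O, preprocessing, and single-subject randomization tests.

A trial table is a tidy DataFrame with one row per trial:

    subject, session (1-6), block (1-12), condition (speed | accuracy),
    direction_deg (30 | 150 | 210 | 330), response (left | right),
    correct (bool), rt_ms (float; NaN when no response was made)

Directions 30 and 330 degrees are rightward, 150 and 210 leftward.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from ._kernels import perm_t_null

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "filter_trials",
    "block_means",
    "randomization_test",
    "speed_time_limit",
    "RT_MIN_MS",
    "RT_MAX_MS",
]

TRIAL_COLUMNS = ["subject", "session", "block", "condition", "direction_deg",
                 "response", "correct", "rt_ms"]

#: fast-guess cutoff: trials faster than 100 ms are discarded.
RT_MIN_MS = 100.0
#: trials without a valid response within 2200 ms are discarded.
RT_MAX_MS = 2200.0

RIGHTWARD_DEG = (30, 330)
LEFTWARD_DEG = (150, 210)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def filter_trials(raw: pd.DataFrame):
    """Remove fast guesses (< 100 ms) and missing/overtime responses.

    Returns (filtered table, discarded fraction of all trials). The boundary
    is inclusive on both sides: rt = 100 ms and rt = 2200 ms are retained.
    Idempotent: filtering a filtered table discards nothing.
    """
    rt = raw["rt_ms"]
    valid = rt.notna() & (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    if "response" in raw.columns:
        valid &= raw["response"].isin(("left", "right"))
    out = raw[valid].copy()
    out["valid"] = True
    discarded = 1.0 - len(out) / len(raw) if len(raw) else 0.0
    return out, discarded


def block_means(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean RT and accuracy (one row per subject x session x block).

    For a complete six-session subject this yields 36 speed and 36 accuracy
    block summaries. Empty blocks are kept with count 0 and NaN means only if
    present as rows; blocks absent from the table do not appear.
    """
    grp = filtered.groupby(["subject", "session", "block", "condition"],
                           as_index=False, observed=True)
    out = grp.agg(mean_rt_ms=("rt_ms", "mean"),
                  prop_correct=("correct", "mean"),
                  n_trials=("rt_ms", "size"))
    return out


def _welch_t(g1, g2):
    n1, n2 = len(g1), len(g2)
    se = math.sqrt(g1.var(ddof=1) / n1 + g2.var(ddof=1) / n2)
    if se == 0:
        raise ValueError("zero variance: the t statistic is undefined")
    return (g1.mean() - g2.mean()) / se


def randomization_test(group1, group2, n_perm=100_000, seed=0, sided="one",
                       add_one=False):
    """Permutation test of a mean difference between two trial-block samples.

    The observed statistic is t = (mean1 - mean2) / SE(difference), with the
    unpooled (Welch) standard error. The null distribution is built by
    shuffling the condition labels n_perm times; the one-sided p-value is the
    plain proportion of shuffled statistics strictly exceeding the observed
    one (two-sided: comparison of |t|). `add_one=True` applies the
    (b + 1) / (m + 1) finite-sample correction instead of the plain
    proportion. When the number of distinct label assignments is at most
    n_perm the null is enumerated exhaustively and the p-value is exact.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.var(np.concatenate([g1, g2])) == 0:
        raise ValueError("zero variance in the pooled data")
    t_obs = _welch_t(g1, g2)
    pooled = np.ascontiguousarray(np.concatenate([g1, g2]))
    n1 = len(g1)
    if math.comb(len(pooled), n1) <= n_perm:
        null = np.array([
            _welch_t(pooled[list(ix)],
                     np.delete(pooled, list(ix)))
            for ix in combinations(range(len(pooled)), n1)
        ])
    else:
        null = perm_t_null(pooled, n1, int(n_perm), int(seed) % (2 ** 31))
    if sided == "one":
        b = int(np.sum(null > t_obs))
    elif sided == "two":
        b = int(np.sum(np.abs(null) > abs(t_obs)))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    m = len(null)
    p = (b + 1) / (m + 1) if add_one else b / m
    return {"t": float(t_obs), "p": float(p), "n_perm": m}


def speed_time_limit(first_accuracy_block_rts) -> float:
    """Speed-condition response deadline: the 40% quantile of the RTs from
    the session's first accuracy block (linear interpolation between order
    statistics)."""
    rts = np.asarray(first_accuracy_block_rts, dtype=float)
    rts = rts[~np.isnan(rts)]
    if rts.size == 0:
        raise ValueError("no RTs supplied")
    return float(np.quantile(rts, 0.4))
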