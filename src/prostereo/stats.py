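"""Cohort statistics: balanced two-way ANOVA, Student t, Mann-Whitney.

The tests are implemented from first principles (explicit sums of squares
and rank statistics) so each one can be checked against brute-force oracles;
only the tail probabilities come from the standard F, t and normal
distributions.  Significance is flagged at p <= 0.05 throughout, matching
the study design the package emulates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class DegenerateDataError(ValueError):
    pass


class UnbalancedDesignError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    df: tuple | float | None
    p: float
    significant: bool

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.significant != (self.p <= ALPHA):
            raise ValueError("significance flag inconsistent with p-value")


def _result(name, statistic, df, p) -> StatResult:
    p = float(min(max(p, 0.0), 1.0))
    return StatResult(
        name=name, statistic=float(statistic), df=df, p=p, significant=p <= ALPHA
    )


# ---------------------------------------------------------------------------
# two-way ANOVA (balanced, fixed effects, with interaction)


def two_way_anova(
    frame: pd.DataFrame,
    endpoint: str,
    factor_a: str = "treatment",
    factor_b: str = "age",
) -> dict:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Sums of squares are computed from cell and marginal means (the balanced
    decomposition SS_total = SS_A + SS_B + SS_AB + SS_error); F statistics
    are tested against the residual mean square.  Raises
    :class:`UnbalancedDesignError` when cell sizes differ and
    :class:`DegenerateDataError` when factors have < 2 levels or cells < 2
    replicates.
    """
    y = frame[endpoint].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DegenerateDataError("endpoint contains non-finite values")
    a_lab = frame[factor_a].to_numpy()
    b_lab = frame[factor_b].to_numpy()
    a_levels = sorted(pd.unique(a_lab).tolist(), key=str)
    b_levels = sorted(pd.unique(b_lab).tolist(), key=str)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise DegenerateDataError("each factor needs at least 2 levels")
    cells = {}
    for ai in a_levels:
        for bj in b_levels:
            vals = y[(a_lab == ai) & (b_lab == bj)]
            cells[(ai, bj)] = vals
    sizes = {len(v) for v in cells.values()}
    if len(sizes) != 1:
        raise UnbalancedDesignError(f"unequal cell sizes {sorted(sizes)}")
    n = sizes.pop()
    if n < 2:
        raise DegenerateDataError("need >= 2 replicates per cell")

    grand = y.mean()
    mean_a = {ai: y[a_lab == ai].mean() for ai in a_levels}
    mean_b = {bj: y[b_lab == bj].mean() for bj in b_levels}
    mean_ab = {k: v.mean() for k, v in cells.items()}

    ss_a = n * b * sum((mean_a[ai] - grand) ** 2 for ai in a_levels)
    ss_b = n * a * sum((mean_b[bj] - grand) ** 2 for bj in b_levels)
    ss_ab = n * sum(
        (mean_ab[(ai, bj)] - mean_a[ai] - mean_b[bj] + grand) ** 2
        for ai in a_levels
        for bj in b_levels
    )
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    ss_tot = ((y - grand) ** 2).sum()

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err
    out = {"_ss": {"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_err, "total": ss_tot}}
    for key, ss, df in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", ss_ab, df_ab),
    ):
        if ms_err == 0:
            f_stat = math.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f_stat = (ss / df) / ms_err
            p = sps.f.sf(f_stat, df, df_err)
        out[key] = _result(f"two-way ANOVA {key}", f_stat, (df, df_err), p)
    return out


# ---------------------------------------------------------------------------
# Student t (pooled variance, two-sided)


def student_t(group_a, group_b, name: str = "Student t") -> StatResult:
    """Two-sample pooled-variance Student t test, two-sided."""
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise DegenerateDataError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return _result(name, 0.0, df, 1.0)
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return _result(name, t, df, p)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample, from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    na = len(x)
    n = len(pooled)
    offset = na * (na + 1) / 2.0
    us = [
        sum(ranks[i] for i in comb) - offset
        for comb in itertools.combinations(range(n), na)
    ]
    us = np.asarray(us)
    mean_u = len(x) * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    return float(np.mean(np.abs(us - mean_u) >= dev - 1e-12))


def mann_whitney(
    group_a, group_b, mode: str = "auto", name: str = "Mann-Whitney U"
) -> StatResult:
    """Mann-Whitney U test with midranks for ties.

    ``mode``: ``"exact"`` enumerates all rank assignments (feasible for
    small samples), ``"normal"`` uses the tie-corrected normal
    approximation with continuity correction, ``"auto"`` picks exact when
    n_a + n_b <= 12 and the data are tie-free.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    na, nb = len(x), len(y)
    if na < 1 or nb < 1:
        raise DegenerateDataError("each group needs n >= 1")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (na + nb <= 12 and not has_ties) else "normal"
    if mode == "exact":
        p = _exact_two_sided_p(x, y, u)
    elif mode == "normal":
        mean_u = na * nb / 2.0
        n = na + nb
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var_u = na * nb / 12.0 * (n + 1 - tie_term)
        if var_u == 0:
            p = 1.0
        else:
            z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal'")
    return _result(name, u, None, p)


# ---------------------------------------------------------------------------
# summaries and multiplicity


def group_summary(frame: pd.DataFrame, endpoint: str, by: str = "group") -> pd.DataFrame:
    """Per-group mean +/- sample SD (n - 1 denominator) table.

    Groups with a single observation report SD = 0 together with a
    ``sd_defined = False`` flag (the sample SD is undefined at n = 1).
    """
    rows = []
    for label, sub in frame.groupby(by, sort=True):
        vals = sub[endpoint].to_numpy(dtype=float)
        if len(vals) == 0:
            raise DegenerateDataError(f"empty group {label!r}")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                by: label,
                "mean": float(vals.mean()),
                "sd": sd,
                "n": len(vals),
                "sd_defined": len(vals) > 1,
            }
        )
    return pd.DataFrame(rows).set_index(by)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
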