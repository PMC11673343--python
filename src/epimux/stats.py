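"""Cohort statistics: normality routing, correlation, region and group tests.

The battery mirrors a standard neuropathology quantification workflow:
Shapiro-Wilk decides between parametric and non-parametric branches at
alpha = 0.05 (parametric only when every group passes); Pearson correlation
relates epitope measures to one another; a repeated-measures one-way ANOVA
with Tukey adjustment compares regions within a disease (cases are the
repeated subjects); unpaired Student's t or Mann-Whitney U compares PD with
MSA.  Summaries are reported mean +/- SD.

Pearson, the pooled t statistic, the RM-ANOVA sums of squares and the Tukey
studentized-range p-values are computed from their closed forms here;
distribution functions and the Shapiro-Wilk / Mann-Whitney procedures come
from scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_NORMALITY = 0.05


@dataclass
class StatResult:
    """One statistical test outcome."""

    test: str                      # shapiro_wilk, pearson, rm_anova,
                                   # tukey_pair, t_unpaired, mann_whitney
    statistic: float
    p_value: float
    df: tuple | None = None
    effect: float | None = None    # r, mean difference, or U'
    comparison: tuple = ()
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise AssertionError(f"p-value out of [0,1]: {self.p_value}")


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def normality_route(groups: dict[str, np.ndarray]) -> tuple[str, list[StatResult]]:
    """Shapiro-Wilk each group; route 'parametric' iff every group's p >= 0.05.

    Each group needs n >= 3.  Returns the route and the per-group results.
    """
    results = []
    all_normal = True
    for name, values in groups.items():
        arr = _as_array(values, name)
        if arr.size < 3:
            raise ValueError(f"group {name!r} has n={arr.size} < 3")
        if np.ptp(arr) == 0:
            # constant sample: W undefined, clearly non-normal in routing terms
            results.append(StatResult("shapiro_wilk", float("nan"), 0.0,
                                      comparison=(name,)))
            all_normal = False
            continue
        w, p = sps.shapiro(arr)
        results.append(StatResult("shapiro_wilk", float(w), float(p),
                                  comparison=(name,)))
        if p < ALPHA_NORMALITY:
            all_normal = False
    return ("parametric" if all_normal else "nonparametric"), results


def correlate_pearson(x, y) -> StatResult:
    """Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise ValueError("samples differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the samples")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return StatResult("pearson", r, float(p), df=(n - 2,), effect=r,
                      extra={"n": n})


def rm_anova_tukey(
    table: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "case_id",
    within_col: str = "region",
) -> tuple[StatResult, list[StatResult]]:
    """Repeated-measures one-way ANOVA with Tukey pairwise adjustment.

    Only complete cases (subjects observed in all k levels) enter; dropped
    subjects are counted in the result's ``extra``.  F = MS_within /
    MS_error from the two-way subject x level decomposition with df (k-1)
    and (k-1)(n-1).  Pairwise p-values come from the studentized-range
    distribution with q = |mean_i - mean_j| / sqrt(MS_error / n).
    """
    levels = sorted(table[within_col].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    wide = table.pivot_table(index=subject_col, columns=within_col,
                             values=value_col, aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    n = len(complete)
    if n < 2:
        raise ValueError("need >= 2 complete cases")
    data = complete[levels].to_numpy(float)

    grand = data.mean()
    level_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_level = n * float(((level_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_error = ss_total - ss_level - ss_subj
    df_level = k - 1
    df_error = (k - 1) * (n - 1)
    ms_level = ss_level / df_level
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_stat = 0.0 if ms_level == 0 else float("inf")
        p = 1.0 if ms_level == 0 else 0.0
    else:
        f_stat = ms_level / ms_error
        p = float(sps.f.sf(f_stat, df_level, df_error))
    anova = StatResult("rm_anova", float(f_stat), p,
                       df=(df_level, df_error),
                       extra={"n_complete": n, "n_dropped": dropped,
                              "ms_error": ms_error})

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(level_means[i] - level_means[j])
            if ms_error <= 0:
                p_pair = 1.0 if diff == 0 else 0.0
                q = 0.0 if diff == 0 else float("inf")
            else:
                q = abs(diff) / math.sqrt(ms_error / n)
                p_pair = float(sps.studentized_range.sf(q, k, df_error))
            pairs.append(StatResult(
                "tukey_pair", q, min(max(p_pair, 0.0), 1.0),
                df=(k, df_error), effect=diff,
                comparison=(levels[i], levels[j]), adjustment="tukey",
            ))
    return anova, pairs


def compare_two_groups(x, y, route: str) -> StatResult:
    """Unpaired two-group comparison on the decided route.

    ``parametric``: two-sided pooled-variance Student's t.
    ``nonparametric``: Mann-Whitney U with the tie-corrected normal
    approximation (continuity-corrected); U + U' = n_x * n_y.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs n >= 3")
    nx, ny = x.size, y.size
    if route == "parametric":
        mx, my = x.mean(), y.mean()
        sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
               / (nx + ny - 2))
        df = nx + ny - 2
        if sp2 == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
            p = 2.0 * float(sps.t.sf(abs(t_stat), df))
        return StatResult("t_unpaired", float(t_stat), min(p, 1.0), df=(df,),
                          effect=float(mx - my))
    if route == "nonparametric":
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u = float(res.statistic)
        return StatResult("mann_whitney", u, float(res.pvalue),
                          effect=float(nx * ny - u),
                          extra={"U_prime": nx * ny - u})
    raise ValueError(f"unknown route {route!r}")


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n per group x region x measure.

    A singleton slice reports sd = 0 with ``single_value = True``; the
    formatted column renders the headline "mean% +/- sd%" style.
    """
    rows = []
    for (group, region, measure), sub in table.groupby(
            ["group", "region", "measure"], sort=True):
        vals = sub["value"].to_numpy(float)
        n = vals.size
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append({
            "group": group, "region": region, "measure": measure,
            "mean": mean, "sd": sd, "n": n, "single_value": n == 1,
            "formatted": f"{mean:.2f}% ± {sd:.2f}%",
        })
    return pd.DataFrame(rows)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (emitted alongside unadjusted correlations)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
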