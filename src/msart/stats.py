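"""Inferential layer: ANOVA variants, rank-based two-way test, post hoc
comparisons and a-priori sample-size computation.

The one-way tests report partial eta squared alongside the F statistic.
When group variances are heterogeneous the Welch variant (with its
Welch–Satterthwaite fractional denominator df) is the appropriate choice,
followed by Games–Howell comparisons; the classical F is paired with Tukey
HSD.  The Scheirer–Ray–Hare test is a rank-based two-factor analogue of
ANOVA: all observations are mid-ranked together, the rank sums of squares
are partitioned by the two-way layout, and each effect's H statistic is its
rank SS divided by the total rank variance (which absorbs the tie
correction), referred to a chi-square distribution on the effect's df.

Sample-size computation uses the noncentral F distribution: with Cohen's f,
total N and k equal groups, the noncentrality is lambda = f^2 * N and power
is the upper tail of F'(k-1, N-k; lambda) beyond the central critical
value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps


@dataclass
class StatsResult:
    statistic_name: str          # "F" or "H"
    statistic: float
    df1: float
    df2: float
    p_value: float
    eta_p_sq: Optional[float] = None
    effect: Optional[str] = None

    def __str__(self) -> str:
        df2 = f"{self.df2:g}" if float(self.df2).is_integer() else f"{self.df2:.2f}"
        s = f"{self.statistic_name}({self.df1:g}, {df2}) = {self.statistic:.2f}, p = {self.p_value:.4g}"
        if self.eta_p_sq is not None:
            s += f", eta_p^2 = {self.eta_p_sq:.3f}"
        return s


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the a-priori power computation for a one-way fixed-effects
    ANOVA with k equal groups."""

    effect_size_f: float = 0.25
    alpha: float = 0.05
    power: float = 0.80
    k_groups: int = 3

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")


def _as_groups(groups: Sequence[Sequence[float]], min_size: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(gs):
        if g.ndim != 1 or len(g) < min_size:
            raise ValueError(f"group {i} needs at least {min_size} values")
    return gs


def oneway_anova(groups: Sequence[Sequence[float]]) -> StatsResult:
    """Classical one-way fixed-effects ANOVA with partial eta squared.

    F on (k-1, N-k) df; eta_p^2 = SS_between / (SS_between + SS_within).
    If every group has zero variance and all means are equal, F is 0 by
    convention; with zero within-variance but separated means F is
    infinite.
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    means = np.array([g.mean() for g in gs])
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df1, df2 = k - 1, n_total - k
    if ss_w == 0.0:
        if ss_b == 0.0:
            return StatsResult("F", 0.0, df1, df2, 1.0, 0.0)
        return StatsResult("F", math.inf, df1, df2, 0.0, 1.0)
    f = (ss_b / df1) / (ss_w / df2)
    p = float(_sps.f.sf(f, df1, df2))
    eta = ss_b / (ss_b + ss_w)
    return StatsResult("F", f, df1, df2, p, eta)


def welch_anova(groups: Sequence[Sequence[float]]) -> StatsResult:
    """Welch's heteroscedastic one-way ANOVA.

    Weights w_i = n_i / s_i^2; the denominator df is the Welch–Satterthwaite
    fraction (k^2 - 1) / (3 * Lambda).  Zero-variance groups are rejected —
    the weights are undefined there.
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs], dtype=float)
    means = np.array([g.mean() for g in gs])
    variances = np.array([g.var(ddof=1) for g in gs])
    if np.any(variances <= 0):
        bad = [i for i, v in enumerate(variances) if v <= 0]
        raise ValueError(f"welch_anova requires positive variance in every group; zero in group(s) {bad}")
    w = ns / variances
    w_sum = w.sum()
    mean_w = float((w * means).sum() / w_sum)
    a = float((w * (means - mean_w) ** 2).sum()) / (k - 1)
    lam = float(np.sum((1 - w / w_sum) ** 2 / (ns - 1)))
    b = 1 + 2 * (k - 2) / (k * k - 1) * lam
    f = a / b
    df1 = k - 1
    df2 = (k * k - 1) / (3 * lam)
    p = float(_sps.f.sf(f, df1, df2))
    # eta_p^2 on the classical decomposition, as commonly reported with Welch F
    grand = float(np.concatenate(gs).mean())
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    eta = ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0
    return StatsResult("F", f, df1, df2, p, eta)


def scheirer_ray_hare(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, StatsResult]:
    """Rank-based two-factor test (Scheirer–Ray–Hare).

    All N observations are mid-ranked together; the rank sums of squares of
    the two main effects and their interaction are each divided by the
    total rank variance MS_total = SS_total / (N - 1), computed on the tied
    ranks (which is exactly the Kruskal–Wallis tie correction).  Each H is
    referred to chi-square with the corresponding factorial df.  Returns a
    dict with keys "A", "B" and "A:B".
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("values and factors must have equal length")
    n = len(y)
    if n == 0:
        raise ValueError("empty data")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    for la in a_levels:
        for lb in b_levels:
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty cell ({la!r}, {lb!r}); a complete layout is required")

    r = _sps.rankdata(y)
    grand = r.sum()
    correction = grand * grand / n
    ss_total = float((r * r).sum() - correction)
    if ss_total == 0.0:
        out = {}
        for name, df in (("A", len(a_levels) - 1), ("B", len(b_levels) - 1),
                         ("A:B", (len(a_levels) - 1) * (len(b_levels) - 1))):
            out[name] = StatsResult("H", 0.0, max(df, 1), n, 1.0, effect=name)
        return out
    ms_total = ss_total / (n - 1)

    def group_ss(labels: np.ndarray) -> float:
        s = 0.0
        for lv in np.unique(labels):
            mask = labels == lv
            s += r[mask].sum() ** 2 / mask.sum()
        return float(s - correction)

    ss_a = group_ss(fa)
    ss_b = group_ss(fb)
    cell_labels = np.array([f"{x}\x00{y_}" for x, y_ in zip(fa, fb)])
    ss_cells = group_ss(cell_labels)
    ss_ab = ss_cells - ss_a - ss_b

    out: dict[str, StatsResult] = {}
    for name, ss, df in (
        ("A", ss_a, len(a_levels) - 1),
        ("B", ss_b, len(b_levels) - 1),
        ("A:B", ss_ab, (len(a_levels) - 1) * (len(b_levels) - 1)),
    ):
        df = max(df, 1)
        h = max(ss, 0.0) / ms_total
        p = float(_sps.chi2.sf(h, df))
        # df2 slot reports N_total: the convention "H(df, N)" pairs the
        # chi-square df with the total observation count.
        out[name] = StatsResult("H", h, df, n, p, effect=name)
    return out


def _games_howell_pair(gi: np.ndarray, gj: np.ndarray, k: int) -> float:
    ni, nj = len(gi), len(gj)
    vi, vj = gi.var(ddof=1), gj.var(ddof=1)
    se2 = vi / ni + vj / nj
    if se2 == 0.0:
        return 1.0 if gi.mean() == gj.mean() else 0.0
    t = abs(gi.mean() - gj.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
    return float(_sps.studentized_range.sf(t * math.sqrt(2.0), k, df))


def pairwise_posthoc(
    groups: Sequence[Sequence[float]], method: str = "games_howell"
) -> np.ndarray:
    """All pairwise comparisons; returns a symmetric k x k matrix of
    p-values with 1.0 on the diagonal.

    ``tukey`` — Tukey HSD (equal-variance studentized range);
    ``games_howell`` — unequal-variance studentized range with
    Welch–Satterthwaite df; ``bonferroni`` — Welch t-tests with Bonferroni
    correction.
    """
    gs = _as_groups(groups)
    k = len(gs)
    p = np.ones((k, k))
    if method == "tukey":
        res = _sps.tukey_hsd(*gs)
        p = np.array(res.pvalue)
        np.fill_diagonal(p, 1.0)
        return p
    if method == "games_howell":
        for i, j in itertools.combinations(range(k), 2):
            pij = _games_howell_pair(gs[i], gs[j], k)
            p[i, j] = p[j, i] = min(pij, 1.0)
        return p
    if method == "bonferroni":
        m = k * (k - 1) // 2
        for i, j in itertools.combinations(range(k), 2):
            pij = _sps.ttest_ind(gs[i], gs[j], equal_var=False).pvalue * m
            p[i, j] = p[j, i] = min(float(pij), 1.0)
        return p
    raise ValueError(f"unknown post hoc method {method!r}")


def anova_from_window_long(long_table, metric: str, test: str = "welch") -> StatsResult:
    """One-way comparison of a metric across time windows, fed by the
    long-format per-window CSV (columns: session_id, window, metric,
    value).  Sessions are the observations, windows the groups."""
    import pandas as pd

    df = pd.read_csv(long_table) if not hasattr(long_table, "columns") else long_table
    sub = df[(df["metric"] == metric) & df["value"].notna()]
    if sub.empty:
        raise ValueError(f"no observations for metric {metric!r}")
    groups = [g["value"].to_numpy(float) for _, g in sub.groupby("window")]
    res = welch_anova(groups) if test == "welch" else oneway_anova(groups)
    res.effect = f"window:{metric}"
    return res


def results_to_table(results) -> "object":
    """ANOVA/H results as a flat table (effect, statistic name and value,
    df1, df2, p, partial eta squared), ready to write as CSV."""
    import pandas as pd

    if isinstance(results, dict):
        results = list(results.values())
    elif isinstance(results, StatsResult):
        results = [results]
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2,
                "p_value": r.p_value,
                "eta_p_sq": r.eta_p_sq,
            }
            for r in results
        ]
    )


def anova_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the one-way fixed-effects ANOVA at total sample size
    ``n_total`` under noncentrality lambda = f^2 * N."""
    k = spec.k_groups
    df1, df2 = k - 1, n_total - k
    if df2 < 1:
        return 0.0
    lam = spec.effect_size_f ** 2 * n_total
    f_crit = float(_sps.f.isf(spec.alpha, df1, df2))
    return float(_sps.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, step: Optional[int] = None) -> int:
    """Smallest total N reaching the target power.

    The default search increments N in steps of ``k_groups`` (equal
    allocation, whole groups); pass ``step=1`` for a per-unit search.
    """
    step = spec.k_groups if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    n = spec.k_groups * 2  # at least 2 per group
    if step == spec.k_groups and n % step:
        n = ((n + step - 1) // step) * step
    limit = 10_000_000
    while n <= limit:
        if anova_power(n, spec) >= spec.power:
            return n
        n += step
    raise ValueError("target power unattainable within the search limit")
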