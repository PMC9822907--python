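"""Statistical decision procedure for the morphometry read-outs.

The selection tree mirrors standard biostatistics practice for small-sample
histology panels: test each group for normality (D'Agostino–Pearson,
α = 0.05), then compare variances (F test for two groups, Bartlett for
more); if every group is normal and variances are equal, use the parametric
branch (unpaired two-tailed Student's t, or one-/two-way ANOVA with Tukey's
post hoc), otherwise the nonparametric branch (Mann–Whitney U, or
Kruskal–Wallis with Dunn's post hoc).  A Grubbs test (α = 0.05) screens
each group for a single outlier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "select_and_run_test",
    "grubbs_test",
    "grubbs_critical_value",
    "dunn_posthoc",
]

ALPHA_NORMALITY = 0.05
ALPHA_VARIANCE = 0.05


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None   # comparison, p_adjusted
    trace: dict = field(default_factory=dict)


def _normality_p(x: np.ndarray) -> tuple[float, str]:
    """Per-group normality p-value.

    D'Agostino–Pearson needs n ≥ 8 (its skewness component is undefined
    below that); smaller groups fall back to Shapiro–Wilk, recorded in the
    trace.
    """
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return 0.0, "constant-sample"
    if len(x) >= 8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.normaltest(x).pvalue), "dagostino-pearson"
    return float(stats.shapiro(x).pvalue), "shapiro-wilk"


def _variance_p(groups) -> tuple[float, str]:
    if len(groups) == 2:
        a, b = (np.asarray(g, float) for g in groups)
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        if v2 == 0 and v1 == 0:
            return 1.0, "F"
        if min(v1, v2) == 0:
            return 0.0, "F"
        f = v1 / v2
        d1, d2 = len(a) - 1, len(b) - 1
        p = 2 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
        return float(min(p, 1.0)), "F"
    if any(np.asarray(g, float).var(ddof=1) == 0 for g in groups):
        # degenerate: a constant group; call variances unequal unless all constant
        all_const = all(np.asarray(g, float).var(ddof=1) == 0 for g in groups)
        return (1.0 if all_const else 0.0), "bartlett"
    return float(stats.bartlett(*groups).pvalue), "bartlett"


def _tukey(groups, names) -> pd.DataFrame:
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({"comparison": f"{names[i]} vs {names[j]}",
                         "p_adjusted": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


def dunn_posthoc(groups, names=None) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal–Wallis, with
    Bonferroni adjustment and the standard mid-rank tie correction."""
    names = names or [f"g{i}" for i in range(len(groups))]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(2 * stats.norm.sf(abs(z)) * m, 1.0)
            rows.append({"comparison": f"{names[i]} vs {names[j]}",
                         "p_adjusted": float(p)})
    return pd.DataFrame(rows)


def _two_way_anova(df: pd.DataFrame):
    """Two-way ANOVA value ~ timepoint + subject via statsmodels OLS."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    model = ols("value ~ C(timepoint) + C(subject)", data=df).fit()
    tbl = sm.stats.anova_lm(model, typ=2)
    row = tbl.loc["C(timepoint)"]
    return float(row["F"]), float(row["PR(>F)"])


def select_and_run_test(groups, design: str = "one-way",
                        names=None, data: pd.DataFrame | None = None) -> StatResult:
    """Run the normality → variance → test-selection decision tree.

    ``groups`` is a list of 1-D samples (for the two-way design these are
    the per-timepoint groups used for the branch decision, and ``data`` must
    be a tidy frame with columns value/timepoint/subject supplying the
    factorial structure).  Every group needs n ≥ 3.  The decision trace
    (normality p per group, variance p, chosen branch) fully determines the
    reported test.
    """
    if design not in {"two-group", "one-way", "two-way"}:
        raise ValueError(f"unknown design {design!r}")
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group needs n >= 3 (normality test undefined below)")
    if design == "two-group" and len(groups) != 2:
        raise ValueError("two-group design requires exactly 2 groups")
    names = names or [f"g{i}" for i in range(len(groups))]

    norm = [_normality_p(g) for g in groups]
    all_normal = all(p >= ALPHA_NORMALITY for p, _ in norm)
    var_p, var_test = _variance_p(groups)
    equal_var = var_p >= ALPHA_VARIANCE
    parametric = all_normal and equal_var
    trace = {
        "normality_p": [p for p, _ in norm],
        "normality_test": [t for _, t in norm],
        "variance_p": var_p,
        "variance_test": var_test,
        "branch": "parametric" if parametric else "nonparametric",
        "design": design,
    }

    posthoc = None
    if len(groups) == 2:
        if parametric:
            r = stats.ttest_ind(groups[0], groups[1], equal_var=True)
            name = "Student's t (unpaired, two-tailed)"
        else:
            r = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "Mann-Whitney U (two-tailed)"
        stat, p = float(r.statistic), float(r.pvalue)
    else:
        if parametric:
            if design == "two-way":
                if data is None:
                    raise ValueError("two-way design needs a tidy data frame")
                stat, p = _two_way_anova(data)
                name = "two-way ANOVA (timepoint + subject) + Tukey"
            else:
                r = stats.f_oneway(*groups)
                stat, p = float(r.statistic), float(r.pvalue)
                name = "one-way ANOVA + Tukey"
            posthoc = _tukey(groups, names)
        else:
            r = stats.kruskal(*groups)
            stat, p = float(r.statistic), float(r.pvalue)
            name = "Kruskal-Wallis + Dunn"
            posthoc = dunn_posthoc(groups, names)
    return StatResult(name, stat, p, posthoc, trace)


# --------------------------------------------------------------------------
# Grubbs outlier screen
# --------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student t quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_test(sample, alpha: float = 0.05):
    """Single-outlier Grubbs test; returns the outlier's index or None.

    G = max|x − mean| / sd, compared against the two-sided critical value at
    the stated α.  At most one point is flagged per call; a zero-variance
    sample yields no outlier.
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("Grubbs: zero standard deviation, no outlier")
        return None
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical_value(n, alpha):
        return int(np.argmax(dev))
    return None
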