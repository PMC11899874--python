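"""Assumption-driven test selection for comparing NMI distributions.

The dispatcher mirrors common practice for comparing similarity scores
across groups: every group is first screened for normality
(Kolmogorov-Smirnov with the Lilliefors estimated-parameter correction) and
for equal variance (F-test for two groups; Brown-Forsythe and Bartlett for
more).  The branch taken:

* all normal, equal variance       -> t-test | one-way ANOVA + Tukey HSD
* all normal, unequal variance     -> Welch t-test | Welch ANOVA + Welch pairs
* any group non-normal             -> Mann-Whitney U | Kruskal-Wallis + Dunn
* paired design, both normal       -> paired t-test
* paired design, any non-normal    -> Wilcoxon signed-rank

When Brown-Forsythe and Bartlett disagree, unequal variance is assumed
(the conservative choice).  Every report carries the diagnostics needed to
re-derive the branch taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class GroupComparison:
    """Named samples plus the design (independent or paired)."""

    samples: dict[str, np.ndarray]
    design: str = "independent"

    def __post_init__(self) -> None:
        if self.design not in ("independent", "paired"):
            raise ValueError("design must be 'independent' or 'paired'")
        self.samples = {k: np.asarray(v, dtype=float) for k, v in self.samples.items()}
        if len(self.samples) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.samples.items():
            if vals.size < 3:
                raise ValueError(f"group {name!r} has fewer than 3 values")
        if self.design == "paired":
            sizes = {v.size for v in self.samples.values()}
            if len(sizes) != 1:
                raise ValueError("paired design requires equal group sizes")
            if len(self.samples) != 2:
                raise ValueError("paired design supports exactly 2 groups")


@dataclass
class TestReport:
    """The chosen test, its result, and the diagnostics that selected it."""

    chosen_test: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None
    normality_p: dict[str, float]
    variance_test: str
    variance_p: dict[str, float]
    all_normal: bool
    equal_variance: bool
    posthoc: list[dict] = field(default_factory=list)


def _normality(samples: dict[str, np.ndarray]) -> dict[str, float]:
    out = {}
    for name, vals in samples.items():
        if np.ptp(vals) == 0:
            out[name] = 0.0   # a constant sample is not plausibly normal
        else:
            out[name] = float(lilliefors(vals, dist="norm")[1])
    return out


def _variance_two(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of two variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return 0.0
    if va >= vb:
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return float(min(p, 1.0))


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, tuple[float, float], float]:
    import pingouin as pg

    values = np.concatenate(groups)
    labels = np.concatenate([[i] * g.size for i, g in enumerate(groups)])
    df = pd.DataFrame({"value": values, "group": labels})
    res = pg.welch_anova(data=df, dv="value", between="group")
    return (
        float(res["F"].iloc[0]),
        (float(res["ddof1"].iloc[0]), float(res["ddof2"].iloc[0])),
        float(res["p_unc"].iloc[0]),
    )


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis, with tie
    correction and Bonferroni adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[n] for n in names])
    ranks = stats.rankdata(all_vals)
    n_total = all_vals.size
    mean_ranks, sizes, start = {}, {}, 0
    for n in names:
        k = groups[n].size
        mean_ranks[n] = ranks[start : start + k].mean()
        sizes[n] = k
        start += k
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
            out.append({"test": "Dunn", "groups": (a, b),
                        "statistic": float(z), "p_value": float(p)})
    return out


def compare_groups(
    data: GroupComparison, alpha: float = 0.05
) -> TestReport:
    """Route a group comparison through the assumption-based decision tree."""
    samples = data.samples
    names = list(samples)
    groups = [samples[n] for n in names]
    norm_p = _normality(samples)
    all_normal = all(p >= alpha for p in norm_p.values())

    if data.design == "paired":
        a, b = groups
        if all_normal:
            stat, p = stats.ttest_rel(a, b)
            return TestReport("paired t-test", float(stat), float(p),
                              float(a.size - 1), norm_p, "none", {},
                              all_normal, True)
        stat, p = stats.wilcoxon(a, b)
        return TestReport("Wilcoxon signed-rank", float(stat), float(p), None,
                          norm_p, "none", {}, all_normal, True)

    if len(groups) == 2:
        var_test, var_p = "F-test", {"F": _variance_two(*groups)}
        equal_var = var_p["F"] >= alpha
    else:
        bf = stats.levene(*groups, center="median")       # Brown-Forsythe
        bart = stats.bartlett(*groups)
        var_test = "Brown-Forsythe + Bartlett"
        var_p = {"Brown-Forsythe": float(bf.pvalue), "Bartlett": float(bart.pvalue)}
        equal_var = all(p >= alpha for p in var_p.values())

    if not all_normal:
        if len(groups) == 2:
            stat, p = stats.mannwhitneyu(*groups, alternative="two-sided")
            return TestReport("Mann-Whitney", float(stat), float(p), None,
                              norm_p, var_test, var_p, all_normal, equal_var)
        stat, p = stats.kruskal(*groups)
        posthoc = _dunn_posthoc(samples)
        return TestReport("Kruskal-Wallis", float(stat), float(p),
                          float(len(groups) - 1), norm_p, var_test, var_p,
                          all_normal, equal_var, posthoc)

    if len(groups) == 2:
        a, b = groups
        if equal_var:
            stat, p = stats.ttest_ind(a, b)
            return TestReport("t-test", float(stat), float(p),
                              float(a.size + b.size - 2), norm_p, var_test,
                              var_p, all_normal, equal_var)
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestReport("Welch t-test", float(res.statistic),
                          float(res.pvalue), float(res.df), norm_p, var_test,
                          var_p, all_normal, equal_var)

    if equal_var:
        stat, p = stats.f_oneway(*groups)
        tukey = stats.tukey_hsd(*groups)
        posthoc = [
            {"test": "Tukey HSD", "groups": (names[i], names[j]),
             "statistic": float(tukey.statistic[i, j]),
             "p_value": float(tukey.pvalue[i, j])}
            for i in range(len(names)) for j in range(i + 1, len(names))
        ]
        df = (float(len(groups) - 1), float(sum(g.size for g in groups) - len(groups)))
        return TestReport("one-way ANOVA", float(stat), float(p), df,
                          norm_p, var_test, var_p, all_normal, equal_var, posthoc)

    stat, df, p = _welch_anova(groups)
    posthoc = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            posthoc.append({"test": "Welch t-test", "groups": (names[i], names[j]),
                            "statistic": float(res.statistic),
                            "p_value": float(res.pvalue)})
    return TestReport("Welch ANOVA", stat, p, df, norm_p, var_test, var_p,
                      all_normal, equal_var, posthoc)
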