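"""Statistical dispatch for band-power and canonical-variable comparisons.

The branch choice follows a normality gate: a Lilliefors-corrected
Kolmogorov-Smirnov test per group (parameters are estimated from the
data, so the plain KS null distribution would be too lenient).  If every
group is compatible with normality the parametric branch runs (ANOVA or
t-test, Bonferroni-adjusted pairwise t-tests post hoc); otherwise the
rank branch runs (Kruskal-Wallis or Mann-Whitney, Bonferroni-adjusted
pairwise Mann-Whitney post hoc).  Descriptives report mean with t-based
CI on the parametric branch, median with bootstrap percentile CI on the
rank branch.  Family-wise correction is applied only within the
post-hoc family of one comparison, not across bands or nerves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors

from .errors import ArgumentError, InsufficientDataError

BOOTSTRAP_RESAMPLES = 2000


@dataclass(frozen=True)
class ComparisonDesign:
    """Options steering one comparison (the 'design' of the dispatch)."""

    alpha: float = 0.05
    paired: bool = False
    force_gate: str | None = None  # 'parametric' | 'nonparametric' | None (auto)
    bootstrap_seed: int = 0


@dataclass
class GroupDescriptives:
    group: str
    n: int
    center: float  # mean (parametric) or median (nonparametric)
    ci_low: float
    ci_high: float
    kind: str  # 'mean' | 'median'


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    branch: str  # 'parametric' | 'nonparametric'
    posthoc: pd.DataFrame | None = None
    descriptives: list[GroupDescriptives] = field(default_factory=list)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m*p)."""
    return min(1.0, m * p)


def normality_gate(samples_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """'parametric' iff every group passes the Lilliefors KS normality test."""
    for name, x in samples_by_group.items():
        if len(np.asarray(x)) < 3:
            raise InsufficientDataError(
                f"group {name!r} has only {len(np.asarray(x))} values; "
                "need >= 3 for the normality gate"
            )
    for name, x in samples_by_group.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            return "nonparametric"  # degenerate: KS undefined, normality untenable
        if len(x) >= 4:
            _, p = lilliefors(x, dist="norm")
        else:
            # the Lilliefors table starts at n=4; Shapiro-Wilk covers n=3
            _, p = sstats.shapiro(x)
        if p < alpha:
            return "nonparametric"
    return "parametric"


def confidence_interval(
    samples,
    level: float = 0.95,
    method: str = "auto",
    seed: int = 0,
) -> tuple[float, float]:
    """CI of the mean (t-based) or of the median (bootstrap percentile).

    ``method='auto'`` runs the normality gate on the single sample.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ArgumentError("need at least 2 values for a confidence interval")
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    if method == "auto":
        method = "mean" if (len(x) >= 3 and normality_gate({"_": x}) == "parametric") else "median"
    if method == "mean":
        sem = x.std(ddof=1) / np.sqrt(len(x))
        t = sstats.t.ppf(0.5 + level / 2.0, df=len(x) - 1)
        m = x.mean()
        return float(m - t * sem), float(m + t * sem)
    if method == "median":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(x), size=(BOOTSTRAP_RESAMPLES, len(x)))
        meds = np.median(x[idx], axis=1)
        lo, hi = np.percentile(meds, [50 * (1 - level), 50 * (1 + level)])
        return float(lo), float(hi)
    raise ArgumentError("method must be 'auto', 'mean' or 'median'")


def _descriptives(groups: dict[str, np.ndarray], branch: str, level: float, seed: int):
    out = []
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        if branch == "parametric":
            lo, hi = confidence_interval(x, level, method="mean")
            out.append(GroupDescriptives(name, len(x), float(np.mean(x)), lo, hi, "mean"))
        else:
            lo, hi = confidence_interval(x, level, method="median", seed=seed)
            out.append(GroupDescriptives(name, len(x), float(np.median(x)), lo, hi, "median"))
    return out


def _pairwise(groups: dict[str, np.ndarray], branch: str, design: ComparisonDesign) -> pd.DataFrame:
    names = list(groups)
    m = comb(len(names), 2)
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if branch == "parametric":
            if design.paired:
                stat, p = sstats.ttest_rel(xa, xb)
                test = "paired t-test"
            else:
                stat, p = sstats.ttest_ind(xa, xb)
                test = "t-test"
        else:
            if design.paired:
                stat, p = sstats.wilcoxon(xa, xb)
                test = "Wilcoxon signed-rank"
            else:
                stat, p = sstats.mannwhitneyu(xa, xb, alternative="two-sided")
                test = "Mann-Whitney U"
        p_adj = bonferroni(float(p), m)
        rows.append(
            {
                "pair": f"{a}|{b}",
                "test": test,
                "statistic": float(stat),
                "p_value": float(p),
                "p_adjusted": p_adj,
                "significant": p_adj < design.alpha,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    samples_by_group: dict[str, np.ndarray],
    design: ComparisonDesign = ComparisonDesign(),
) -> ComparisonResult:
    """Gate on normality, then run the matching omnibus test and post hocs."""
    groups = {k: np.asarray(v, dtype=float) for k, v in samples_by_group.items()}
    if len(groups) < 2:
        raise ArgumentError("need at least 2 groups to compare")

    branch = design.force_gate or normality_gate(groups, design.alpha)
    if branch == "parametric" and any(np.ptp(x) == 0 for x in groups.values()):
        warnings.warn(
            "degenerate (zero-variance) group on the parametric branch; "
            "switching to nonparametric",
            RuntimeWarning,
            stacklevel=2,
        )
        branch = "nonparametric"

    values = list(groups.values())
    if np.ptp(np.concatenate(values)) == 0:
        # all observations identical: no evidence of any difference
        result = ComparisonResult("degenerate", 0.0, 1.0, design.alpha, False, branch)
        result.descriptives = _descriptives(groups, branch, 0.95, design.bootstrap_seed)
        return result

    posthoc = None
    if len(groups) == 2:
        a, b = values
        if branch == "parametric":
            if design.paired:
                stat, p = sstats.ttest_rel(a, b)
                name = "paired t-test"
            else:
                stat, p = sstats.ttest_ind(a, b)
                name = "t-test"
        else:
            if design.paired:
                stat, p = sstats.wilcoxon(a, b)
                name = "Wilcoxon signed-rank"
            else:
                stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
                name = "Mann-Whitney U"
    else:
        if branch == "parametric":
            stat, p = sstats.f_oneway(*values)
            name = "one-way ANOVA"
        else:
            stat, p = sstats.kruskal(*values)
            name = "Kruskal-Wallis"
        posthoc = _pairwise(groups, branch, design)

    result = ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        alpha=design.alpha,
        significant=float(p) < design.alpha,
        branch=branch,
        posthoc=posthoc,
    )
    result.descriptives = _descriptives(groups, branch, 0.95, design.bootstrap_seed)
    return result
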