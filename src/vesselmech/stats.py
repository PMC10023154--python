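"""Group statistics and headline arithmetic.

Group comparisons use one- or two-way ANOVA with Bonferroni-adjusted
pairwise t-tests (all group pairs within a metric form the adjustment
family); descriptives are reported as mean +/- SEM.  Survival is summarized
as raw alive/total fractions; headline ratios follow the printed-precision
conventions (fold changes to one decimal, percent reductions to the nearest
integer, survival to the nearest integer at >= 50% and one decimal below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "survival_fraction",
           "fold_change", "percent_reduction", "significance_stars",
           "survival_curve"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


@dataclass
class GroupComparison:
    metric: str
    design: str
    group_stats: dict              # group -> (mean, sem, n)
    anova_F: float
    anova_p: float
    pairwise: dict = field(default_factory=dict)  # (g1, g2) -> adjusted p
    stars: dict = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05):
        return [pair for pair, p in self.pairwise.items() if p < alpha]


def _bonferroni(p_raw: float, m: int) -> float:
    return float(min(1.0, m * p_raw))


def compare_groups(table: pd.DataFrame, metric: str = "value",
                   group_col: str = "group", design: str = "one_way",
                   factor2: str | None = None) -> GroupComparison:
    """ANOVA plus Bonferroni pairwise contrasts on a long-format table.

    ``table`` must hold one observation per row with columns
    ``[group_col, metric]`` (plus ``factor2`` for the two-way design).
    The two-way design tests main effects and interaction via an OLS fit
    (type-II sums of squares); the reported F/p are for ``group_col``.
    """
    groups = {g: sub[metric].to_numpy(dtype=float)
              for g, sub in table.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two observations per group")

    if design == "one_way":
        F, p = sps.f_oneway(*groups.values())
    elif design == "two_way":
        if factor2 is None:
            raise ValueError("two_way design requires factor2")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = table.rename(columns={group_col: "g1", factor2: "g2",
                                   metric: "y"})
        model = smf.ols("y ~ C(g1) * C(g2)", data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        F = float(aov.loc["C(g1)", "F"])
        p = float(aov.loc["C(g1)", "PR(>F)"])
    else:
        raise ValueError(f"unknown design {design!r}")

    pairs = list(combinations(sorted(groups), 2))
    m = len(pairs)
    pairwise, stars = {}, {}
    for g1, g2 in pairs:
        _, p_raw = sps.ttest_ind(groups[g1], groups[g2])
        if np.isnan(p_raw):  # zero variance in both samples, identical means
            p_raw = 1.0
        p_adj = _bonferroni(float(p_raw), m)
        pairwise[(g1, g2)] = p_adj
        stars[(g1, g2)] = significance_stars(p_adj)

    group_stats = {g: (float(np.mean(v)), float(sps.sem(v)), len(v))
                   for g, v in groups.items()}
    return GroupComparison(metric=metric, design=design,
                           group_stats=group_stats,
                           anova_F=float(F), anova_p=float(p),
                           pairwise=pairwise, stars=stars)


def survival_fraction(n_alive: int, n_total: int) -> float:
    """Percent survival at the printed precision: nearest integer when
    >= 50%, one decimal below 50%."""
    n_alive, n_total = float(n_alive), float(n_total)
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_alive <= n_total:
        raise ValueError("need 0 <= n_alive <= n_total")
    pct = 100.0 * n_alive / n_total
    q = Decimal("1") if pct >= 50 else Decimal("0.1")
    return float(Decimal(repr(pct)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(numerator: float, denominator: float) -> float:
    """Ratio rounded half-up to one decimal."""
    numerator, denominator = float(numerator), float(denominator)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float(Decimal(repr(numerator / denominator))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_reduction(reference: float, value: float) -> int:
    """Percent reduction from reference, rounded half-up to an integer."""
    reference, value = float(reference), float(value)
    if reference <= 0:
        raise ValueError("reference must be positive")
    pct = 100.0 * (reference - value) / reference
    return int(Decimal(repr(pct)).quantize(Decimal("1"),
                                           rounding=ROUND_HALF_UP))


def survival_curve(n_total: int, death_days, horizon: int = 170):
    """Fraction alive at each day 0..horizon from a death-day list.

    Censoring is not modeled (the study reports raw fractions); the curve
    is non-increasing by construction.
    """
    days = np.arange(horizon + 1)
    deaths = np.asarray(sorted(death_days), dtype=float)
    alive = n_total - np.searchsorted(deaths, days, side="right")
    return pd.DataFrame({"day": days, "fraction_alive": alive / n_total})
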