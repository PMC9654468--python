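"""Construct validity and internal consistency of the questionnaire score.

Construct validity: Spearman rank correlations between each sub-score (and
the total) and the matching model-based usual-intake variable; linear trend
of intake across total-score quartiles.  Internal consistency: raw and
standardized Cronbach's alpha over the score's components.  Group contrasts
(sex, age band, 1 vs 2+ recalls) are Shapiro–Wilk gated: a t test when both
groups look normal, otherwise the rank-sum test; three or more groups get a
one-way ANOVA with Bonferroni-corrected pairwise follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ConstantInputError(ValueError):
    """A statistic is undefined because an input vector is constant."""


# -- correlations --------------------------------------------------------------

def spearman(x, y) -> tuple[float, float, int]:
    """Spearman's ρ with a two-sided p from the t approximation (n−2 df).

    Ties receive average ranks.  A constant vector makes ρ undefined and
    raises rather than silently returning 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def cronbach_alpha(items: np.ndarray) -> tuple[float, float]:
    """Raw and standardized Cronbach's alpha of a participants × items matrix.

    raw α = k/(k−1)·(1 − Σ item variances / variance of row sums);
    standardized α = k·r̄/(1 + (k−1)·r̄) with r̄ the mean off-diagonal Pearson
    correlation.  Variances use the unbiased (n−1) denominator.
    """
    m = np.asarray(items, float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-d matrix with k >= 2 items")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    k = m.shape[1]
    total_var = float(np.var(m.sum(axis=1), ddof=1))
    if total_var <= 0:
        raise ConstantInputError("zero total-score variance")
    item_vars = np.var(m, axis=0, ddof=1)
    if np.any(item_vars <= 0):
        raise ConstantInputError("an item has zero variance")
    alpha_raw = k / (k - 1) * (1.0 - float(item_vars.sum()) / total_var)
    r = np.corrcoef(m, rowvar=False)
    r_bar = float((r.sum() - k) / (k * (k - 1)))
    alpha_std = k * r_bar / (1.0 + (k - 1) * r_bar)
    return alpha_raw, alpha_std


# -- trends and group comparisons ----------------------------------------------

def quartile_trend(values, quartiles) -> tuple[float, float]:
    """OLS slope of ``values`` on quartile index (1..4 treated as numeric),
    with the two-sided t-test p for the slope.  Constant values return
    (0.0, 1.0) by convention."""
    v = np.asarray(values, float)
    q = np.asarray(quartiles, float)
    if len(np.unique(q)) < 2:
        raise ValueError("trend needs at least two distinct quartiles")
    if np.ptp(v) == 0:
        return 0.0, 1.0
    res = stats.linregress(q, v)
    return float(res.slope), float(res.pvalue)


@dataclass
class GroupTestResult:
    test: str               # "t" | "rank-sum" | "anova"
    statistic: float
    p: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    shapiro_p: tuple[float, ...] = ()


def group_compare(
    values, labels, normality_alpha: float = 0.05
) -> GroupTestResult:
    """Two-group or multi-group location comparison.

    Two groups: Shapiro–Wilk on each (at ``normality_alpha``) gates Student's
    t (both normal) vs the Wilcoxon–Mann–Whitney rank-sum test (normal
    approximation with tie correction).  Three or more groups: one-way ANOVA;
    pairwise Welch t follow-ups with Bonferroni-multiplied p values capped
    at 1.
    """
    v = np.asarray(values, float)
    labs = np.asarray(labels)
    names = [str(g) for g in dict.fromkeys(labs)]
    groups = [v[labs == g] for g in dict.fromkeys(labs)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two members")

    if len(groups) == 2:
        identical = np.ptp(v) == 0
        # Shapiro-Wilk needs n >= 3; tiny or constant groups cannot reject normality
        sw = tuple(
            1.0 if (len(g) < 3 or np.ptp(g) == 0) else float(stats.shapiro(g).pvalue)
            for g in groups
        )
        if identical:
            return GroupTestResult("t", 0.0, 1.0, shapiro_p=sw)
        if all(p > normality_alpha for p in sw):
            t, p = stats.ttest_ind(*groups)
            return GroupTestResult("t", float(t), float(p), shapiro_p=sw)
        u, p = stats.mannwhitneyu(*groups, alternative="two-sided", method="asymptotic")
        return GroupTestResult("rank-sum", float(u), float(p), shapiro_p=sw)

    f, p = stats.f_oneway(*groups)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, p_ij = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            pairwise.append((names[i], names[j], min(1.0, float(p_ij) * n_pairs)))
    return GroupTestResult("anova", float(f), float(p), pairwise=pairwise)


# -- report assembly -----------------------------------------------------------

@dataclass
class ValidityReport:
    pairs: list[dict]
    alpha_raw: float
    alpha_standardized: float
    trend: list[dict]
    group_tests: list[dict]

    def to_dict(self) -> dict:
        return {
            "validity_correlations": self.pairs,
            "alpha_raw": self.alpha_raw,
            "alpha_standardized": self.alpha_standardized,
            "quartile_trends": self.trend,
            "group_tests": self.group_tests,
        }


#: default sub-score → usual-intake variable pairing for validity correlations
DEFAULT_VALIDITY_PAIRS = {
    "cereal": "serves_grains",
    "fruit_veg": "serves_fruit_veg",
    "takeaway": "serves_discretionary",
    "fiber": "nutrient_fiber",
    "fat": "nutrient_total_fat",
    "omega3": "nutrient_omega3",
    "food_choices": "nutrient_polyunsaturated_fat",
    "food_preparation": "nutrient_total_fat",
}


def validity_report(
    scores, usual, pairs: dict[str, str] | None = None,
    alpha_mode: str = "sub_scores",
) -> ValidityReport:
    """Assemble the validity/consistency report for a scored cohort.

    ``scores``: output of :func:`dietval.scoring.score_cohort` (must contain
    total, quartile and ``sub_<name>`` columns).  ``usual``: wide usual-intake
    table with participant_id plus variable columns.  ``pairs`` maps sub-score
    (or "total") to the intake column it is validated against; pairs whose
    column is absent are skipped.  ``alpha_mode``: "sub_scores" computes
    Cronbach's alpha over the eight sub-scores (default); "items" is for
    callers that pass item-level matrices through :func:`cronbach_alpha`
    directly.
    """
    pairs = dict(DEFAULT_VALIDITY_PAIRS if pairs is None else pairs)
    merged = scores.merge(usual, on="participant_id", how="inner")

    correlations = []
    for sub_name, var in pairs.items():
        col = "total" if sub_name == "total" else f"sub_{sub_name}"
        if col not in merged.columns or var not in merged.columns:
            continue
        rho, p, n = spearman(merged[col], merged[var])
        correlations.append(
            {"score": sub_name, "variable": var, "rho": rho, "p": p, "n": n}
        )
        if sub_name != "total":
            rho_t, p_t, n_t = spearman(merged["total"], merged[var])
            correlations.append(
                {"score": "total", "variable": var, "rho": rho_t, "p": p_t, "n": n_t}
            )

    sub_cols = [c for c in scores.columns if c.startswith("sub_")]
    alpha_raw, alpha_std = cronbach_alpha(merged[sub_cols].to_numpy())

    trends = []
    intake_cols = [c for c in usual.columns if c != "participant_id"]
    for var in intake_cols:
        slope, p = quartile_trend(merged[var], merged["quartile"])
        trends.append({"variable": var, "slope": slope, "p": p})

    return ValidityReport(
        pairs=correlations,
        alpha_raw=alpha_raw,
        alpha_standardized=alpha_std,
        trend=trends,
        group_tests=[],
    )
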