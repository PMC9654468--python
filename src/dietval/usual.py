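"""Usual (habitual) intake from repeated 24-h recalls via two-part shrinkage.

A single recall day is a noisy draw around a person's habitual intake: the
observed day value mixes between-person signal with within-person day-to-day
noise.  With a subset of participants contributing repeated recalls, the two
variance components are identifiable and each person's observed mean can be
shrunk toward the population mean in proportion to its unreliability —
removing (in expectation) the day-to-day noise.

The model is two-part, as episodically consumed foods (fish, alcohol, soup…)
produce many true zero days:

* probability part — each participant's probability of consuming on a given
  day, estimated by empirical-Bayes beta-binomial shrinkage of the observed
  consuming-day fraction toward the cohort fraction;
* amount part — positive amounts are Box-Cox transformed (λ selected from a
  fixed grid by profile likelihood), variance components estimated by the
  unbalanced one-way ANOVA method of moments, person means shrunk by the
  classical reliability factor σ²_b/(σ²_b + σ²_w/nᵢ), then back-transformed
  with a second-order Taylor bias correction.

Usual intake is the product of the two parts.  Variables declared "daily"
(energy, macronutrients) skip the probability part (p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Box-Cox exponents searched by profile likelihood; 0 means log.
DEFAULT_LAMBDA_GRID = (0.0, 0.25, 1.0 / 3.0, 0.5, 1.0)

DEFAULT_WITHIN_FLOOR = 1e-8


class ShrinkageUnidentifiableError(ValueError):
    """Raised when no participant repeats a recall: the within-person variance,
    hence the shrinkage factor, cannot be estimated."""


@dataclass(frozen=True)
class VarianceComponents:
    variable: str
    lam: float            # Box-Cox exponent (0 = log)
    delta: float          # offset added before transforming
    mu: float             # population mean, transformed scale
    sigma2_b: float       # between-person variance, transformed scale
    sigma2_w: float       # within-person variance, transformed scale
    n_repeat: int         # participants contributing >=2 positive days

    def shrinkage_factor(self, n_days: int) -> float:
        if n_days <= 0:
            return 0.0
        return self.sigma2_b / (self.sigma2_b + self.sigma2_w / n_days)


@dataclass(frozen=True)
class UsualIntake:
    participant_id: str
    variable: str
    p_consume: float
    usual_amount: float
    usual: float


# -- Box-Cox ------------------------------------------------------------------

def boxcox_transform(x, lam: float, delta: float = 0.0):
    x = np.asarray(x, dtype=float) + delta
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires positive values (after offset)")
    if lam == 0.0:
        return np.log(x)
    return (x**lam - 1.0) / lam


def boxcox_inverse(t, lam: float, delta: float = 0.0):
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return np.exp(t) - delta
    base = np.maximum(lam * t + 1.0, 0.0)
    return base ** (1.0 / lam) - delta


def _inverse_second_derivative(t: float, lam: float) -> float:
    # d²/dt² of the inverse transform, used in the Taylor bias correction.
    if lam == 0.0:
        return float(np.exp(t))
    base = lam * t + 1.0
    if base <= 0:
        return 0.0
    return float((1.0 - lam) * base ** (1.0 / lam - 2.0))


def select_lambda(
    positive_values, grid=DEFAULT_LAMBDA_GRID, delta: float = 0.0
) -> float:
    """Box-Cox exponent from ``grid`` maximizing the profile log-likelihood."""
    x = np.asarray(positive_values, dtype=float)
    if x.size < 2:
        return 1.0
    best_lam, best_ll = None, -np.inf
    logx = np.log(x + delta)
    for lam in grid:
        y = boxcox_transform(x, lam, delta)
        var = float(np.var(y))
        if var <= 0:
            continue
        ll = -0.5 * x.size * np.log(var) + (lam - 1.0) * float(np.sum(logx))
        if ll > best_ll:
            best_lam, best_ll = lam, ll
    return 1.0 if best_lam is None else float(best_lam)


# -- variance components -------------------------------------------------------

def fit_components(
    values_by_participant: dict[str, np.ndarray],
    variable: str = "",
    grid=DEFAULT_LAMBDA_GRID,
    delta: float = 0.0,
    within_floor: float | None = None,
) -> VarianceComponents:
    """Variance components of positive day amounts, unbalanced one-way ANOVA.

    ``values_by_participant`` maps participant id to that person's positive
    day amounts.  Requires at least two participants with >=2 positive days;
    zero estimated within-person variance raises unless ``within_floor`` is
    given, in which case it is floored (and reported at the floor).
    """
    groups = [np.asarray(v, float) for v in values_by_participant.values() if len(v) > 0]
    n_repeat = sum(1 for g in groups if len(g) >= 2)
    if n_repeat < 2:
        raise ShrinkageUnidentifiableError(
            f"{variable or 'variable'}: needs >=2 participants with repeated "
            "positive days to separate within- from between-person variance; "
            f"found {n_repeat}"
        )
    pooled = np.concatenate(groups)
    lam = select_lambda(pooled, grid, delta)
    t_groups = [boxcox_transform(g, lam, delta) for g in groups]

    sizes = np.array([len(g) for g in t_groups], float)
    means = np.array([g.mean() for g in t_groups])
    n_total = sizes.sum()
    k = len(t_groups)
    grand = float(np.concatenate(t_groups).mean())

    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(t_groups, means)))
    msw = ssw / (n_total - k)
    ssb = float((sizes * (means - grand) ** 2).sum())
    msb = ssb / (k - 1)
    # coefficient of sigma2_b in E[MSB] for unbalanced designs
    c = (n_total - (sizes**2).sum() / n_total) / (k - 1)
    sigma2_b = max(0.0, (msb - msw) / c)

    if msw <= 0:
        if within_floor is None:
            raise ValueError(
                f"{variable or 'variable'}: within-person variance is zero; "
                "supply within_floor to proceed"
            )
        msw = within_floor
    elif within_floor is not None:
        msw = max(msw, within_floor)

    return VarianceComponents(
        variable=variable, lam=lam, delta=delta, mu=grand,
        sigma2_b=sigma2_b, sigma2_w=msw, n_repeat=n_repeat,
    )


def shrink_mean(xbar: float, n_days: int, comp: VarianceComponents) -> float:
    """Shrink a person's transformed-scale mean toward the population mean.

    tᵢ = μ + (x̄ᵢ − μ)·σ²_b/(σ²_b + σ²_w/nᵢ); with no observed days the
    population mean is returned.
    """
    if n_days <= 0:
        return comp.mu
    return comp.mu + (xbar - comp.mu) * comp.shrinkage_factor(n_days)


# -- probability part ----------------------------------------------------------

def consumption_probability(
    consuming_days: np.ndarray,
    total_days: np.ndarray,
    m_floor: float = 1.0,
    m_no_overdispersion: float = 1e6,
) -> tuple[np.ndarray, float, float]:
    """Beta-binomial shrinkage of per-person consuming-day fractions.

    Returns (pᵢ, pooled fraction p̄, prior strength m) with
    pᵢ = (cᵢ + m·p̄)/(nᵢ + m).  m comes from the method-of-moments
    between-person overdispersion of the observed fractions, floored at
    ``m_floor``; with no detectable overdispersion everyone is pooled to p̄
    (m very large).
    """
    c = np.asarray(consuming_days, float)
    n = np.asarray(total_days, float)
    if np.any(n < 1):
        raise ValueError("every participant needs at least one recall day")
    if np.any(c > n) or np.any(c < 0):
        raise ValueError("consuming days must lie in [0, total days]")
    p_bar = float(c.sum() / n.sum())
    if p_bar in (0.0, 1.0):
        return np.full(c.shape, p_bar), p_bar, np.inf
    phat = c / n
    s2 = float(np.var(phat, ddof=1)) if len(phat) > 1 else 0.0
    binom_part = p_bar * (1 - p_bar) * float(np.mean(1.0 / n))
    denom = p_bar * (1 - p_bar) * (1.0 - float(np.mean(1.0 / n)))
    rho = (s2 - binom_part) / denom if denom > 0 else 0.0
    if rho <= 0:
        m = m_no_overdispersion
    elif rho >= 1:
        m = m_floor
    else:
        m = max(m_floor, (1.0 - rho) / rho)
    p_i = (c + m * p_bar) / (n + m)
    return p_i, p_bar, float(m)


# -- back transform ------------------------------------------------------------

def usual_amount_from_shrunken(
    t_i: float, n_days: int, comp: VarianceComponents, bias_correction: bool = True
) -> float:
    """Back-transform a shrunken mean to the original scale, never negative.

    The second-order Taylor correction ½·g⁻¹″(tᵢ)·σ²_b·(1−f) accounts for the
    curvature of the inverse transform over the residual person-level
    uncertainty (f is the shrinkage factor; λ=1 has no curvature).
    """
    value = float(boxcox_inverse(t_i, comp.lam, comp.delta))
    if bias_correction:
        residual_var = comp.sigma2_b * (1.0 - comp.shrinkage_factor(n_days))
        value += 0.5 * _inverse_second_derivative(t_i, comp.lam) * residual_var
    return max(0.0, value)


# -- cohort-level model --------------------------------------------------------

class UsualIntakeModel:
    """Fit the two-part model per variable over a long day-values table.

    Input columns: participant_id, day_index, day_type, variable, value.
    Variables named in ``episodic`` get the probability part; all others are
    treated as consumed daily (p = 1).  A day with value 0 counts as a
    non-consuming day for episodic variables and is excluded from the amount
    part either way.
    """

    def __init__(
        self,
        episodic: set[str] | frozenset[str] = frozenset(),
        lambda_grid=DEFAULT_LAMBDA_GRID,
        delta: float = 0.0,
        within_floor: float | None = DEFAULT_WITHIN_FLOOR,
        bias_correction: bool = True,
        weekday_weighting: bool = False,
    ):
        self.episodic = frozenset(episodic)
        self.lambda_grid = tuple(lambda_grid)
        self.delta = delta
        self.within_floor = within_floor
        self.bias_correction = bias_correction
        self.weekday_weighting = weekday_weighting
        self.components_: dict[str, VarianceComponents] = {}
        self.probability_: dict[str, tuple[float, float]] = {}  # (p_bar, m)
        self.skipped_: dict[str, str] = {}  # variable → reason

    def _person_mean(self, values: np.ndarray, day_types: np.ndarray, lam: float) -> float:
        t = boxcox_transform(values, lam, self.delta)
        if self.weekday_weighting and len(set(day_types)) > 1:
            w = np.where(np.asarray(day_types) == "weekend", 2.0, 5.0)
            return float(np.average(t, weights=w))
        return float(t.mean())

    def fit_predict(self, day_values: pd.DataFrame) -> pd.DataFrame:
        """Fit components per variable and return per-participant usual intakes.

        Output: one row per participant (ordered by first appearance), one
        column per variable holding usual = p_consume × usual_amount.
        """
        participants = list(dict.fromkeys(day_values["participant_id"].astype(str)))
        out = pd.DataFrame({"participant_id": participants}).set_index("participant_id")
        for var, sub in day_values.groupby("variable", sort=False):
            try:
                res = self._fit_one(var, sub, participants)
            except ShrinkageUnidentifiableError as err:
                # e.g. a variable nobody (or only one person) ever consumed
                self.skipped_[str(var)] = str(err)
                continue
            out[var] = [res[p].usual for p in participants]
        return out.reset_index()

    def _fit_one(
        self, var: str, sub: pd.DataFrame, participants: list[str]
    ) -> dict[str, UsualIntake]:
        sub = sub.assign(participant_id=sub["participant_id"].astype(str))
        episodic = var in self.episodic
        by_pid: dict[str, pd.DataFrame] = {
            pid: grp for pid, grp in sub.groupby("participant_id", sort=False)
        }
        pos_by_pid = {
            pid: grp.loc[grp["value"] > 0, "value"].to_numpy()
            for pid, grp in by_pid.items()
        }
        comp = fit_components(
            pos_by_pid, var, self.lambda_grid, self.delta, self.within_floor
        )
        self.components_[var] = comp

        if episodic:
            ids = list(by_pid)
            c = np.array([(by_pid[p]["value"] > 0).sum() for p in ids], float)
            n = np.array([len(by_pid[p]) for p in ids], float)
            p_i, p_bar, m = consumption_probability(c, n)
            p_map = dict(zip(ids, p_i))
            self.probability_[var] = (p_bar, m)
        else:
            p_map = {}
            self.probability_[var] = (1.0, np.inf)

        results: dict[str, UsualIntake] = {}
        for pid in participants:
            grp = by_pid.get(pid)
            pos = pos_by_pid.get(pid, np.asarray([], float))
            n_pos = len(pos)
            if n_pos:
                xbar = self._person_mean(
                    pos,
                    grp.loc[grp["value"] > 0, "day_type"].to_numpy(),
                    comp.lam,
                )
            else:
                xbar = comp.mu  # population fallback for never-consumers
            t_i = shrink_mean(xbar, n_pos, comp)
            amount = usual_amount_from_shrunken(t_i, n_pos, comp, self.bias_correction)
            p = float(p_map.get(pid, 1.0)) if episodic else 1.0
            results[pid] = UsualIntake(pid, var, p, amount, max(0.0, p * amount))
        return results
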