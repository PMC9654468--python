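"""Synthetic cohorts with known ground truth for end-to-end validation.

Every statistical structure the pipeline assumes is planted explicitly:

* a latent diet-quality trait z ~ N(0,1) per participant drives both the
  questionnaire answers (through per-sub-score item loadings) and the
  person-level intake effects, inducing a *target* correlation between each
  sub-score and its matching usual-intake variable;
* daily food-group gram amounts are zero-inflated log-normal: a person-level
  effect (mixing the trait, planted pattern-factor scores and a unique part)
  plus independent day-to-day noise, with day-level consumption an
  informative probit of the same latent;
* the person-level effects across the 17 major food groups mix 5 orthogonal
  pattern factors through a block loading matrix, so data-driven pattern
  extraction has a known answer;
* the recall design mirrors a cohort in which only a fraction of participants
  contribute a second (weekend) recall day.

The trait→item loadings cannot be written in closed form for arbitrary
category ladders, so they are calibrated by a deterministic monotone
bisection: the generator simulates the observable chain (sub-score vs. the
two-part-shrinkage usual-intake estimate under the cohort's recall design) on
an internal calibration sample and searches the loading that attains the
target correlation, raising with the attainable bound when the target is out
of reach.  The planted correlation is therefore defined on the quantity the
pipeline actually estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import SUB_SCORES, DhqSchema, score_item
from .usual import UsualIntakeModel

#: sub-score → usual-intake variable used for calibration and validity checks
SUB_SCORE_VARIABLES = {
    "cereal": "serves_grains",
    "fruit_veg": "serves_fruit_veg",
    "takeaway": "serves_discretionary",
    "fiber": "nutrient_fiber",
    "fat": "nutrient_total_fat",
    "omega3": "nutrient_omega3",
    "food_choices": "nutrient_polyunsaturated_fat",
    "food_preparation": "nutrient_total_fat",
}

#: variables treated as episodically consumed by default (zero days possible)
EPISODIC_VARIABLES = frozenset(
    {
        "serves_vegetables",
        "serves_fruits",
        "serves_grains",
        "serves_milk_alt",
        "serves_meat_alt",
        "serves_discretionary",
        "serves_fruit_veg",
        "nutrient_omega3",
        "nutrient_alcohol",
    }
)

NUTRIENTS = (
    "protein",
    "carbohydrate",
    "total_fat",
    "saturated_fat",
    "polyunsaturated_fat",
    "omega3",
    "fiber",
    "alcohol",
)

N_FACTORS = 5


class InfeasibleTargetError(ValueError):
    """A target sub-score↔intake correlation exceeds what the item ladders and
    intake model can attain; the message reports the attainable bound."""


@dataclass(frozen=True)
class FoodGroupSpec:
    """One major food group: its representative food's composition, serve
    weights (serves per 100 g), zero-inflated log-normal intake model and its
    links to the diet-quality trait and the planted pattern factors."""

    name: str
    code: str                       # 2-digit hierarchical major-group code
    base_grams: float               # median positive-day amount, g
    sigma_b: float                  # between-person SD, log scale
    sigma_w: float                  # within-person SD, log scale
    p_consume: float                # marginal day-level consumption probability
    trait_weight: float             # share of person effect carried by z
    factor_loadings: tuple[float, ...] = (0.0,) * N_FACTORS
    energy_kj_per_100g: float = 0.0
    nutrients: dict[str, float] = field(default_factory=dict)  # g per 100 g
    serve_weights: dict[str, float] = field(default_factory=dict)
    discretionary: bool = False

    def unique_weight(self) -> float:
        rest = 1.0 - self.trait_weight**2 - float(np.sum(np.square(self.factor_loadings)))
        if rest < -1e-9:
            raise ValueError(f"{self.name}: trait weight and loadings exceed unit variance")
        return float(np.sqrt(max(0.0, rest)))


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int = 96
    p_repeat_recall: float = 0.3125     # 30 of 96 with a second recall day
    seed: int = 0
    trait_targets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_TARGETS))
    groups: tuple[FoodGroupSpec, ...] = ()
    consumption_link: float = 0.75      # probit link of consumption to intake latent
    female_fraction: float = 0.823      # cohort shape only; carries no effect
    age_bands: tuple[tuple[str, float], ...] = (
        ("33-44", 20 / 96),
        ("45-64", 67 / 96),
        ("65-86", 9 / 96),
    )
    calibration_n: int = 1500
    calibration_tol: float = 0.01
    calibration_max_iter: int = 25

    def __post_init__(self):
        if not (0 <= self.p_repeat_recall <= 1):
            raise ValueError("p_repeat_recall must lie in [0,1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not self.groups:
            object.__setattr__(self, "groups", default_food_groups())


#: default planted sub-score ↔ usual-intake correlations (the study conditions)
DEFAULT_TRAIT_TARGETS = {
    "cereal": 0.40,
    "fruit_veg": 0.45,
    "takeaway": -0.30,
    "fiber": 0.50,
    "fat": -0.086,
    "omega3": 0.40,
    "food_choices": -0.10,
    "food_preparation": -0.10,
}


def default_food_groups() -> tuple[FoodGroupSpec, ...]:
    """The 17 major food groups with their planted 5-factor block structure.

    Factor blocks: 1 miscellaneous/sugar; 2 special-dietary/alcohol/fats;
    3 fruit/fish/substitutes; 4 milk/meat/(−)soup; 5 confectionery/cereals/
    vegetables/beverages.  Each group loads exactly one factor so the loading
    matrix columns are orthogonal by construction.
    """
    L = lambda j, v: tuple(v if i == j else 0.0 for i in range(N_FACTORS))
    g = FoodGroupSpec
    return (
        g("non_alcoholic_beverages", "11", 1200, 0.40, 0.25, 0.95, 0.0, L(4, 0.50),
          80, {"carbohydrate": 2.0}),
        g("cereals", "12", 150, 0.45, 0.30, 0.90, 0.55, L(4, 0.63),
          1200, {"fiber": 8.0, "carbohydrate": 60.0, "protein": 10.0, "total_fat": 2.0},
          {"grains": 2.5}),
        g("cereal_based_dishes", "13", 120, 0.45, 0.35, 0.50, 0.45, L(0, 0.0),
          900, {"fiber": 4.0, "carbohydrate": 30.0, "protein": 8.0, "total_fat": 8.0,
                "saturated_fat": 3.0},
          {"grains": 1.0}),
        g("fats_and_oils", "14", 45, 0.45, 0.35, 0.90, -0.50, L(1, 0.62),
          3000, {"total_fat": 80.0, "saturated_fat": 25.0, "polyunsaturated_fat": 30.0,
                 "omega3": 0.05}),
        g("fish_and_seafood", "15", 90, 0.55, 0.30, 0.70, 0.70, L(2, 0.65),
          700, {"protein": 20.0, "total_fat": 5.0, "polyunsaturated_fat": 2.0,
                "omega3": 1.5},
          {"meat_alt": 1.0}),
        g("fruit", "16", 250, 0.45, 0.30, 0.90, 0.55, L(2, 0.70),
          250, {"fiber": 2.5, "carbohydrate": 12.0},
          {"fruits": 0.667}),
        g("eggs", "17", 45, 0.40, 0.35, 0.50, 0.10, L(0, 0.0),
          550, {"protein": 13.0, "total_fat": 10.0, "saturated_fat": 3.0, "omega3": 0.1},
          {"meat_alt": 0.833}),
        g("meat_poultry_game", "18", 120, 0.45, 0.30, 0.80, 0.0, L(3, 0.60),
          800, {"protein": 25.0, "total_fat": 10.0, "saturated_fat": 4.0},
          {"meat_alt": 1.54}),
        g("milk_products", "19", 250, 0.45, 0.30, 0.90, 0.15, L(3, 0.79),
          300, {"protein": 3.3, "total_fat": 4.0, "saturated_fat": 2.5, "carbohydrate": 5.0},
          {"milk_alt": 0.4}),
        g("dairy_meat_substitutes", "20", 100, 0.50, 0.35, 0.60, 0.25, L(2, 0.68),
          250, {"protein": 4.0},
          {"milk_alt": 0.4}),
        g("soup", "21", 250, 0.50, 0.35, 0.50, 0.10, L(3, -0.40),
          150, {"fiber": 1.0, "protein": 2.0},
          {"vegetables": 0.3}),
        g("vegetables", "24", 300, 0.45, 0.30, 0.97, 0.55, L(4, 0.55),
          150, {"fiber": 3.5, "carbohydrate": 6.0, "protein": 2.0},
          {"vegetables": 1.333}),
        g("sugar_products", "27", 30, 0.55, 0.35, 0.80, -0.45, L(0, 0.81),
          1600, {"carbohydrate": 90.0}, discretionary=True),
        g("confectionery", "28", 40, 0.55, 0.35, 0.70, -0.45, L(4, 0.84),
          2000, {"carbohydrate": 60.0, "total_fat": 25.0, "saturated_fat": 15.0},
          discretionary=True),
        g("alcoholic_beverages", "29", 200, 0.50, 0.35, 0.45, -0.35, L(1, 0.73),
          300, {"carbohydrate": 3.0, "alcohol": 5.0}, discretionary=True),
        g("special_dietary_foods", "30", 20, 0.55, 0.35, 0.50, 0.10, L(1, 0.81),
          1500, {"total_fat": 30.0, "polyunsaturated_fat": 15.0, "omega3": 0.5}),
        g("miscellaneous", "31", 15, 0.50, 0.30, 0.85, -0.15, L(0, 0.82),
          1000, {"carbohydrate": 20.0, "protein": 5.0}),
    )


# -- truth ---------------------------------------------------------------------

@dataclass
class TruthTable:
    participants: pd.DataFrame    # z, sex, age_band, factor scores, true usual
    item_loadings: dict[str, float]
    group_params: pd.DataFrame


@dataclass
class SyntheticCohort:
    questionnaire: pd.DataFrame   # participant_id, item_id, category
    recalls: pd.DataFrame         # participant_id, day_index, day_type, food_code, grams
    foods: pd.DataFrame           # composition table schema
    components: pd.DataFrame      # composite recipes (empty for generated cohorts)
    participants: pd.DataFrame    # participant_id, sex, age_band
    truth: TruthTable


# -- generator -----------------------------------------------------------------

class CohortGenerator:
    """Deterministic cohort factory; calibration is computed once per spec."""

    _CALIBRATION_SEED = 202_20_31   # internal; independent of cohort seeds

    def __init__(self, spec: CohortSpec, schema: DhqSchema | None = None):
        self.spec = spec
        self.schema = schema or DhqSchema.default()
        self._loadings: dict[str, float] | None = None
        self._groups = list(spec.groups)
        codes = [g.code for g in self._groups]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate food-group codes")

    # -- composition fixture ---------------------------------------------------

    def composition_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rows = []
        for g in self._groups:
            row = {
                "food_code": f"F{g.code}",
                "description": g.name.replace("_", " "),
                "major_group_code": g.code,
                "energy_kj_per_100g": g.energy_kj_per_100g,
                "discretionary": g.discretionary,
            }
            for n in NUTRIENTS:
                row[f"nutrient_{n}"] = g.nutrients.get(n, 0.0)
            for s in ("vegetables", "fruits", "grains", "milk_alt", "meat_alt"):
                row[f"serve_{s}"] = g.serve_weights.get(s, 0.0)
            rows.append(row)
        return pd.DataFrame(rows), pd.DataFrame(
            columns=["parent_code", "component_code", "fraction"]
        )

    # -- intake simulation -----------------------------------------------------

    def _person_effects(self, rng: np.random.Generator, n: int):
        """Latent trait, factor scores and standardized person effects B (n × groups)."""
        z = rng.standard_normal(n)
        f = rng.standard_normal((n, N_FACTORS))
        eta = rng.standard_normal((n, len(self._groups)))
        B = np.empty((n, len(self._groups)))
        for j, g in enumerate(self._groups):
            lam = np.asarray(g.factor_loadings)
            B[:, j] = g.trait_weight * z + f @ lam + g.unique_weight() * eta[:, j]
        return z, f, B

    def _day_grams(
        self, rng: np.random.Generator, B: np.ndarray, day_rows: np.ndarray
    ) -> np.ndarray:
        """Gram amounts for the given person rows (one call per recall day)."""
        n = len(day_rows)
        k = len(self._groups)
        eps = rng.standard_normal((n, k))
        xi = rng.standard_normal((n, k))
        a = self.spec.consumption_link
        grams = np.empty((n, k))
        for j, g in enumerate(self._groups):
            sigma_tot = np.hypot(g.sigma_b, g.sigma_w)
            s = (g.sigma_b * B[day_rows, j] + g.sigma_w * eps[:, j]) / sigma_tot
            tau = a * s + np.sqrt(1.0 - a**2) * xi[:, j]
            consumed = tau > sps.norm.ppf(1.0 - g.p_consume)
            amount = g.base_grams * np.exp(
                g.sigma_b * B[day_rows, j] + g.sigma_w * eps[:, j]
            )
            grams[:, j] = np.where(consumed, amount, 0.0)
        return grams

    def _true_usual_grams(self, B: np.ndarray) -> np.ndarray:
        """Exact E[day grams | person] per group (consumption and amount share
        the day noise, handled by exponential tilting of the probit)."""
        a = self.spec.consumption_link
        out = np.empty_like(B)
        for j, g in enumerate(self._groups):
            sigma_tot = np.hypot(g.sigma_b, g.sigma_w)
            t_g = sps.norm.ppf(1.0 - g.p_consume)
            m = a * g.sigma_b * B[:, j] / sigma_tot
            alpha = a * g.sigma_w / sigma_tot
            sd_rest = np.hypot(alpha, np.sqrt(1.0 - a**2))
            p_tilted = sps.norm.cdf((m + alpha * g.sigma_w - t_g) / sd_rest)
            out[:, j] = (
                g.base_grams * np.exp(g.sigma_b * B[:, j] + 0.5 * g.sigma_w**2) * p_tilted
            )
        return out

    # -- variable extraction (mirrors the composition stage, vectorized) -------

    def variable_matrix(self, grams: np.ndarray) -> dict[str, np.ndarray]:
        """Map a (rows × groups) gram matrix to the pipeline's intake variables."""
        gs = self._groups
        e = np.array([g.energy_kj_per_100g for g in gs]) / 100.0
        out: dict[str, np.ndarray] = {"energy_kj": grams @ e}
        for n in NUTRIENTS:
            dens = np.array([g.nutrients.get(n, 0.0) for g in gs]) / 100.0
            out[f"nutrient_{n}"] = grams @ dens
        for s in ("vegetables", "fruits", "grains", "milk_alt", "meat_alt"):
            w = np.array([g.serve_weights.get(s, 0.0) for g in gs]) / 100.0
            out[f"serves_{s}"] = grams @ w
        # alcoholic drinks count through alcohol mass (10 g/serve), all other
        # discretionary foods through energy (600 kJ/serve)
        disc = np.array(
            [g.discretionary and g.nutrients.get("alcohol", 0.0) == 0 for g in gs],
            float,
        )
        out["serves_discretionary"] = (
            grams @ (disc * e) / 600.0 + out["nutrient_alcohol"] / 10.0
        )
        out["serves_fruit_veg"] = out["serves_vegetables"] + out["serves_fruits"]
        return out

    # -- questionnaire ---------------------------------------------------------

    def _draw_items(
        self, rng: np.random.Generator, z: np.ndarray, loadings: dict[str, float]
    ) -> dict[str, np.ndarray]:
        """Category answers per item: ordinal ladders thresholded on a latent
        that shares loading a with the trait (reversal folded in so answers are
        monotone in effective points)."""
        n = len(z)
        answers: dict[str, np.ndarray] = {}
        for it in self.schema.items:
            k = len(it.categories)
            if it.scored:
                a = loadings[it.sub_score]
                u = a * z + np.sqrt(1.0 - a**2) * rng.standard_normal(n)
                # categories ordered by effective (post-reversal) points
                eff = [score_item(it, c) for c in it.categories]
                order = np.argsort(np.asarray(eff), kind="stable")
                edges = sps.norm.ppf(np.arange(1, k) / k)
                idx = np.searchsorted(edges, u)
            else:
                order = np.arange(k)
                idx = rng.integers(0, k, size=n)
            cats = np.asarray(it.categories, dtype=object)[order]
            answers[it.item_id] = cats[idx]
        return answers

    def _sub_scores_from_answers(self, answers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name in SUB_SCORES:
            items = self.schema.sub_score_items(name)
            pts = np.stack(
                [
                    np.asarray([score_item(it, c) for c in answers[it.item_id]], float)
                    for it in items
                ]
            )
            out[name] = pts.mean(axis=0)
        return out

    # -- calibration -----------------------------------------------------------

    @property
    def item_loadings(self) -> dict[str, float]:
        if self._loadings is None:
            self._loadings = self._calibrate()
        return self._loadings

    def _observable_usual(
        self, rng: np.random.Generator, n: int
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Simulate the recall design and return (z, usual-intake estimates per
        variable) for the calibration sample, using the same two-part shrinkage
        estimator the pipeline applies."""
        z, _, B = self._person_effects(rng, n)
        two_days = rng.random(n) < self.spec.p_repeat_recall
        rows = []
        for day in (1, 2):
            day_rows = np.arange(n) if day == 1 else np.flatnonzero(two_days)
            grams = self._day_grams(rng, B, day_rows)
            vars_ = self.variable_matrix(grams)
            for name in set(SUB_SCORE_VARIABLES.values()):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": day_rows.astype(str),
                            "day_index": day,
                            "day_type": "week" if day == 1 else "weekend",
                            "variable": name,
                            "value": vars_[name],
                        }
                    )
                )
        frame = pd.concat(rows, ignore_index=True)
        model = UsualIntakeModel(episodic=EPISODIC_VARIABLES)
        usual = model.fit_predict(frame).set_index("participant_id")
        usual = usual.loc[[str(i) for i in range(n)]]
        return z, {c: usual[c].to_numpy() for c in usual.columns}

    def _calibrate(self) -> dict[str, float]:
        rng = np.random.default_rng(self._CALIBRATION_SEED)
        n = self.spec.calibration_n
        z, usual = self._observable_usual(rng, n)

        loadings: dict[str, float] = {}
        for i, name in enumerate(SUB_SCORES):
            target = float(self.spec.trait_targets.get(name, 0.0))
            v = usual[SUB_SCORE_VARIABLES[name]]
            # one frozen noise matrix per sub-score: the correlation is then a
            # deterministic monotone function of the loading, so bisection works
            items = self.schema.sub_score_items(name)
            noise = np.random.default_rng(
                self._CALIBRATION_SEED + 1 + i
            ).standard_normal((len(items), n))

            def chain_corr(a: float) -> float:
                return self._subscore_corr(name, a, z, v, noise)

            if target == 0.0:
                loadings[name] = 0.0
                continue
            bound = chain_corr(0.999)
            if target * bound < 0 or abs(target) > abs(bound) + 1e-12:
                raise InfeasibleTargetError(
                    f"{name}: target correlation {target:+.3f} unattainable; "
                    f"attainable range is 0 to {bound:+.3f} given the item "
                    "ladders and intake model"
                )
            lo, hi = 0.0, 0.999
            for _ in range(self.spec.calibration_max_iter):
                mid = 0.5 * (lo + hi)
                r = chain_corr(mid)
                if abs(r - target) < self.spec.calibration_tol:
                    lo = hi = mid
                    break
                if abs(r) < abs(target):
                    lo = mid
                else:
                    hi = mid
            loadings[name] = 0.5 * (lo + hi)
        return loadings

    def _subscore_corr(
        self, name: str, a: float, z: np.ndarray, v: np.ndarray, noise: np.ndarray
    ) -> float:
        items = self.schema.sub_score_items(name)
        pts_sum = np.zeros(len(z))
        for row, it in enumerate(items):
            u = a * z + np.sqrt(1.0 - a**2) * noise[row]
            k = len(it.categories)
            eff = np.sort([score_item(it, c) for c in it.categories])
            edges = sps.norm.ppf(np.arange(1, k) / k)
            pts_sum += eff[np.searchsorted(edges, u)]
        rho, _ = sps.spearmanr(pts_sum, v)
        return float(rho)

    # -- public API ------------------------------------------------------------

    def generate(self, seed: int | None = None) -> SyntheticCohort:
        """Draw one cohort.  Same seed → identical output, bit for bit."""
        spec = self.spec
        seed = spec.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        n = spec.n_participants
        pids = [f"P{i + 1:04d}" for i in range(n)]

        z, f, B = self._person_effects(rng, n)
        sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
        bands, probs = zip(*spec.age_bands)
        age_band = np.asarray(bands, dtype=object)[
            rng.choice(len(bands), size=n, p=np.asarray(probs) / np.sum(probs))
        ]
        two_days = rng.random(n) < spec.p_repeat_recall

        recall_rows = []
        for day in (1, 2):
            day_rows = np.arange(n) if day == 1 else np.flatnonzero(two_days)
            if len(day_rows) == 0:
                continue
            grams = self._day_grams(rng, B, day_rows)
            for jj, g in enumerate(self._groups):
                nz = grams[:, jj] > 0
                recall_rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": np.asarray(pids, dtype=object)[day_rows[nz]],
                            "day_index": day,
                            "day_type": "week" if day == 1 else "weekend",
                            "food_code": f"F{g.code}",
                            "grams": np.round(grams[nz, jj], 3),
                        }
                    )
                )
        recalls = (
            pd.concat(recall_rows, ignore_index=True)
            .sort_values(["participant_id", "day_index", "food_code"], kind="stable")
            .reset_index(drop=True)
        )

        answers = self._draw_items(rng, z, self.item_loadings)
        questionnaire = pd.DataFrame(
            {
                "participant_id": np.repeat(pids, len(self.schema.items)),
                "item_id": [it.item_id for _ in pids for it in self.schema.items],
                "category": [
                    answers[it.item_id][i]
                    for i in range(n)
                    for it in self.schema.items
                ],
            }
        )

        true_grams = self._true_usual_grams(B)
        true_vars = self.variable_matrix(true_grams)
        truth_frame = pd.DataFrame({"participant_id": pids, "z": z})
        truth_frame["sex"] = sex
        truth_frame["age_band"] = age_band
        truth_frame["n_recall_days"] = np.where(two_days, 2, 1)
        for j in range(N_FACTORS):
            truth_frame[f"factor_{j + 1}"] = f[:, j]
        for name, vals in true_vars.items():
            truth_frame[f"true_{name}"] = vals

        foods, components = self.composition_frames()
        group_params = pd.DataFrame(
            {
                "name": [g.name for g in self._groups],
                "code": [g.code for g in self._groups],
                "base_grams": [g.base_grams for g in self._groups],
                "sigma_b": [g.sigma_b for g in self._groups],
                "sigma_w": [g.sigma_w for g in self._groups],
                "p_consume": [g.p_consume for g in self._groups],
                "trait_weight": [g.trait_weight for g in self._groups],
            }
        )
        participants = pd.DataFrame(
            {"participant_id": pids, "sex": sex, "age_band": age_band}
        )
        return SyntheticCohort(
            questionnaire=questionnaire,
            recalls=recalls,
            foods=foods,
            components=components,
            participants=participants,
            truth=TruthTable(truth_frame, dict(self.item_loadings), group_params),
        )

    def planted_loading_matrix(self) -> pd.DataFrame:
        """The planted factor loading matrix (groups × factors)."""
        return pd.DataFrame(
            [g.factor_loadings for g in self._groups],
            index=[g.name for g in self._groups],
            columns=[f"factor_{j + 1}" for j in range(N_FACTORS)],
        )


def generate(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """One-shot convenience wrapper around :class:`CohortGenerator`."""
    return CohortGenerator(spec).generate(seed)


# -- miniature deterministic fixture ------------------------------------------

def fixture_small() -> SyntheticCohort:
    """A hand-checkable 6-participant cohort over a 5-food composition table
    (plus one composite dish), used in unit tests and documentation.

    Participant P0001 answers every item at its best category (total 100);
    P0002 at its worst (total 20); the rest are fixed mixtures.
    """
    foods = pd.DataFrame(
        [
            # code, desc, major, kJ/100g, disc, fiber, fat, alcohol, veg, fruit, grains
            ("V01", "mixed vegetables", "24", 150, False, 3.5, 0.0, 0.0, 1.333, 0.0, 0.0),
            ("R01", "cooked grain", "12", 1200, False, 8.0, 2.0, 0.0, 0.0, 0.0, 2.5),
            ("S01", "confectionery bar", "28", 2000, True, 0.0, 25.0, 0.0, 0.0, 0.0, 0.0),
            ("B01", "beer", "29", 300, True, 0.0, 0.0, 5.0, 0.0, 0.0, 0.0),
            ("A01", "apple", "16", 250, False, 2.5, 0.0, 0.0, 0.0, 0.667, 0.0),
            ("C01", "veg and grain casserole", "13", 0, False, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ],
        columns=[
            "food_code", "description", "major_group_code", "energy_kj_per_100g",
            "discretionary", "nutrient_fiber", "nutrient_total_fat",
            "nutrient_alcohol", "serve_vegetables", "serve_fruits", "serve_grains",
        ],
    )
    components = pd.DataFrame(
        [("C01", "V01", 0.5), ("C01", "R01", 0.5)],
        columns=["parent_code", "component_code", "fraction"],
    )
    schema = DhqSchema.default()
    best, worst = {}, {}
    for it in schema.items:
        eff = [score_item(it, c) for c in it.categories]
        best[it.item_id] = it.categories[int(np.argmax(eff))]
        worst[it.item_id] = it.categories[int(np.argmin(eff))]
    mid = {
        it.item_id: it.categories[len(it.categories) // 2] for it in schema.items
    }
    answer_sets = [best, worst, mid, best, mid, worst]
    pids = [f"P{i + 1:04d}" for i in range(6)]
    questionnaire = pd.DataFrame(
        [
            (pid, it.item_id, ans[it.item_id])
            for pid, ans in zip(pids, answer_sets)
            for it in schema.items
        ],
        columns=["participant_id", "item_id", "category"],
    )
    # P0001 eats well on both days; P0002 eats 200 g of confectionery (4000 kJ
    # discretionary = 6.67 serves) and 200 g beer (10 g alcohol = 1 serve).
    recalls = pd.DataFrame(
        [
            ("P0001", 1, "week", "V01", 300.0),
            ("P0001", 1, "week", "R01", 150.0),
            ("P0001", 1, "week", "A01", 150.0),
            ("P0001", 2, "weekend", "C01", 200.0),
            ("P0001", 2, "weekend", "A01", 300.0),
            ("P0002", 1, "week", "S01", 200.0),
            ("P0002", 1, "week", "B01", 200.0),
            ("P0003", 1, "week", "C01", 100.0),
            ("P0003", 2, "weekend", "V01", 150.0),
            ("P0004", 1, "week", "R01", 100.0),
            ("P0004", 2, "weekend", "R01", 120.0),
            ("P0005", 1, "week", "A01", 225.0),
            ("P0006", 1, "week", "V01", 75.0),
            ("P0006", 1, "week", "S01", 30.0),
        ],
        columns=["participant_id", "day_index", "day_type", "food_code", "grams"],
    )
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": ["female", "female", "male", "female", "female", "male"],
            "age_band": ["45-64", "33-44", "45-64", "65-86", "45-64", "45-64"],
        }
    )
    truth = TruthTable(
        participants=pd.DataFrame({"participant_id": pids}),
        item_loadings={},
        group_params=pd.DataFrame(),
    )
    return SyntheticCohort(questionnaire, recalls, foods, components, participants, truth)
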