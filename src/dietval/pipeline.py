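"""End-to-end orchestration: recalls + questionnaire → validity report bundle.

Stage order: input validation (exclusion of participants with no valid recall
day) → food composition (per-day nutrient totals, guideline serves, major
food-group grams) → questionnaire scoring and quartiles → usual-intake
estimation → psychometrics (validity correlations, Cronbach's alpha, quartile
trends, group contrasts) → dietary-pattern extraction on single-day
food-group grams.  All outputs are plain CSV/JSON and byte-identical across
re-runs on unchanged inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import composition, patterns, psychometrics, scoring
from .synthetic import EPISODIC_VARIABLES, SUB_SCORE_VARIABLES
from .usual import DEFAULT_LAMBDA_GRID, UsualIntakeModel


class RunConfig(BaseModel):
    questionnaire: str
    recalls: str
    foods: str
    components: str | None = None
    participants: str | None = None
    schema_path: str | None = None
    output_dir: str = "dietval_out"
    episodic: list[str] = Field(default_factory=lambda: sorted(EPISODIC_VARIABLES))
    lambda_grid: list[float] = Field(default_factory=lambda: list(DEFAULT_LAMBDA_GRID))
    missing_policy: str = "reject"
    include_alcohol_serves: bool = True
    normality_alpha: float = Field(0.05, gt=0, lt=1)
    eigenvalue_cut: float = Field(1.0, ge=0)
    msa_cut: float = Field(0.5, ge=0, le=1)
    loading_cut: float = Field(0.2, ge=0, le=1)
    weekday_weighting: bool = False
    seed: int = 0

    @field_validator("missing_policy")
    @classmethod
    def _policy(cls, v):
        if v not in ("reject", "prorate"):
            raise ValueError("missing_policy must be 'reject' or 'prorate'")
        return v


def day_values_long(day_frame: pd.DataFrame) -> pd.DataFrame:
    """Melt a per-day intake table into (participant, day, variable, value),
    adding the combined fruit-and-vegetable serve variable; major-group gram
    columns stay out (they feed pattern analysis, not usual-intake modelling)."""
    frame = day_frame.copy()
    if "serves_vegetables" in frame and "serves_fruits" in frame:
        frame["serves_fruit_veg"] = frame["serves_vegetables"] + frame["serves_fruits"]
    value_cols = [
        c
        for c in frame.columns
        if c == "energy_kj" or c.startswith(("nutrient_", "serves_"))
    ]
    return frame.melt(
        id_vars=["participant_id", "day_index", "day_type"],
        value_vars=value_cols,
        var_name="variable",
        value_name="value",
    )


def validate_inputs(
    questionnaire: pd.DataFrame,
    recalls: pd.DataFrame,
    table: composition.CompositionTable,
    schema: scoring.DhqSchema,
) -> dict:
    """Pre-flight diagnostics and the analysis/exclusion split.

    A valid recall day has at least one food record with positive total
    energy.  Participants with no valid day are excluded (counted, listed);
    a participant whose second day is invalid is kept as a 1-recall
    participant.  Unknown food codes and unanswered scored items are flagged.
    """
    unknown = sorted(
        {c for c in recalls["food_code"].astype(str) if c not in table}
    )
    known = recalls[recalls["food_code"].astype(str).map(lambda c: c in table)]

    day_valid: dict[tuple[str, int], bool] = {}
    for (pid, day), grp in known.groupby(["participant_id", "day_index"], sort=False):
        records = composition.recalls_from_frame(grp)[(str(pid), int(day))]
        di = composition.day_intake(records, table)
        day_valid[(str(pid), int(day))] = di.energy_kj > 0
    recall_pids = list(dict.fromkeys(recalls["participant_id"].astype(str)))
    valid_days = {
        pid: [d for (p, d), ok in day_valid.items() if p == pid and ok]
        for pid in recall_pids
    }

    scored_ids = {it.item_id for it in schema.scored_items}
    missing_items: dict[str, list[str]] = {}
    for pid, grp in questionnaire.groupby("participant_id", sort=False):
        missing = sorted(scored_ids - set(grp["item_id"].astype(str)))
        if missing:
            missing_items[str(pid)] = missing

    q_pids = set(questionnaire["participant_id"].astype(str))
    excluded = [
        {"participant_id": pid, "reason": "no valid recall day"}
        for pid in recall_pids
        if not valid_days[pid]
    ]
    excluded += [
        {"participant_id": pid, "reason": "no recall data"}
        for pid in sorted(q_pids - set(recall_pids))
    ]
    excluded_ids = {e["participant_id"] for e in excluded}
    analysis = [p for p in recall_pids if p not in excluded_ids]
    return {
        "analysis_participants": analysis,
        "exclusions": excluded,
        "n_excluded": len(excluded),
        "unknown_food_codes": unknown,
        "missing_scored_items": missing_items,
        "valid_days": valid_days,
    }


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; writes per-stage outputs and a summary.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    schema = (
        scoring.DhqSchema.from_json(config.schema_path)
        if config.schema_path
        else scoring.DhqSchema.default()
    )
    questionnaire = pd.read_csv(config.questionnaire, dtype=str)
    recalls = pd.read_csv(config.recalls, dtype={"participant_id": str, "food_code": str})
    table = composition.CompositionTable.from_csv(config.foods, config.components)

    diag = validate_inputs(questionnaire, recalls, table, schema)
    pd.DataFrame(
        diag["exclusions"], columns=["participant_id", "reason"]
    ).to_csv(out / "exclusions.csv", index=False)
    analysis_ids = diag["analysis_participants"]

    # stage: composition — keep only valid days of analysis participants
    valid_pairs = {
        (pid, d) for pid, days in diag["valid_days"].items() for d in days
    }
    keep = [
        (str(r.participant_id), int(r.day_index)) in valid_pairs
        and str(r.participant_id) in analysis_ids
        and str(r.food_code) in table  # unknown codes are flagged, then dropped
        for r in recalls.itertuples()
    ]
    recalls = recalls[keep]
    day_frame = composition.day_intake_frame(
        recalls, table, include_alcohol_serves=config.include_alcohol_serves
    )
    day_frame.to_csv(out / "day_intakes.csv", index=False, float_format="%.6g")

    # stage: questionnaire scoring
    questionnaire = questionnaire[
        questionnaire["participant_id"].astype(str).isin(analysis_ids)
    ]
    scores = scoring.score_cohort(schema, questionnaire, missing=config.missing_policy)
    scores.to_csv(out / "dhq_scores.csv", index=False, float_format="%.6g")

    # stage: usual intake
    long = day_values_long(day_frame)
    model = UsualIntakeModel(
        episodic=set(config.episodic),
        lambda_grid=config.lambda_grid,
        weekday_weighting=config.weekday_weighting,
    )
    usual = model.fit_predict(long)
    usual.to_csv(out / "usual_intake.csv", index=False, float_format="%.6g")
    comp_json = {
        var: {
            "lambda": c.lam,
            "mu": round(c.mu, 10),
            "sigma2_between": round(c.sigma2_b, 10),
            "sigma2_within": round(c.sigma2_w, 10),
            "n_repeat": c.n_repeat,
        }
        for var, c in sorted(model.components_.items())
    }
    (out / "variance_components.json").write_text(
        json.dumps(comp_json, indent=1, sort_keys=True)
    )

    # stage: psychometrics
    report = psychometrics.validity_report(scores, usual)
    participants = None
    if config.participants:
        participants = pd.read_csv(config.participants, dtype=str)
        merged = scores.merge(participants, on="participant_id", how="inner")
        n_days = (
            recalls.groupby("participant_id")["day_index"].nunique().rename("n_days")
        )
        merged = merged.merge(n_days, on="participant_id", how="left")
        merged["recall_group"] = np.where(merged["n_days"] >= 2, "2plus", "1")
        for grouping in ("sex", "age_band", "recall_group"):
            if grouping not in merged.columns:
                continue
            counts = merged[grouping].value_counts()
            if len(counts) < 2 or counts.min() < 2:
                continue
            res = psychometrics.group_compare(
                merged["total"].to_numpy(),
                merged[grouping].to_numpy(),
                normality_alpha=config.normality_alpha,
            )
            report.group_tests.append(
                {
                    "variable": "total",
                    "grouping": grouping,
                    "test": res.test,
                    "statistic": round(res.statistic, 10),
                    "p": round(res.p, 10),
                    "pairwise": [
                        [a, b, round(p, 10)] for a, b, p in res.pairwise
                    ],
                }
            )
    report_dict = report.to_dict()
    for row in report_dict["validity_correlations"]:
        row["rho"] = round(row["rho"], 10)
        row["p"] = round(row["p"], 10)
    for row in report_dict["quartile_trends"]:
        row["slope"] = round(row["slope"], 10)
        row["p"] = round(row["p"], 10)
    report_dict["alpha_raw"] = round(report_dict["alpha_raw"], 10)
    report_dict["alpha_standardized"] = round(report_dict["alpha_standardized"], 10)
    (out / "validity.json").write_text(json.dumps(report_dict, indent=1, sort_keys=True))

    # stage: dietary patterns on single-day (day 1) major-group grams
    gram_cols = [c for c in day_frame.columns if c.startswith("grams_")]
    day1 = day_frame[day_frame["day_index"] == 1].set_index("participant_id")
    pattern_summary = {}
    model_p = None
    if gram_cols and len(day1) >= 3:
        try:
            model_p = patterns.extract(
                day1[gram_cols],
                eigenvalue_cut=config.eigenvalue_cut,
                msa_cut=config.msa_cut,
                loading_cut=config.loading_cut,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            # too few participants relative to food groups, or a singular
            # correlation matrix — record and carry on with the other stages
            pattern_summary = {"error": str(err)}
    if model_p is not None:
        patterns.loadings_table(model_p, config.loading_cut).to_csv(
            out / "pattern_loadings.csv", index=False, float_format="%.6g"
        )
        model_p.scores.to_csv(out / "pattern_scores.csv", float_format="%.6g")
        adq = model_p.adequacy
        (out / "pattern_adequacy.json").write_text(
            json.dumps(
                {
                    "kmo_overall": round(adq.kmo_overall, 10),
                    "msa": {k: round(v, 10) for k, v in sorted(adq.msa.items())},
                    "bartlett_chi2": round(adq.bartlett_chi2, 10),
                    "bartlett_df": adq.bartlett_df,
                    "bartlett_p": round(adq.bartlett_p, 10),
                    "scree_eigenvalues": [round(e, 10) for e in model_p.eigenvalues],
                },
                indent=1,
                sort_keys=True,
            )
        )
        pattern_summary = {
            "retained_factors": model_p.retained_k,
            "pct_variance": [round(v, 4) for v in model_p.pct_variance],
            "cumulative_pct_variance": round(model_p.cumulative_pct, 4),
            "kmo": round(adq.kmo_overall, 4),
        }

    summary = {
        "stages": [
            "validate",
            "composition",
            "scoring",
            "usual_intake",
            "psychometrics",
            "patterns",
        ],
        "n_analysis": len(analysis_ids),
        "n_excluded": diag["n_excluded"],
        "median_total_dhq": round(float(scores["total"].median()), 4),
        "alpha_standardized": report_dict["alpha_standardized"],
        "patterns": pattern_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
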