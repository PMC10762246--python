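"""Scoring, exclusion rules and trial filters.

Implements the incentive scheme (a Brier-based proper scoring rule mapping
choice correctness and confidence to points, plus the bonus formula), the
subject-level exclusion criteria, and the per-analysis trial filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONFIDENCE_GRID = (0.50, 0.60, 0.70, 0.80, 0.90, 1.00)

ANALYSES = ("accuracy", "accumulation", "ordinal")


def confidence_from_category(j: np.ndarray | int) -> np.ndarray:
    """Confidence level (.50 .. 1.00) implied by an 11-point category."""
    j = np.asarray(j)
    return 0.5 + 0.1 * np.abs(j - 6)


def add_judgment_columns(dataset: pd.DataFrame) -> pd.DataFrame:
    """Derive reported side, confidence and correctness from the category.

    ``reported_side`` is +1 (orange), -1 (blue) or 0 (the neutral 50%
    response); ``correct`` is 1/0 and NaN for neutral responses, for which
    correctness is undefined.
    """
    df = dataset.copy()
    j = df["confidence_category"].to_numpy(int)
    side = np.sign(j - 6)
    df["reported_side"] = side
    df["conf"] = confidence_from_category(j)
    correct = np.where(side == 0, np.nan, (side == df["col"].to_numpy(int)) * 1.0)
    df["correct"] = correct
    return df


def score_judgment(correct: int, conf: float) -> float:
    """Points for one judgment: 100 * [1 - (correct - conf)^2] - 75.

    Proper in expectation: reporting the true probability of being correct
    maximizes expected points. A fully confident correct judgment earns 25,
    a fully confident wrong one loses 75, and a 50% response earns 0 either
    way.
    """
    if correct not in (0, 1):
        raise ValueError("correct must be 0 or 1")
    if not any(abs(conf - g) < 1e-9 for g in CONFIDENCE_GRID):
        raise ValueError(f"conf must be one of {CONFIDENCE_GRID}")
    return 100.0 * (1.0 - (correct - conf) ** 2) - 75.0


def compute_bonus(total_points: float) -> float:
    """Bonus payment in dollars: $0.2 per 100 points, floored at $1.

    The floor binds exactly when the session total is below 500 points.
    """
    return max(1.0, 0.2 * total_points / 100.0)


@dataclass(frozen=True)
class ExclusionCriteria:
    """Subject-level exclusion thresholds.

    A subject is excluded when they give an extreme-confidence (100%)
    response in more than ``max_share_full_confidence`` of trials, score
    below ``min_accuracy`` on average, respond late more than
    ``max_late_responses`` times, or (optionally) are on average more
    confident when wrong than when correct. ``glitch_flag_field`` names an
    optional boolean column carrying self-reported display problems; the
    flag is honoured, never inferred.
    """

    max_share_full_confidence: float = 0.90
    min_accuracy: float = 0.50
    max_late_responses: int = 10
    require_conf_correct_ge_wrong: bool = True
    glitch_flag_field: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.max_share_full_confidence <= 1:
            raise ValueError("max_share_full_confidence must lie in (0, 1]")
        if not 0 <= self.min_accuracy <= 1:
            raise ValueError("min_accuracy must lie in [0, 1]")
        if self.max_late_responses < 0:
            raise ValueError("max_late_responses must be non-negative")


@dataclass
class ExclusionReport:
    """Per-subject exclusion outcome; a subject may trigger several criteria."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def excluded_ids(self) -> list:
        return self.table.loc[~self.table["kept"], "subject_id"].tolist()

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for reasons in self.table["reasons"]:
            for r in reasons:
                counts[r] = counts.get(r, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "n_subjects": int(len(self.table)),
            "n_excluded": int((~self.table["kept"]).sum()),
            "reason_counts": self.reason_counts(),
            "subjects": [
                {
                    "subject_id": str(row.subject_id),
                    "kept": bool(row.kept),
                    "reasons": list(row.reasons),
                }
                for row in self.table.itertuples()
            ],
        }


def apply_subject_exclusions(
    dataset: pd.DataFrame, criteria: ExclusionCriteria | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects violating any exclusion criterion.

    Conventions: neutral (50%) responses count toward the full-confidence
    share denominator and the late count but are excluded from accuracy and
    from the confidence-calibration comparison; all trials, fillers
    included, enter the counts.
    """
    criteria = criteria or ExclusionCriteria()
    required = {"subject_id", "confidence_category", "col", "late_flag"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    df = add_judgment_columns(dataset)
    rows = []
    for subject_id, grp in df.groupby("subject_id", sort=False):
        reasons = []
        share_full = (grp["conf"] >= 1.0 - 1e-9).mean()
        if share_full > criteria.max_share_full_confidence:
            reasons.append("full-confidence share")
        decided = grp.dropna(subset=["correct"])
        if len(decided) and decided["correct"].mean() < criteria.min_accuracy:
            reasons.append("below-chance accuracy")
        if grp["late_flag"].sum() > criteria.max_late_responses:
            reasons.append("late responses")
        if criteria.require_conf_correct_ge_wrong and len(decided):
            conf_correct = decided.loc[decided["correct"] == 1, "conf"]
            conf_wrong = decided.loc[decided["correct"] == 0, "conf"]
            if (
                len(conf_correct)
                and len(conf_wrong)
                and conf_wrong.mean() > conf_correct.mean()
            ):
                reasons.append("higher confidence when wrong")
        if criteria.glitch_flag_field and criteria.glitch_flag_field in grp:
            if grp[criteria.glitch_flag_field].any():
                reasons.append("self-reported glitch")
        rows.append(
            {"subject_id": subject_id, "kept": not reasons, "reasons": reasons}
        )
    report = ExclusionReport(pd.DataFrame(rows))
    kept_ids = set(report.table.loc[report.table["kept"], "subject_id"])
    kept = dataset[dataset["subject_id"].isin(kept_ids)].reset_index(drop=True)
    return kept, report


def apply_trial_filters(dataset: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Trial-level filter for a named analysis.

    - ``accuracy``: drop neutral (50%) responses and filler trials;
    - ``accumulation``: drop late responses and filler trials;
    - ``ordinal``: drop filler trials only.

    Filters are idempotent; the applied filter is recorded in
    ``DataFrame.attrs['trial_filter']``.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    df = dataset[dataset["treatment"] != "filler"]
    if analysis == "accuracy":
        df = df[df["confidence_category"] != 6]
    elif analysis == "accumulation":
        df = df[~df["late_flag"].astype(bool)]
    df = df.reset_index(drop=True)
    df.attrs["trial_filter"] = analysis
    return df


def si_validity_label(dataset: pd.DataFrame) -> pd.Series:
    """Label each trial's social information as correct / wrong / none."""
    return pd.Series(
        np.select(
            [dataset["si_validity"] == 1, dataset["si_validity"] == -1],
            ["correct", "wrong"],
            default="none",
        ),
        index=dataset.index,
        name="si_validity_label",
    )


def summarize_accuracy(
    dataset: pd.DataFrame, grouping: str | list[str]
) -> pd.DataFrame:
    """Mean accuracy with twice its standard error, subject as the unit.

    Subject means are computed first; the group mean and SE are taken over
    subjects, so each participant contributes equally. Groups present in a
    categorical grouping but empty in the data are listed with a flag
    rather than dropped.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    df = add_judgment_columns(dataset).dropna(subset=["correct"])
    per_subject = (
        df.groupby(grouping + ["subject_id"], observed=False)["correct"]
        .mean()
        .reset_index()
    )
    rows = []
    for key, grp in per_subject.groupby(grouping, observed=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["correct"].dropna().to_numpy()
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0 if n == 1 else np.nan
        rows.append(
            {
                **dict(zip(grouping, key)),
                "n_subjects": n,
                "mean_accuracy": mean,
                "se": se,
                "ci_half_width": 2 * se if n else np.nan,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)
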