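"""Scoring of Shepard–Metzler same/different sessions.

Each trial shows a pair of 2D renderings of 3D block shapes; the participant
answers "same" or "different" and the reaction time (RT) is recorded.  The
analyses here reproduce the standard cohort-level accounting:

* per-participant error counts and mean *correct* RTs split by truth class;
* a per-stimulus population index of difficulty — the number of participants
  who misjudged that pair;
* response-bias counts (how often "same" was said to a different pair and
  vice versa);
* least-squares lines of mean correct RT against the index of difficulty,
  fitted separately for same-truth and different-truth stimuli, plus the
  population mean-RT gap between correct "same" and correct "different"
  responses;
* the population speed–accuracy association between error counts and mean RT.

Trial tables are pandas DataFrames with columns ``participant_id``,
``pair_id``, ``truth``, ``response`` (both "same"/"different") and ``rt_s``
(seconds, positive).  RT means use correct trials only; a mean over an empty
class is represented as missing (``None``/NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DataIntegrityError,
    EmptySessionError,
    InvalidInputError,
    UnderdeterminedFitError,
)

__all__ = [
    "TRUTH_LEVELS",
    "ParticipantSMRSummary",
    "BiasCounts",
    "LineFit",
    "RTDifficultyResult",
    "SpeedAccuracyResult",
    "validate_trials",
    "summarize_participant",
    "summarize_cohort",
    "pair_difficulties",
    "bias_counts",
    "rt_by_difficulty",
    "speed_accuracy",
]

TRUTH_LEVELS = ("same", "different")

_REQUIRED_COLUMNS = ("participant_id", "pair_id", "truth", "response", "rt_s")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the (unmodified) table."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidInputError(f"trial table is missing columns {missing}")
    for col in ("truth", "response"):
        bad = set(trials[col].unique()) - set(TRUTH_LEVELS)
        if bad:
            raise InvalidInputError(f"{col} contains values outside {TRUTH_LEVELS}: {sorted(bad)}")
    if len(trials) and not (trials["rt_s"] > 0).all():
        raise InvalidInputError("all reaction times must be positive")
    return trials


@dataclass(frozen=True)
class ParticipantSMRSummary:
    """Per-participant session summary (correct-trial RT means per truth class)."""

    participant_id: object
    n_trials: int
    n_errors: int
    n_correct_same: int
    n_correct_different: int
    mean_rt_correct_same: float | None
    mean_rt_correct_different: float | None

    @property
    def mean_rt_correct(self) -> float | None:
        """Mean correct RT pooled over both truth classes; None if no correct trials."""
        n = self.n_correct_same + self.n_correct_different
        if n == 0:
            return None
        total = 0.0
        if self.n_correct_same:
            total += self.n_correct_same * self.mean_rt_correct_same
        if self.n_correct_different:
            total += self.n_correct_different * self.mean_rt_correct_different
        return total / n


@dataclass(frozen=True)
class BiasCounts:
    """Cross-class error counts; their imbalance is the population response bias."""

    said_same_when_different: int
    said_different_when_same: int

    @property
    def bias_direction(self) -> str:
        """'same', 'different', or 'none' — the direction the population leans."""
        delta = self.said_same_when_different - self.said_different_when_same
        if delta > 0:
            return "same"
        if delta < 0:
            return "different"
        return "none"


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class RTDifficultyResult:
    """Per-class RT-vs-difficulty lines and the same/different mean-RT gap (s)."""

    fit_same: LineFit
    fit_different: LineFit
    gap: float


@dataclass(frozen=True)
class SpeedAccuracyResult:
    """Association between per-participant error counts and mean correct RT.

    A negative statistic is the classical speed–accuracy tradeoff: faster
    participants commit more errors.  ``defined`` is False when either margin
    is constant.
    """

    statistic: float
    pvalue: float
    slope: float
    n: int
    defined: bool
    method: str = "spearman"


def summarize_participant(trials: pd.DataFrame) -> ParticipantSMRSummary:
    """Summarize one participant's session.

    Error count is the number of trials whose response differs from the truth;
    RT means are over correct trials only, separately per truth class, and are
    missing (None) for a class with no correct trials.
    """
    validate_trials(trials)
    if len(trials) == 0:
        raise EmptySessionError("cannot summarize an empty session")
    ids = trials["participant_id"].unique()
    if len(ids) != 1:
        raise InvalidInputError(f"expected a single participant, got {list(ids)}")

    correct = trials[trials["truth"] == trials["response"]]

    def class_stats(truth: str) -> tuple[int, float | None]:
        rts = correct.loc[correct["truth"] == truth, "rt_s"]
        return len(rts), (float(rts.mean()) if len(rts) else None)

    n_same, mean_same = class_stats("same")
    n_diff, mean_diff = class_stats("different")
    return ParticipantSMRSummary(
        participant_id=ids[0],
        n_trials=len(trials),
        n_errors=int(len(trials) - len(correct)),
        n_correct_same=n_same,
        n_correct_different=n_diff,
        mean_rt_correct_same=mean_same,
        mean_rt_correct_different=mean_diff,
    )


def summarize_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summary table (one row per participant)."""
    validate_trials(trials)
    if len(trials) == 0:
        raise EmptySessionError("cannot summarize an empty trial table")
    rows = []
    for pid, group in trials.groupby("participant_id", sort=True):
        s = summarize_participant(group)
        rows.append(
            {
                "participant_id": pid,
                "n_trials": s.n_trials,
                "n_errors": s.n_errors,
                "n_correct_same": s.n_correct_same,
                "n_correct_different": s.n_correct_different,
                "mean_rt_correct_same": s.mean_rt_correct_same,
                "mean_rt_correct_different": s.mean_rt_correct_different,
                "mean_rt_correct": s.mean_rt_correct,
            }
        )
    return pd.DataFrame(rows)


def pair_difficulties(trials: pd.DataFrame) -> pd.DataFrame:
    """Population index of difficulty per stimulus pair.

    The raw index is simply the number of participants who misjudged the pair;
    zero-error pairs are included.  Each participant may contribute at most one
    record per pair.
    """
    validate_trials(trials)
    dup = trials.duplicated(subset=["participant_id", "pair_id"])
    if dup.any():
        pairs = trials.loc[dup, ["participant_id", "pair_id"]].drop_duplicates()
        raise DataIntegrityError(
            f"duplicate participant/pair records: {pairs.to_records(index=False).tolist()}"
        )
    err = (trials["truth"] != trials["response"]).astype(int)
    out = (
        trials.assign(error=err)
        .groupby(["pair_id", "truth"], sort=True, as_index=False)
        .agg(error_count=("error", "sum"), n_presentations=("error", "size"))
    )
    return out


def bias_counts(trials: pd.DataFrame) -> BiasCounts:
    """Count the two cross-class confusions across all trials."""
    validate_trials(trials)
    if len(trials) == 0:
        raise EmptySessionError("cannot count bias on an empty trial table")
    sswd = int(((trials["truth"] == "different") & (trials["response"] == "same")).sum())
    sdws = int(((trials["truth"] == "same") & (trials["response"] == "different")).sum())
    return BiasCounts(said_same_when_different=sswd, said_different_when_same=sdws)


def rt_by_difficulty(
    trials: pd.DataFrame,
    difficulties: pd.DataFrame | None = None,
    per_pair: bool = True,
) -> RTDifficultyResult:
    """Fit mean correct RT against the population index of difficulty, per class.

    By default each stimulus pair contributes one point (its mean correct RT
    across participants) so easy, frequently-correct pairs do not dominate;
    ``per_pair=False`` regresses raw correct trials instead.  The ``gap`` is
    the population difference mean-correct-same-RT − mean-correct-different-RT.
    """
    validate_trials(trials)
    if difficulties is None:
        difficulties = pair_difficulties(trials)
    correct = trials[trials["truth"] == trials["response"]]
    if per_pair:
        points = (
            correct.groupby(["pair_id", "truth"], sort=True, as_index=False)
            .agg(rt=("rt_s", "mean"))
            .merge(difficulties[["pair_id", "truth", "error_count"]], on=["pair_id", "truth"])
        )
    else:
        points = correct.merge(
            difficulties[["pair_id", "truth", "error_count"]], on=["pair_id", "truth"]
        ).rename(columns={"rt_s": "rt"})

    fits = {}
    for truth in TRUTH_LEVELS:
        sub = points[points["truth"] == truth]
        if sub["error_count"].nunique() < 2:
            raise UnderdeterminedFitError(
                f"need >= 2 distinct difficulty values for truth class {truth!r}"
            )
        res = stats.linregress(sub["error_count"], sub["rt"])
        fits[truth] = LineFit(slope=float(res.slope), intercept=float(res.intercept))

    mean_same = correct.loc[correct["truth"] == "same", "rt_s"].mean()
    mean_diff = correct.loc[correct["truth"] == "different", "rt_s"].mean()
    return RTDifficultyResult(
        fit_same=fits["same"],
        fit_different=fits["different"],
        gap=float(mean_same - mean_diff),
    )


def speed_accuracy(summaries: pd.DataFrame) -> SpeedAccuracyResult:
    """Rank-correlate per-participant error counts with mean correct RT.

    Spearman is used because the cohorts are small and error counts ordinal;
    the least-squares slope (seconds per error) is reported alongside.
    """
    if len(summaries) < 3:
        raise InvalidInputError("speed_accuracy requires at least 3 participants")
    errors = summaries["n_errors"].to_numpy(dtype=float)
    rts = summaries["mean_rt_correct"].to_numpy(dtype=float)
    if np.isnan(rts).any():
        raise InvalidInputError("every participant needs a defined mean correct RT")
    if np.ptp(errors) == 0 or np.ptp(rts) == 0:
        return SpeedAccuracyResult(
            statistic=float("nan"), pvalue=float("nan"), slope=float("nan"),
            n=len(summaries), defined=False,
        )
    rho, p = stats.spearmanr(rts, errors)
    slope = float(stats.linregress(rts, errors).slope)
    return SpeedAccuracyResult(
        statistic=float(rho), pvalue=float(p), slope=slope, n=len(summaries), defined=True
    )
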