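"""Composite speed+accuracy performance indices and their correlation.

Both tasks are scored by the same speed–accuracy fusion: an accuracy
component in [0, 1] divided by a mean completion time, giving an index in
1/seconds (higher is better).

* EVD targeting: accuracy is ``mean(1 − min(|D|/D_max, 1))`` over a
  participant's trials, where |D| is the magnitude of the targeting distance
  metric and D_max caps unbounded misses (default 3R); the index divides by
  the mean task time.
* Spatial reasoning: accuracy is ``1 − n_errors/n_trials``; the index divides
  by the mean correct RT pooled over truth classes.

Accuracy-per-unit-time is the simplest fusion of "task time and error rate";
both raw components are always carried alongside so alternative composites
can be formed downstream.  The cohort-level association between the two
indices is reported as a Spearman rank correlation with a seeded bootstrap
percentile confidence interval (appropriate at cohort sizes of ~25–53).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptySessionError, InvalidInputError
from .smr import ParticipantSMRSummary

__all__ = [
    "EVDPerformance",
    "SpatialScore",
    "CorrelationResult",
    "evd_performance",
    "spatial_score",
    "correlate",
    "performance_table",
]

#: default miss cap, as a multiple of the target radius
D_MAX_RADIUS_FACTOR = 3.0


@dataclass(frozen=True)
class EVDPerformance:
    """Per-participant EVD targeting components and composite index."""

    accuracy: float  # in [0, 1]
    mean_time: float  # seconds
    index: float  # 1/seconds

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise InvalidInputError(f"accuracy must lie in [0, 1], got {self.accuracy!r}")


@dataclass(frozen=True)
class SpatialScore:
    """Per-participant spatial-reasoning components and composite index.

    ``defined`` is False when the participant had no correct trials, in which
    case the mean RT (and hence the index) does not exist.
    """

    accuracy: float
    mean_rt: float
    index: float
    defined: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    statistic: float
    n: int
    interval: tuple[float, float]
    method: str
    n_boot: int
    defined: bool = True


def evd_performance(measures: pd.DataFrame, d_max: float | None = None) -> EVDPerformance:
    """Score one participant's EVD trials.

    ``measures`` needs columns ``D_mag_mm``, ``task_time_s`` and (when
    ``d_max`` is None) ``target_r_mm``, in which case each trial is capped at
    3R for its own target.
    """
    if len(measures) == 0:
        raise EmptySessionError("cannot score an empty EVD session")
    dmag = measures["D_mag_mm"].to_numpy(dtype=float)
    times = measures["task_time_s"].to_numpy(dtype=float)
    if not (times > 0).all():
        raise InvalidInputError("task times must be positive")
    if d_max is None:
        caps = D_MAX_RADIUS_FACTOR * measures["target_r_mm"].to_numpy(dtype=float)
    else:
        if not d_max > 0:
            raise InvalidInputError(f"d_max must be positive, got {d_max!r}")
        caps = np.full_like(dmag, float(d_max))
    accuracy = float(np.mean(1.0 - np.minimum(dmag / caps, 1.0)))
    mean_time = float(np.mean(times))
    return EVDPerformance(accuracy=accuracy, mean_time=mean_time, index=accuracy / mean_time)


def spatial_score(summary: ParticipantSMRSummary) -> SpatialScore:
    """Score one participant's spatial-reasoning session."""
    if summary.n_trials <= 0:
        raise EmptySessionError("summary covers no trials")
    accuracy = 1.0 - summary.n_errors / summary.n_trials
    mean_rt = summary.mean_rt_correct
    if mean_rt is None:
        return SpatialScore(accuracy=accuracy, mean_rt=float("nan"), index=float("nan"),
                            defined=False)
    return SpatialScore(accuracy=accuracy, mean_rt=mean_rt, index=accuracy / mean_rt)


def correlate(
    x,
    y,
    method: str = "spearman",
    n_boot: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> CorrelationResult:
    """Correlation between two per-participant indices with a bootstrap CI.

    Participants are resampled with replacement ``n_boot`` times and the
    percentile interval of the resampled statistics is reported.  Constant
    input on either side yields an undefined result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise InvalidInputError("correlation requires at least 4 records")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("indices must be finite")
    if method not in ("spearman", "pearson"):
        raise InvalidInputError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            statistic=float("nan"), n=n, interval=(float("nan"), float("nan")),
            method=method, n_boot=n_boot, defined=False,
        )

    if method == "spearman":
        statistic = float(stats.spearmanr(x, y).statistic)
    else:
        statistic = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    if method == "spearman":
        bx = stats.rankdata(bx, axis=1)
        by = stats.rankdata(by, axis=1)
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx**2).sum(axis=1) * (by**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (bx * by).sum(axis=1) / denom
    boots = boots[np.isfinite(boots)]  # degenerate resamples (constant draw) dropped
    alpha = 1.0 - confidence
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CorrelationResult(
        statistic=statistic, n=n, interval=(float(lo), float(hi)),
        method=method, n_boot=n_boot,
    )


def performance_table(
    measures: pd.DataFrame,
    summaries: pd.DataFrame,
    d_max: float | None = None,
) -> pd.DataFrame:
    """Join per-participant EVD and spatial-reasoning indices into one table.

    ``measures`` is the per-trial EVD measures table; ``summaries`` the
    per-participant spatial-reasoning summary table.  Participants missing
    from either side are dropped (inner join); participants with an undefined
    spatial score (no correct trials) are kept with NaN score.
    """
    rows = []
    for pid, group in measures.groupby("participant_id", sort=True):
        perf = evd_performance(group, d_max=d_max)
        rows.append(
            {
                "participant_id": pid,
                "evd_accuracy": perf.accuracy,
                "evd_mean_time_s": perf.mean_time,
                "evd_performance": perf.index,
            }
        )
    evd = pd.DataFrame(rows)

    srows = []
    for rec in summaries.to_dict("records"):
        summary = ParticipantSMRSummary(
            participant_id=rec["participant_id"],
            n_trials=int(rec["n_trials"]),
            n_errors=int(rec["n_errors"]),
            n_correct_same=int(rec["n_correct_same"]),
            n_correct_different=int(rec["n_correct_different"]),
            mean_rt_correct_same=_maybe(rec["mean_rt_correct_same"]),
            mean_rt_correct_different=_maybe(rec["mean_rt_correct_different"]),
        )
        score = spatial_score(summary)
        srows.append(
            {
                "participant_id": rec["participant_id"],
                "smr_accuracy": score.accuracy,
                "smr_mean_rt_s": score.mean_rt,
                "spatial_score": score.index,
            }
        )
    smr = pd.DataFrame(srows)
    return evd.merge(smr, on="participant_id", how="inner")


def _maybe(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)
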