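"""High-level pipeline stages tying the modules into one analysis.

Stage functions operate on the tables defined in :mod:`evdassess.io`:

``score_evd_trials``   trial table -> per-trial measures (+ emulated IA)
``score_smr_trials``   same/different trials -> summaries, difficulties, report
``analyze``            both score outputs -> performance table + correlation
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry, rubric, smr
from .exceptions import InvalidInputError
from .performance import correlate, performance_table

__all__ = ["score_evd_trials", "score_smr_trials", "analyze"]


def score_evd_trials(
    trials: pd.DataFrame,
    thresholds: rubric.RubricThresholds = rubric.RubricThresholds(),
    frame: geometry.AnatomicalFrame = geometry.RAS,
) -> pd.DataFrame:
    """Compute all geometric measures plus the emulated expert score per trial."""
    rows = []
    for rec in trials.to_dict("records"):
        traj = geometry.Trajectory(
            entry=[rec["entry_x"], rec["entry_y"], rec["entry_z"]],
            direction=_unit([rec["dir_x"], rec["dir_y"], rec["dir_z"]]),
            depth=rec["depth"],
        )
        target = geometry.TargetSphere(
            center=[rec["target_x"], rec["target_y"], rec["target_z"]],
            radius=rec["target_r"],
        )
        ideal = geometry.Trajectory(
            entry=traj.entry,
            direction=_unit([rec["ideal_dir_x"], rec["ideal_dir_y"], rec["ideal_dir_z"]]),
            depth=rec["depth"],
        )
        m = geometry.measure_trial(traj, target, ideal, rec["task_time_s"], frame)
        features = rubric.extract_features(m, target, thresholds)
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "trial_id": rec["trial_id"],
                "engagement_mm": m.engagement,
                "d_mm": m.closest_distance,
                "D_real_mm": m.metric.real_part,
                "D_imag_mm": m.metric.imag_part,
                "D_mag_mm": m.metric.magnitude,
                "outside": m.metric.outside,
                "sagittal_angle_deg": m.sagittal_angle,
                "coronal_angle_deg": m.coronal_angle,
                "mdm_mm": m.mdm,
                "task_time_s": m.task_time,
                "target_r_mm": target.radius,
                "ia": rubric.assign_ia(features),
            }
        )
    return pd.DataFrame(rows)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise InvalidInputError("zero-length direction in trial table")
    return v / norm


def score_smr_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full same/different analysis.

    Returns (per-participant summaries, per-pair difficulty table, report
    dict).  The report carries the bias counts, the RT-vs-difficulty line
    fits with the same/different RT gap, and the speed–accuracy association.
    """
    summaries = smr.summarize_cohort(trials)
    difficulties = smr.pair_difficulties(trials)
    bias = smr.bias_counts(trials)
    rt_fit = smr.rt_by_difficulty(trials, difficulties)
    tradeoff = smr.speed_accuracy(summaries)
    report = {
        "n_participants": int(summaries.shape[0]),
        "n_trials": int(len(trials)),
        "bias": {
            "said_same_when_different": bias.said_same_when_different,
            "said_different_when_same": bias.said_different_when_same,
            "direction": bias.bias_direction,
        },
        "rt_vs_difficulty": {
            "same": {"slope": rt_fit.fit_same.slope, "intercept": rt_fit.fit_same.intercept},
            "different": {
                "slope": rt_fit.fit_different.slope,
                "intercept": rt_fit.fit_different.intercept,
            },
            "gap_s": rt_fit.gap,
        },
        "speed_accuracy": {
            "method": tradeoff.method,
            "statistic": tradeoff.statistic,
            "pvalue": tradeoff.pvalue,
            "slope_errors_per_s": tradeoff.slope,
            "defined": tradeoff.defined,
        },
    }
    return summaries, difficulties, report


def analyze(
    measures: pd.DataFrame,
    summaries: pd.DataFrame,
    d_max: float | None = None,
    method: str = "spearman",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Derive both performance indices and their cohort correlation.

    Returns the per-participant performance table and a correlation report.
    Alongside the headline composite-vs-composite statistic, the report
    includes the EVD index's correlation with each spatial-reasoning margin
    (accuracy-only and RT-only), since a cohort plot of "objective scores"
    could be read either way.
    """
    table = performance_table(measures, summaries, d_max=d_max)
    usable = table.dropna(subset=["evd_performance", "spatial_score"])
    result = correlate(
        usable["evd_performance"], usable["spatial_score"],
        method=method, n_boot=n_boot, seed=seed,
    )
    report = {
        "n": result.n,
        "method": result.method,
        "statistic": result.statistic,
        "ci95": [result.interval[0], result.interval[1]],
        "n_boot": result.n_boot,
        "defined": result.defined,
        "seed": seed,
        "margins": {
            "evd_vs_smr_accuracy": _margin(usable, "smr_accuracy", method, seed),
            "evd_vs_smr_mean_rt": _margin(usable, "smr_mean_rt_s", method, seed),
        },
    }
    return table, report


def _margin(table: pd.DataFrame, column: str, method: str, seed: int) -> float:
    res = correlate(table["evd_performance"], table[column],
                    method=method, n_boot=200, seed=seed)
    return res.statistic
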