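"""Synthetic trainee cohorts with a shared latent spatial ability.

Every analysis stage in this package is exercised on simulated cohorts whose
statistical structure matches the assessment's working assumption: a single
latent spatial ability :math:`\\theta_i \\sim N(\\mu, \\sigma)` per trainee
drives *both* tasks.

EVD targeting trials
    A spherical target of radius R is placed at a random pose; the entry
    point sits a fixed skull-to-ventricle distance away in a random
    direction.  The trainee aims at the centre with isotropic Gaussian error
    whose spread shrinks with ability, ``aim_sd_base * exp(-coupling * θ)``,
    plus angular execution jitter; the catheter is advanced to the aim point.
    Task time is log-normal with log-location ``log(time_base) −
    coupling * time_ability_slope * θ``.  The ``coupling`` knob in [0, 1]
    gates *every* ability→targeting pathway, so at coupling 0 targeting
    outcomes are statistically independent of ability (the ablation case).

Spatial-reasoning (same/different) trials
    A pool of ``n_pairs`` base stimulus pairs, each existing in a "same" and
    a "different" version, spans a linear latent-difficulty grid; every
    participant sees each version exactly once, in per-participant shuffled
    order, so truth classes are balanced and each (participant, stimulus)
    occurs at most once.  The perceptual comparison fails with probability
    ``logistic(difficulty − θ − error_baseline)``; on failure the participant
    guesses, leaning "same" with probability ``0.5 + bias_same``.  RT is
    ``rt_base + rt_difficulty_slope*difficulty + same_penalty*1[truth=same] +
    rt_ability_slope*θ + noise``, truncated below at ``rt_min`` — the
    exhaustive-search account in which "same" verdicts take longer because
    the search for a difference must be exhausted, and careful (high-θ)
    responders spend slightly longer per trial.

All randomness flows from one :func:`numpy.random.default_rng` seeded by the
config, so a (config, seed) pair reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort"]

#: burr-hole-to-ventricle lever arm (mm); typical frontal-approach distance
ENTRY_DISTANCE_MM = 80.0
#: half-width of the cube (mm) in which target centres are placed
WORKSPACE_HALFWIDTH_MM = 20.0
#: span of the latent stimulus-difficulty grid
DIFFICULTY_RANGE = (-2.0, 2.0)
#: floor applied to truncated reaction times (s)
RT_MIN_S = 0.25


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are the package's reference conditions.

    The cohort size defaults to 25 trainees (a typical residency bootcamp
    intake) with 10 targeting trials each and a 48-trial same/different
    session over 24 base stimulus pairs (each pair has a "same" and a
    "different" version, so classes are balanced and every stimulus is seen
    once).  ``coupling`` in [0, 1] sets how strongly latent ability drives
    targeting performance; ``same_penalty`` defaults to 2 s, the population
    same-vs-different RT gap the exhaustive-search account predicts.
    """

    n_participants: int = 25
    n_evd_trials: int = 10
    n_smr_trials: int = 48
    n_pairs: int = 24
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    coupling: float = 0.6
    aim_sd_base: float = 6.0  # mm, aim scatter for an average (θ=0) trainee
    angle_sd: float = 2.0  # degrees, execution jitter of the insertion axis
    time_base: float = 30.0  # s, median targeting task time at θ=0
    time_ability_slope: float = 0.2  # log-time decrease per ability unit (gated by coupling)
    time_log_sd: float = 0.3  # sd of log task time
    rt_base: float = 3.0  # s, response-time intercept
    rt_difficulty_slope: float = 0.5  # s per difficulty unit
    same_penalty: float = 2.0  # s, extra time to exhaust the search on "same" stimuli
    rt_ability_slope: float = 0.12  # s per ability unit (careful responders are slower)
    rt_noise_sd: float = 1.0  # s
    bias_same: float = 0.2  # guessing lean toward "same", in [0, 0.5]
    error_baseline: float = 1.0  # logistic offset setting the overall failure rate
    target_R: float = 10.0  # mm, ventricular target radius
    seed: int = 0

    def validate(self) -> "CohortConfig":
        for name in ("n_participants", "n_evd_trials", "n_smr_trials", "n_pairs"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_smr_trials != 2 * self.n_pairs:
            raise ConfigError(
                "n_smr_trials must equal 2 * n_pairs (each base pair is shown once "
                f"as 'same' and once as 'different'); got {self.n_smr_trials} vs "
                f"{self.n_pairs} pairs"
            )
        for name in ("ability_sd", "aim_sd_base", "angle_sd", "time_log_sd", "rt_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError(f"coupling must lie in [0, 1], got {self.coupling!r}")
        if not 0.0 <= self.bias_same <= 0.5:
            raise ConfigError(f"bias_same must lie in [0, 0.5], got {self.bias_same!r}")
        for name in ("time_base", "rt_base", "target_R"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown cohort-config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: latent abilities plus both trial tables."""

    config: CohortConfig
    abilities: pd.DataFrame  # participant_id, ability
    evd_trials: pd.DataFrame
    smr_trials: pd.DataFrame


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perpendicular_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pair spanning the plane perpendicular to each row of u."""
    helper = np.zeros_like(u)
    smallest = np.argmin(np.abs(u), axis=1)
    helper[np.arange(len(u)), smallest] = 1.0
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    return t1, t2


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one synthetic cohort under ``config`` (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_participants)
    pids = [f"P{i:03d}" for i in range(1, n + 1)]
    theta = rng.normal(config.ability_mean, config.ability_sd, size=n)
    abilities = pd.DataFrame({"participant_id": pids, "ability": theta})

    evd = _generate_evd(config, rng, pids, theta)
    smr = _generate_smr(config, rng, pids, theta)
    return SyntheticCohort(config=config, abilities=abilities, evd_trials=evd, smr_trials=smr)


def _generate_evd(
    config: CohortConfig, rng: np.random.Generator, pids: list[str], theta: np.ndarray
) -> pd.DataFrame:
    n, m = len(pids), int(config.n_evd_trials)
    total = n * m
    R = config.target_R

    centers = rng.uniform(-WORKSPACE_HALFWIDTH_MM, WORKSPACE_HALFWIDTH_MM, size=(total, 3))
    entries = centers + ENTRY_DISTANCE_MM * _random_unit_vectors(rng, total)

    aim_sd = config.aim_sd_base * np.exp(-config.coupling * np.repeat(theta, m))
    aims = centers + rng.standard_normal((total, 3)) * aim_sd[:, None]

    base_dir = aims - entries
    depth = np.linalg.norm(base_dir, axis=1)
    base_dir /= depth[:, None]
    # small-angle execution jitter: tangential Gaussian perturbation of the axis
    t1, t2 = _perpendicular_basis(base_dir)
    jitter = math.tan(math.radians(config.angle_sd))
    direction = base_dir + rng.standard_normal(total)[:, None] * jitter * t1
    direction += rng.standard_normal(total)[:, None] * jitter * t2
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)

    ideal = centers - entries
    ideal /= np.linalg.norm(ideal, axis=1, keepdims=True)

    log_loc = (
        math.log(config.time_base)
        - config.coupling * config.time_ability_slope * np.repeat(theta, m)
    )
    task_time = np.exp(rng.normal(log_loc, config.time_log_sd))

    return pd.DataFrame(
        {
            "participant_id": np.repeat(pids, m),
            "trial_id": np.tile([f"T{j:02d}" for j in range(1, m + 1)], n),
            "entry_x": entries[:, 0], "entry_y": entries[:, 1], "entry_z": entries[:, 2],
            "dir_x": direction[:, 0], "dir_y": direction[:, 1], "dir_z": direction[:, 2],
            "depth": depth,
            "target_x": centers[:, 0], "target_y": centers[:, 1], "target_z": centers[:, 2],
            "target_r": np.full(total, R),
            "ideal_dir_x": ideal[:, 0], "ideal_dir_y": ideal[:, 1], "ideal_dir_z": ideal[:, 2],
            "task_time_s": task_time,
        }
    )


def _generate_smr(
    config: CohortConfig, rng: np.random.Generator, pids: list[str], theta: np.ndarray
) -> pd.DataFrame:
    n_pairs = int(config.n_pairs)
    lo, hi = DIFFICULTY_RANGE
    difficulty = np.linspace(lo, hi, n_pairs) if n_pairs > 1 else np.array([(lo + hi) / 2.0])
    # each base pair exists in a "same" and a "different" version sharing its difficulty
    pair_ids = []
    truths = []
    diffs = []
    for k in range(n_pairs):
        for truth, tag in (("same", "s"), ("different", "d")):
            pair_ids.append(f"pair{k + 1:02d}{tag}")
            truths.append(truth)
            diffs.append(difficulty[k])
    pair_ids = np.array(pair_ids)
    truths = np.array(truths)
    diffs = np.array(diffs)
    n_stim = len(pair_ids)

    frames = []
    for pid, th in zip(pids, theta):
        order = rng.permutation(n_stim)
        p_fail = 1.0 / (1.0 + np.exp(-(diffs[order] - th - config.error_baseline)))
        fail = rng.random(n_stim) < p_fail
        guess_same = rng.random(n_stim) < (0.5 + config.bias_same)
        response = np.where(
            fail, np.where(guess_same, "same", "different"), truths[order]
        )
        rt = (
            config.rt_base
            + config.rt_difficulty_slope * diffs[order]
            + config.same_penalty * (truths[order] == "same")
            + config.rt_ability_slope * th
            + rng.normal(0.0, config.rt_noise_sd, size=n_stim)
        )
        rt = np.maximum(rt, RT_MIN_S)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "pair_id": pair_ids[order],
                    "truth": truths[order],
                    "response": response,
                    "rt_s": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
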