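"""Emulation of the expert 1–6 "index of accuracy" (IA) ranking.

A consultant's verbal rubric for ranking a targeting trial, 1 best:

1. well within the ventricle, good approach angle;
2. within the ventricle but at a poor angle, or inside but close to the wall;
3. slightly outside the ventricle, good angle;
4. slightly outside with a poor angle;
5. a wide miss with a good angle;
6. a wide miss with a poor angle.

``extract_features`` maps a trial's geometric measures onto the rubric's
qualitative clauses under explicit, configurable thresholds; ``assign_ia``
applies the clauses.  ``ia_from_normalized_D`` is the complementary view: a
monotone step map from the normalized distance metric |D|/R straight onto the
1–6 scale, blind to the approach angle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigError, InvalidInputError
from .geometry import TargetingMeasures, TargetSphere

__all__ = [
    "RubricThresholds",
    "RubricFeatures",
    "extract_features",
    "assign_ia",
    "ia_from_normalized_D",
]


@dataclass(frozen=True)
class RubricThresholds:
    """Calibration knobs mapping geometry onto the rubric's verbal clauses.

    wall_margin : fraction of R; "close to the wall" means R − d ≤ wall_margin·R.
    good_angle_max : degrees; a good approach keeps both plane angles at or
        below this.
    slight_margin : fraction of R; "slightly outside" reaches to
        (1 + slight_margin)·R, beyond which a trial is a wide miss.

    The defaults (0.2, 10°, 0.5) are documented calibration stand-ins: the
    verbal rubric gives no numbers, so these are exposed in configuration to
    be re-fit against real expert rankings.
    """

    wall_margin: float = 0.2
    good_angle_max: float = 10.0
    slight_margin: float = 0.5

    def __post_init__(self) -> None:
        if not self.wall_margin > 0:
            raise ConfigError(f"wall_margin must be positive, got {self.wall_margin!r}")
        if not self.good_angle_max > 0:
            raise ConfigError(f"good_angle_max must be positive, got {self.good_angle_max!r}")
        if self.slight_margin < 0:
            raise ConfigError(f"slight_margin must be non-negative, got {self.slight_margin!r}")


@dataclass(frozen=True)
class RubricFeatures:
    """Qualitative trial features the rubric clauses quantify over.

    ``inside``, ``slightly_outside`` and ``wide_miss`` are mutually exclusive
    and exhaustive; ``near_wall`` can hold only for inside trials.
    """

    inside: bool
    near_wall: bool
    good_angle: bool
    slightly_outside: bool
    wide_miss: bool

    def __post_init__(self) -> None:
        if sum((self.inside, self.slightly_outside, self.wide_miss)) != 1:
            raise InvalidInputError(
                "exactly one of inside / slightly_outside / wide_miss must hold"
            )
        if self.near_wall and not self.inside:
            raise InvalidInputError("near_wall requires inside")


def extract_features(
    measures: TargetingMeasures,
    target: TargetSphere,
    thresholds: RubricThresholds = RubricThresholds(),
) -> RubricFeatures:
    """Threshold a trial's geometric measures into rubric features."""
    d = measures.closest_distance
    R = target.radius
    inside = d < R
    slightly_outside = R <= d <= (1.0 + thresholds.slight_margin) * R
    wide_miss = d > (1.0 + thresholds.slight_margin) * R
    return RubricFeatures(
        inside=inside,
        near_wall=inside and (R - d) <= thresholds.wall_margin * R,
        good_angle=max(measures.sagittal_angle, measures.coronal_angle)
        <= thresholds.good_angle_max,
        slightly_outside=slightly_outside,
        wide_miss=wide_miss,
    )


def assign_ia(features: RubricFeatures) -> int:
    """Apply the expert rubric clauses; returns the index of accuracy in 1..6."""
    if features.inside:
        if features.good_angle and not features.near_wall:
            return 1
        return 2
    if features.slightly_outside:
        return 3 if features.good_angle else 4
    # wide miss: the "5 or 6, depending on whether the approach angle was good"
    # clause is read parallel to the 3/4 pattern, good angle taking the lower score
    return 5 if features.good_angle else 6


# step-map breakpoints for the angle-blind |D|/R -> IA view; band 4 is
# unreachable without angle information, by design
_INSIDE_BREAK = 0.8
_SLIGHT_BREAK = 1.5
_WIDE_BREAK = 2.5


def ia_from_normalized_D(nd: float, outside: bool) -> int:
    """Monotone step map from normalized |D|/R (and the miss flag) onto 1..6.

    Inside the target |D|/R runs over [0, 1]; outside it equals d/R ≥ 1.  The
    map is non-decreasing in ``nd`` for each flag value and is blind to the
    approach angle, so the angle-discriminated band 4 is never produced.
    """
    nd = float(nd)
    if not nd >= 0:
        raise InvalidInputError(f"normalized |D| must be non-negative, got {nd!r}")
    if outside and nd < 1.0:
        raise InvalidInputError(f"outside flag requires |D|/R >= 1, got {nd!r}")
    if not outside and nd > 1.0:
        raise InvalidInputError(f"inside trials have |D|/R <= 1, got {nd!r}")
    if not outside:
        return 1 if nd < _INSIDE_BREAK else 2
    if nd <= _SLIGHT_BREAK:
        return 3
    if nd <= _WIDE_BREAK:
        return 5
    return 6
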