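"""Point assignment: affine value<->points maps for every predictor.

Each predictor's influence over its admissible range is summarised by its
*absolute maximum beta value* ``|coef| * (max - min)``.  The predictor
maximising this score is the *initializer* and is anchored to the full
point scale ``P^max`` (100 by default); every other predictor receives a
maximum point budget proportional to its own score.  Values map onto the
point scale affinely, oriented so that larger points always mean larger
risk: ascending for non-negative coefficients, descending otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_meta import ModelSpec, PredictorSpec

__all__ = [
    "PointScale",
    "ScaleSet",
    "ModelConstructionError",
    "absolute_max_beta",
    "select_initializer",
    "max_points",
    "value_to_points",
    "points_to_value",
    "build_point_scales",
]

DEFAULT_P_MAX = 100.0
#: relative slack tolerated on strict range checks (pure float noise)
_RANGE_RTOL = 1e-9


class ModelConstructionError(ValueError):
    """The model cannot be turned into a point scale set."""


@dataclass(frozen=True)
class PointScale:
    """Affine map ``points = slope * value + offset`` for one predictor.

    ``value_to_points`` sends the low-risk end of the range to 0 and the
    high-risk end to ``max_points``: the minimum value when the
    coefficient is non-negative (``ascending``), the maximum value
    otherwise.
    """

    predictor_index: int
    max_points: float
    ascending: bool
    slope: float
    offset: float


@dataclass(frozen=True)
class ScaleSet:
    """One PointScale per predictor plus the chosen initializer."""

    scales: tuple[PointScale, ...]
    initializer_index: int
    p_max: float

    @property
    def total_max_points(self) -> float:
        return float(sum(s.max_points for s in self.scales))


def absolute_max_beta(predictor: PredictorSpec) -> float:
    """Score ``|coef| * (max - min)``: the predictor's largest possible
    contribution (in absolute log-odds) over its admissible range."""
    return abs(predictor.coef) * predictor.range


def select_initializer(model: ModelSpec) -> int:
    """Index of the predictor anchoring the point scale.

    The predictor with the largest absolute maximum beta value wins;
    ties break to the lowest index (file order), keeping construction
    deterministic.

    Raises
    ------
    ModelConstructionError
        If every score is zero (no informative predictor).
    """
    scores = np.array([absolute_max_beta(p) for p in model.predictors])
    if not np.any(scores > 0.0):
        raise ModelConstructionError("model has no informative predictor "
                                     "(all |coef| * range scores are zero)")
    return int(np.argmax(scores))


def max_points(predictor: PredictorSpec, initializer_score: float,
               p_max: float = DEFAULT_P_MAX) -> float:
    """Maximum point budget of a predictor relative to the initializer."""
    if initializer_score <= 0.0:
        raise ModelConstructionError(
            f"initializer score must be positive, got {initializer_score}")
    return p_max * absolute_max_beta(predictor) / initializer_score


def _make_scale(index: int, predictor: PredictorSpec, pmax_i: float) -> PointScale:
    rng = predictor.range
    ascending = predictor.coef >= 0.0
    if rng == 0.0:  # only reachable for coef == 0 rows kept by a caller
        slope, offset = 0.0, 0.0
    elif ascending:
        slope = pmax_i / rng
        offset = -predictor.min * slope
    else:
        slope = -pmax_i / rng
        offset = predictor.max * (pmax_i / rng)
    return PointScale(predictor_index=index, max_points=pmax_i,
                      ascending=ascending, slope=slope, offset=offset)


def value_to_points(scale: PointScale, predictor: PredictorSpec, v: float,
                    strict: bool = True) -> float:
    """Points assigned to value ``v`` of a predictor.

    ``(v - min)/(max - min) * max_points`` for non-negative coefficients,
    mirrored for negative ones.  In strict mode an out-of-range ``v``
    raises; in lenient mode it is clamped to the range first.
    """
    lo, hi = predictor.min, predictor.max
    slack = _RANGE_RTOL * max(1.0, abs(lo), abs(hi))
    if v < lo - slack or v > hi + slack:
        if strict:
            raise ValueError(
                f"value {v} for predictor '{predictor.name}' outside its "
                f"range [{lo}, {hi}]")
        v = min(max(v, lo), hi)
    pts = scale.slope * v + scale.offset
    # clip float noise at the boundaries
    return float(min(max(pts, 0.0), scale.max_points))


def points_to_value(scale: PointScale, predictor: PredictorSpec,
                    points: float) -> float:
    """Inverse of :func:`value_to_points` (used for axis tick labelling)."""
    if scale.max_points == 0.0:
        raise ValueError(
            f"predictor '{predictor.name}' has a zero-length point scale; "
            "the inverse map is undefined")
    slack = _RANGE_RTOL * max(1.0, scale.max_points)
    if points < -slack or points > scale.max_points + slack:
        raise ValueError(
            f"points {points} outside [0, {scale.max_points}] for "
            f"predictor '{predictor.name}'")
    v = (points - scale.offset) / scale.slope
    return float(min(max(v, predictor.min), predictor.max))


def build_point_scales(model: ModelSpec,
                       p_max: float = DEFAULT_P_MAX) -> ScaleSet:
    """Build the full scale set for a model.

    The initializer's scale attains exactly ``p_max``; all other maxima
    are the ratio of scores times ``p_max``, so multiplying every
    coefficient by a common positive constant leaves the scales unchanged.
    """
    if p_max <= 0.0:
        raise ModelConstructionError(f"p_max must be positive, got {p_max}")
    init = select_initializer(model)
    init_score = absolute_max_beta(model.predictors[init])
    scales = []
    for i, pred in enumerate(model.predictors):
        pmax_i = p_max if i == init else max_points(pred, init_score, p_max)
        scales.append(_make_scale(i, pred, pmax_i))
    return ScaleSet(scales=tuple(scales), initializer_index=init, p_max=p_max)
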