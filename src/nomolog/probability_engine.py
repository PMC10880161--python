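"""Probability assignment: mapping the total point sum to a probability.

The linear predictor ``b0 + sum_i b_i x_i`` attains its extremes at the
corners of the predictor box: ``min_value`` takes each positive-coefficient
predictor at its minimum and each negative one at its maximum (and vice
versa for ``max_value``).  The point-assignment construction makes the
total point sum an exact affine image of the linear predictor, so placing
the total-points ruler affinely onto ``[min_value, max_value]`` and
applying the sigmoid reproduces the model probability without loss.  The
probability panel draws that sigmoid explicitly with a uniformly scaled
probability axis, instead of the unevenly spaced probability ruler of
traditional nomograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import expit, logit

from .model_meta import ModelSpec
from .point_engine import ScaleSet

__all__ = [
    "ProbabilityMap",
    "ProbabilityCurve",
    "sigmoid",
    "linear_range",
    "total_max_points",
    "build_probability_map",
    "total_points_to_probability",
    "probability_to_total_points",
    "probability_curve",
]

_TOL = 1e-9
#: beyond this the sigmoid saturates to 0/1 in double precision anyway
_CLIP = 700.0


def sigmoid(x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Logistic function ``1 / (1 + exp(-x))``, numerically stable.

    Inputs are clipped at +-700 before exponentiation; the result is
    exact to double precision everywhere on that interval.
    """
    x = np.clip(x, -_CLIP, _CLIP)
    out = expit(x)
    return float(out) if np.isscalar(x) or np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ProbabilityMap:
    """Affine bridge between total points and the sigmoid input.

    ``min_value``/``max_value`` are the tight bounds of the linear
    predictor over the predictor box; ``total_max_points`` is the sum of
    per-predictor point maxima.  The intercept is carried for audit only.
    """

    min_value: float
    max_value: float
    total_max_points: float
    intercept: float

    @property
    def attainable_probabilities(self) -> tuple[float, float]:
        return (sigmoid(self.min_value), sigmoid(self.max_value))


@dataclass(frozen=True)
class ProbabilityCurve:
    """Sampled sigmoid over the total-points ruler, uniformly spaced."""

    totals: np.ndarray
    probabilities: np.ndarray


def linear_range(model: ModelSpec) -> tuple[float, float]:
    """Tight bounds of ``b0 + sum b_i x_i`` over the predictor box.

    Each one-hot level is treated as an independent [0, 1] coordinate, so
    for nominal groups the interval covers a superset of the totals
    attainable under mutual exclusivity; the round-trip identity still
    holds at every feasible assignment.
    """
    lo = hi = model.intercept
    for p in model.predictors:
        if p.coef >= 0.0:
            lo += p.coef * p.min
            hi += p.coef * p.max
        else:
            lo += p.coef * p.max
            hi += p.coef * p.min
    return float(lo), float(hi)


def total_max_points(scales: ScaleSet) -> float:
    """Maximum total point sum: sum of the per-predictor maxima."""
    return scales.total_max_points


def build_probability_map(model: ModelSpec, scales: ScaleSet) -> ProbabilityMap:
    lo, hi = linear_range(model)
    return ProbabilityMap(min_value=lo, max_value=hi,
                          total_max_points=total_max_points(scales),
                          intercept=model.intercept)


def _check_total(pm: ProbabilityMap, p_total: float, strict: bool) -> float:
    slack = _TOL * max(1.0, pm.total_max_points)
    if p_total < -slack or p_total > pm.total_max_points + slack:
        if strict:
            raise ValueError(
                f"total points {p_total} outside [0, {pm.total_max_points}]")
        p_total = min(max(p_total, 0.0), pm.total_max_points)
    return min(max(p_total, 0.0), pm.total_max_points)


def total_points_to_probability(pm: ProbabilityMap, p_total: float,
                                strict: bool = True) -> float:
    """Probability read off the nomogram for a total point sum.

    The total is placed proportionally onto ``[min_value, max_value]``
    and passed through the sigmoid.
    """
    p_total = _check_total(pm, p_total, strict)
    frac = p_total / pm.total_max_points
    v = pm.min_value + frac * (pm.max_value - pm.min_value)
    return sigmoid(v)


def probability_to_total_points(pm: ProbabilityMap, p: float) -> float:
    """Unique total point sum mapping to probability ``p``.

    Raises ``ValueError`` when ``p`` lies outside the probabilities
    attainable over the predictor box (e.g. a decision threshold the
    model can never reach).
    """
    p_lo, p_hi = pm.attainable_probabilities
    slack = _TOL
    if p < p_lo - slack or p > p_hi + slack:
        raise ValueError(
            f"probability {p} not attainable by this model "
            f"(range [{p_lo:.6g}, {p_hi:.6g}])")
    p = min(max(p, p_lo), p_hi)
    v = float(logit(p))
    span = pm.max_value - pm.min_value
    if span == 0.0:
        return 0.0
    frac = (v - pm.min_value) / span
    total = frac * pm.total_max_points
    return float(min(max(total, 0.0), pm.total_max_points))


def probability_curve(pm: ProbabilityMap, n_samples: int = 512) -> ProbabilityCurve:
    """Sample the total->probability map at uniformly spaced totals."""
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    totals = np.linspace(0.0, pm.total_max_points, n_samples)
    frac = totals / pm.total_max_points
    v = pm.min_value + frac * (pm.max_value - pm.min_value)
    return ProbabilityCurve(totals=totals, probabilities=expit(np.clip(v, -_CLIP, _CLIP)))
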