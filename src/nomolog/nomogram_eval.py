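"""Nomogram evaluation: assign points, sum, map to probability, classify.

Two modes mirror how the chart is used in practice.  *Exact* mode keeps
every point value as a real number and reproduces the underlying logistic
model to float precision.  *Graphical* mode emulates reading the printed
chart by eye: each per-predictor point and the total-points lookup are
rounded to the nearest tick of a given granularity before the probability
is read off.  The rounding error is analytically bounded (see
:func:`graphical_error_bound`), which is what keeps hand-read predictions
trustworthy away from the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model_meta import ModelSpec
from .point_engine import ScaleSet, value_to_points
from .probability_engine import ProbabilityMap, total_points_to_probability

__all__ = [
    "EvaluationResult",
    "evaluate",
    "classify",
    "graphical_error_bound",
    "DEFAULT_GRANULARITY",
]

#: default tick granularity for graphical-mode reading, in points.
#: Printed nomogram rulers are typically labelled every 10 points and
#: read to the nearest label.
DEFAULT_GRANULARITY = 10.0


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of evaluating one patient on a nomogram."""

    per_predictor_points: tuple[float, ...]
    total_points: float
    probability: float
    risk_label: Optional[str]  # "high" / "low", present iff model has a threshold
    mode: str  # "exact" | "graphical"
    granularity: Optional[float]


def classify(probability: float, threshold: float) -> str:
    """Risk label against a probability threshold.

    High risk requires the probability to *strictly* exceed the
    threshold; the boundary case is labelled low, resolving the tie
    deterministically.
    """
    return "high" if probability > threshold else "low"


def _round_to(x: float, granularity: float) -> float:
    return round(x / granularity) * granularity


def evaluate(model: ModelSpec, scales: ScaleSet, pm: ProbabilityMap,
             values: Sequence[float], mode: str = "exact",
             granularity: float = DEFAULT_GRANULARITY,
             strict: bool = True) -> EvaluationResult:
    """Run the full nomogram calculation flow for one value vector.

    Parameters
    ----------
    values
        One value per predictor, in model order.  One-hot levels of a
        nominal variable are separate entries (0 or 1 each).
    mode
        ``"exact"`` keeps unrounded points; ``"graphical"`` rounds each
        per-predictor point and the total to the nearest multiple of
        ``granularity`` before the probability lookup, emulating reading
        the chart at its tick resolution.
    strict
        Reject out-of-range values instead of clamping them.
    """
    if len(values) != model.d:
        raise ValueError(
            f"expected {model.d} values (one per predictor), got {len(values)}")
    if mode not in ("exact", "graphical"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode == "graphical" and not granularity > 0.0:
        raise ValueError("graphical mode requires granularity > 0")

    pts = [value_to_points(s, p, float(v), strict=strict)
           for s, p, v in zip(scales.scales, model.predictors, values)]
    if mode == "graphical":
        # rounding can push a point just past its axis maximum (e.g. 14
        # rounded at granularity 15); the total is clamped to the ruler
        pts = [_round_to(x, granularity) for x in pts]
        total = _round_to(sum(pts), granularity)
        total = min(max(total, 0.0), pm.total_max_points)
    else:
        total = sum(pts)
    prob = total_points_to_probability(pm, total, strict=strict)

    label = None
    if model.threshold is not None:
        label = classify(prob, model.threshold)
    return EvaluationResult(per_predictor_points=tuple(pts),
                            total_points=float(total), probability=prob,
                            risk_label=label, mode=mode,
                            granularity=granularity if mode == "graphical" else None)


def graphical_error_bound(pm: ProbabilityMap, d: int, granularity: float) -> float:
    """Worst-case probability error of graphical-mode reading.

    Each of the ``d`` predictor axes and the total ruler is read to
    within half a tick (``granularity / 2`` points).  The accumulated
    point error propagates through the affine points->sigmoid-input map
    (slope ``(max_value - min_value) / total_max_points``) and the
    sigmoid, whose derivative never exceeds 1/4::

        1/4 * (max_value - min_value) / P_total_max * (d + 1) * g / 2
    """
    span = pm.max_value - pm.min_value
    return 0.25 * span / pm.total_max_points * (d + 1) * (granularity / 2.0)
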