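"""Synthetic models and patients, plus the printed CMV reference model.

Everything here is seed-deterministic so test suites and simulations are
reproducible without shipping data files.  ``cmv_model`` carries the
published refractory/recurrent cytomegalovirus-infection model (logistic
coefficients, intercept and decision threshold) used throughout the
worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_meta import (
    NOMINAL_DELIMITER,
    ModelSpec,
    PredictorSpec,
    validate_model,
)

__all__ = [
    "FixtureConfig",
    "random_model",
    "random_patients",
    "cmv_model",
    "CMV_EXAMPLE_PATIENT",
]

#: worked-example patient: age 50, gender 1, underlying disease 1,
#: cumulative prednisone dose 14, CD34+ cell count 7
CMV_EXAMPLE_PATIENT = (50.0, 1.0, 1.0, 14.0, 7.0)

_DEFAULT_STYLES = ("unit", "wide", "binary")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for random model generation.

    ``range_styles`` entries: ``unit`` (span-1 continuous), ``wide``
    (continuous, span 5..200), ``binary`` (0/1 discrete), ``nominal-k``
    for an integer k >= 2 (a k-level one-hot group, k predictor rows).
    ``d`` counts style slots, so a nominal group consumes one slot but
    contributes k rows.
    """

    d: int = 4
    coef_scale: float = 1.0
    range_styles: tuple[str, ...] = _DEFAULT_STYLES
    threshold_included: bool = True
    seed: int = 0


def _nonzero_normal(rng: np.random.Generator, scale: float) -> float:
    c = 0.0
    while abs(c) < 1e-6 * scale:
        c = rng.normal(0.0, scale)
    return float(c)


def random_model(config: FixtureConfig) -> ModelSpec:
    """Generate a random valid model; fully determined by ``config.seed``."""
    if config.d < 1:
        raise ValueError("need d >= 1")
    rng = np.random.default_rng(config.seed)
    predictors: list[PredictorSpec] = []
    for slot in range(config.d):
        style = config.range_styles[int(rng.integers(len(config.range_styles)))]
        position = "up" if rng.integers(2) == 0 else "down"
        if style.startswith("nominal-"):
            k = int(style.split("-", 1)[1])
            parent = f"g{slot + 1}"
            for lvl in range(k):
                predictors.append(PredictorSpec(
                    name=f"{parent}{NOMINAL_DELIMITER}L{lvl + 1}",
                    coef=_nonzero_normal(rng, config.coef_scale),
                    min=0.0, max=1.0, dtype="nominal", position=position))
            continue
        coef = _nonzero_normal(rng, config.coef_scale)
        if style == "binary":
            predictors.append(PredictorSpec(
                name=f"x{slot + 1}", coef=coef, min=0.0, max=1.0,
                dtype="discrete", position=position))
        else:
            lo = float(rng.uniform(-10.0, 10.0))
            span = 1.0 if style == "unit" else float(rng.uniform(5.0, 200.0))
            predictors.append(PredictorSpec(
                name=f"x{slot + 1}", coef=coef, min=lo, max=lo + span,
                dtype="continuous", position=position))
    threshold = float(rng.uniform(0.05, 0.95)) if config.threshold_included else None
    model = ModelSpec(intercept=float(rng.normal(0.0, 1.0)),
                      threshold=threshold, predictors=tuple(predictors))
    # belt-and-braces: a generated fixture must always validate cleanly
    rows = [("intercept", model.intercept, "", "", "", ""),
            ("threshold", model.threshold if threshold is not None else "", "", "", "", "")]
    rows += [(p.name, p.coef, p.min, p.max, p.dtype, p.position)
             for p in model.predictors]
    checked, report = validate_model(rows)
    assert checked is not None, report.errors
    return model


def random_patients(model: ModelSpec, n: int, seed: int = 0) -> list[tuple[float, ...]]:
    """Draw ``n`` value vectors uniformly within each predictor's range.

    One-hot groups get at most one active level per patient (a uniformly
    chosen level, or the implicit baseline with the same probability);
    discrete/ordinal predictors get integer values.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    groups = model.nominal_groups
    grouped_idx = {i for idxs in groups.values() for i in idxs}
    patients = []
    for _ in range(n):
        values = [0.0] * model.d
        for i, p in enumerate(model.predictors):
            if i in grouped_idx:
                continue
            if p.dtype in ("discrete", "ordinal"):
                lo, hi = int(np.ceil(p.min)), int(np.floor(p.max))
                values[i] = float(rng.integers(lo, hi + 1))
            else:
                values[i] = float(rng.uniform(p.min, p.max))
        for idxs in groups.values():
            pick = int(rng.integers(len(idxs) + 1))  # len(idxs) = baseline
            if pick < len(idxs):
                values[idxs[pick]] = 1.0
        patients.append(tuple(values))
    return patients


def cmv_model(ranges: Optional[Sequence[tuple[float, float]]] = None) -> ModelSpec:
    """The published CMV-infection logistic model as a ModelSpec.

    Coefficients, intercept (-1.2926) and threshold (0.5243) are the
    published values.  The predictor *ranges* are package defaults
    (age [0, 100], gender [0, 1], underlying disease [0, 1], prednisone
    dose [0, 50], CD34+ count [0, 20]) chosen to enclose plausible
    clinical values — the publication shows ranges only graphically.
    Exact-mode evaluation is provably invariant to the range choice;
    only point values and axis extents depend on it.
    """
    defaults = [(0.0, 100.0), (0.0, 1.0), (0.0, 1.0), (0.0, 50.0), (0.0, 20.0)]
    ranges = list(ranges) if ranges is not None else defaults
    if len(ranges) != 5:
        raise ValueError("cmv_model needs exactly 5 (min, max) pairs")
    names_coefs = [
        ("age", 0.0322, "continuous", "up"),
        ("gender", -0.0696, "discrete", "down"),
        ("underlying_disease", 0.5492, "discrete", "up"),
        ("prednisone_dose", 0.0963, "continuous", "up"),
        ("cd34_count", -0.0771, "continuous", "down"),
    ]
    predictors = tuple(
        PredictorSpec(name=n, coef=c, min=lo, max=hi, dtype=t, position=pos)
        for (n, c, t, pos), (lo, hi) in zip(names_coefs, ranges))
    return ModelSpec(intercept=-1.2926, threshold=0.5243, predictors=predictors)
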