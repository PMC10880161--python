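"""Simulated-reader study: how faithfully can a nomogram be read by eye?

A human reading a printed chart cannot place a value more finely than
the tick granularity, and adds some positional noise on top.  The
simulator models each axis reading as the exact point value plus
independent Gaussian noise (in points), rounded to the tick granularity
and clamped to the axis; the total is likewise rounded before the
probability lookup.  Discrimination (confusion matrix and accuracy of
read risk labels against the model's labels) and calibration (binned
read vs. model probabilities with normal-approximation confidence
intervals) summarise the resulting fidelity, mirroring how clinical
prediction charts are conventionally evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .model_meta import ModelSpec
from .nomogram_eval import classify, evaluate
from .point_engine import ScaleSet, value_to_points
from .probability_engine import ProbabilityMap, total_points_to_probability

__all__ = [
    "ReadingCase",
    "ReadingStudy",
    "CalibrationBin",
    "CalibrationSummary",
    "simulate_readings",
    "summarize",
    "plot_calibration",
]


@dataclass(frozen=True)
class ReadingCase:
    values: tuple[float, ...]
    exact_probability: float
    read_probability: float
    exact_label: Optional[str]
    read_label: Optional[str]


@dataclass(frozen=True)
class ReadingStudy:
    """A batch of simulated graphical readings; fully seed-reproducible."""

    cases: tuple[ReadingCase, ...]
    granularity: float
    noise_sd: float
    seed: int


@dataclass(frozen=True)
class CalibrationBin:
    lo: float
    hi: float
    count: int
    mean_read: Optional[float]
    mean_exact: Optional[float]
    ci_half_width: Optional[float]


@dataclass(frozen=True)
class CalibrationSummary:
    """Discrimination and calibration summaries of a reading study.

    ``confusion`` is ``{"tp", "fp", "fn", "tn"}`` with the model label as
    truth (tp: both high).  ``accuracy`` is None when no labels exist.
    """

    bins: tuple[CalibrationBin, ...]
    accuracy: Optional[float]
    confusion: Optional[dict[str, int]]
    n_cases: int
    confidence: float


def _round_clamp(x: float, granularity: float, lo: float, hi: float) -> float:
    if granularity > 0.0:
        x = round(x / granularity) * granularity
    return min(max(x, lo), hi)


def simulate_readings(model: ModelSpec, scales: ScaleSet, pm: ProbabilityMap,
                      patients: Sequence[Sequence[float]],
                      granularity: float = 10.0, noise_sd: float = 0.0,
                      seed: int = 0) -> ReadingStudy:
    """Simulate graphical readings of a batch of patients.

    Per patient and axis: exact points + N(0, noise_sd), rounded to the
    granularity (0 disables rounding) and clamped to the axis; the total
    is rounded and clamped to the total ruler before the probability
    lookup.  With granularity 0 and noise 0 the read probabilities equal
    the exact ones.
    """
    if granularity < 0.0 or noise_sd < 0.0:
        raise ValueError("granularity and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    theta = model.threshold
    cases = []
    for values in patients:
        exact = evaluate(model, scales, pm, values, mode="exact")
        noise = rng.normal(0.0, 1.0, size=model.d) * noise_sd
        read_pts = [
            _round_clamp(p + e, granularity, 0.0, s.max_points)
            for p, e, s in zip(exact.per_predictor_points, noise, scales.scales)
        ]
        total = _round_clamp(sum(read_pts), granularity, 0.0,
                             pm.total_max_points)
        read_prob = total_points_to_probability(pm, total)
        cases.append(ReadingCase(
            values=tuple(float(v) for v in values),
            exact_probability=exact.probability,
            read_probability=read_prob,
            exact_label=classify(exact.probability, theta) if theta is not None else None,
            read_label=classify(read_prob, theta) if theta is not None else None,
        ))
    return ReadingStudy(cases=tuple(cases), granularity=granularity,
                        noise_sd=noise_sd, seed=seed)


def summarize(study: ReadingStudy, threshold: Optional[float] = None,
              n_bins: int = 10, confidence: float = 0.95) -> CalibrationSummary:
    """Summarise a reading study.

    Calibration uses equal-width bins on the *read* probability over
    [0, 1]; each bin reports the mean read and mean exact probability and
    a normal-approximation confidence half-width for the latter.  Empty
    bins are emitted with count 0 and no interval.  Labels are recomputed
    against ``threshold`` when given, otherwise the study's stored labels
    are used.
    """
    if not study.cases:
        raise ValueError("cannot summarise an empty study")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    read = np.array([c.read_probability for c in study.cases])
    exact = np.array([c.exact_probability for c in study.cases])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((read * n_bins).astype(int), n_bins - 1)
    z = norm.ppf(0.5 + confidence / 2.0)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            bins.append(CalibrationBin(edges[b], edges[b + 1], 0,
                                       None, None, None))
            continue
        ex = exact[mask]
        half = float(z * ex.std(ddof=1) / np.sqrt(n)) if n >= 2 else None
        bins.append(CalibrationBin(float(edges[b]), float(edges[b + 1]), n,
                                   float(read[mask].mean()),
                                   float(ex.mean()), half))

    if threshold is not None:
        exact_labels = ["high" if p > threshold else "low" for p in exact]
        read_labels = ["high" if p > threshold else "low" for p in read]
    else:
        exact_labels = [c.exact_label for c in study.cases]
        read_labels = [c.read_label for c in study.cases]

    accuracy = confusion = None
    if all(l is not None for l in exact_labels):
        confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for e, r in zip(exact_labels, read_labels):
            key = {("high", "high"): "tp", ("low", "high"): "fp",
                   ("high", "low"): "fn", ("low", "low"): "tn"}[(e, r)]
            confusion[key] += 1
        accuracy = (confusion["tp"] + confusion["tn"]) / len(study.cases)

    return CalibrationSummary(bins=tuple(bins), accuracy=accuracy,
                              confusion=confusion, n_cases=len(study.cases),
                              confidence=confidence)


def plot_calibration(summary: CalibrationSummary,
                     dest: Union[str, Path]) -> Path:
    """Plot the binned calibration curve with its confidence intervals."""
    from matplotlib.figure import Figure

    dest = Path(dest)
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    xs, ys, errs = [], [], []
    for b in summary.bins:
        if b.count == 0:
            continue
        xs.append(b.mean_read)
        ys.append(b.mean_exact)
        errs.append(b.ci_half_width if b.ci_half_width is not None else 0.0)
    ax.errorbar(xs, ys, yerr=errs, fmt="o-", capsize=3, color="black")
    ax.plot([0, 1], [0, 1], "--", color="grey", linewidth=0.8)
    ax.set_xlabel("Read probability")
    ax.set_ylabel("Model probability")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.savefig(dest)
    return dest


def exact_points(model: ModelSpec, scales: ScaleSet,
                 values: Sequence[float]) -> list[float]:
    """Per-axis exact point values for one patient (no rounding)."""
    return [value_to_points(s, p, float(v))
            for s, p, v in zip(scales.scales, model.predictors, values)]
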