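"""Nomogram geometry and rendering.

The chart is a stack of horizontal axes in normalized coordinates:

* a points ruler spanning ``0..P^max`` (top),
* one axis per predictor — one-hot levels of a nominal variable share a
  single axis — with *value* tick labels placed at their point
  positions,
* a total-points ruler spanning ``0..P_total_max``,
* a probability panel drawing the sigmoid over the total-points scale
  with a uniformly spaced probability axis.

Axis style encodes the data type: solid lines for continuous predictors,
dashed lines for nominal, discrete and ordinal ones (the admissible
values are isolated).  Tick-label side follows each predictor's
``position`` field.  When the model carries a decision threshold that is
attainable over the predictor box, a dashed vertical marker is drawn
through the total ruler and the panel at its total-points preimage.

Rendering goes through matplotlib; SVG, PNG and PDF are supported.  SVG
output tags every axis with a stable ``id`` (``points-ruler``,
``predictor-axis-<k>``, ``total-ruler``, ``probability-panel``,
``threshold-marker``) so the structure can be checked programmatically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib
import numpy as np
from matplotlib.figure import Figure

from .model_meta import ModelSpec, PredictorSpec
from .point_engine import ScaleSet, value_to_points
from .probability_engine import (
    ProbabilityMap,
    probability_curve,
    probability_to_total_points,
)

__all__ = [
    "AxisSpec",
    "NomogramGeometry",
    "RenderOptions",
    "generate_ticks",
    "compute_layout",
    "render",
]

_NICE_MANTISSAS = (1.0, 2.0, 2.5, 5.0)
#: spans smaller than this fraction of the endpoint magnitude get
#: endpoint-only ticks (labels would be unreadable anyway)
_DEGENERATE_REL_SPAN = 1e-3
#: discrete/ordinal axes tick every level up to this many levels
_MAX_ENUMERATED_LEVELS = 25


@dataclass(frozen=True)
class AxisSpec:
    """One horizontal slot of the nomogram.

    ``ticks`` holds ``(x, label)`` pairs with ``x`` in normalized [0, 1]
    chart coordinates.  ``row`` is the vertical slot index, 0 at the top.
    """

    kind: str  # points_ruler | predictor | total_ruler | probability_panel
    name: str
    style: str  # solid | dashed
    label_side: str  # up | down
    ticks: tuple[tuple[float, str], ...]
    row: int
    predictor_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class RenderOptions:
    """Style knobs for layout and rendering.

    Sizes are in inches (matplotlib convention); ``tick_target`` is the
    desired number of labelled ticks per continuous axis.
    """

    width: float = 10.0
    height: Optional[float] = None  # derived from axis count when None
    font_size: float = 9.0
    axis_color: str = "black"
    tick_target: int = 11
    show_probability_curve: bool = True
    curve_samples: int = 512
    dpi: int = 100

    def with_overrides(self, **kwargs) -> "RenderOptions":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NomogramGeometry:
    """Laid-out nomogram, ready to render.

    ``curve`` is the sampled sigmoid as ``(x, probability)`` with ``x``
    on the total-ruler scale (total / P_total_max);
    ``threshold_x`` is the marker position on that same scale, or None
    when the model has no (attainable) threshold.
    """

    axes: tuple[AxisSpec, ...]
    curve: tuple[tuple[float, float], ...]
    threshold_x: Optional[float]
    threshold_value: Optional[float]
    p_max: float
    total_max_points: float
    options: RenderOptions = field(default_factory=RenderOptions)

    @property
    def n_predictor_axes(self) -> int:
        return sum(1 for a in self.axes if a.kind == "predictor")


def _decimals_for_step(step: float) -> int:
    if step >= 1.0:
        return 0
    return max(0, -int(math.floor(math.log10(step))) + 1)


def _fmt_value(v: float, step: Optional[float] = None) -> str:
    """Compact tick label: integers without a decimal point."""
    if step is not None:
        v = round(v, _decimals_for_step(step) + 2)
    if abs(v - round(v)) < 1e-9 * max(1.0, abs(v)):
        return str(int(round(v)))
    return f"{v:g}"


def generate_ticks(lo: float, hi: float, target_count: int = 11) -> list[float]:
    """'Nice' tick values covering ``[lo, hi]``, endpoints included.

    Steps are drawn from {1, 2, 2.5, 5} x 10^k; the step whose tick
    count lands closest to ``target_count`` (within a factor of two of
    it when possible) wins.  Spans below 0.1% of the endpoint magnitude
    are treated as degenerate and yield the endpoints only.
    """
    if not hi > lo:
        raise ValueError(f"need hi > lo, got [{lo}, {hi}]")
    if target_count < 2:
        raise ValueError("target_count must be at least 2")
    span = hi - lo
    if span <= _DEGENERATE_REL_SPAN * max(abs(lo), abs(hi)):
        return [lo, hi]

    raw = span / (target_count - 1)
    k = math.floor(math.log10(raw))
    candidates = sorted({m * 10.0 ** e for m in _NICE_MANTISSAS
                         for e in (k - 1, k, k + 1)})

    def build(step: float) -> list[float]:
        eps = step * 1e-9
        first = math.ceil((lo - eps) / step)
        last = math.floor((hi + eps) / step)
        dec = _decimals_for_step(step) + 2
        vals = [round(i * step, dec) for i in range(first, last + 1)]
        if not vals or vals[0] > lo + eps:
            vals.insert(0, lo)
        else:
            vals[0] = lo if abs(vals[0] - lo) <= eps else vals[0]
        if vals[-1] < hi - eps:
            vals.append(hi)
        else:
            vals[-1] = hi if abs(vals[-1] - hi) <= eps else vals[-1]
        return vals

    best, best_key = None, None
    for step in candidates:
        vals = build(step)
        n = len(vals)
        in_band = target_count / 2 <= n <= 2 * target_count
        key = (0 if in_band else 1, abs(n - target_count), step)
        if best_key is None or key < best_key:
            best, best_key = vals, key
    return best


def _predictor_tick_values(pred: PredictorSpec, target: int) -> tuple[list[float], Optional[float]]:
    """Tick values for a stand-alone predictor axis, plus the step used."""
    if pred.dtype == "continuous":
        vals = generate_ticks(pred.min, pred.max, target)
        step = vals[1] - vals[0] if len(vals) > 2 else None
        return vals, step
    # discrete / ordinal / lone nominal: enumerate integer levels when few
    lo, hi = math.ceil(pred.min), math.floor(pred.max)
    n_levels = hi - lo + 1
    if 2 <= n_levels <= _MAX_ENUMERATED_LEVELS:
        vals = [float(v) for v in range(lo, hi + 1)]
        if vals[0] > pred.min:
            vals.insert(0, pred.min)
        if vals[-1] < pred.max:
            vals.append(pred.max)
        return vals, 1.0
    return generate_ticks(pred.min, pred.max, target), None


def compute_layout(model: ModelSpec, scales: ScaleSet, pm: ProbabilityMap,
                   options: Optional[RenderOptions] = None) -> NomogramGeometry:
    """Compute the full nomogram geometry for a model.

    Predictor axes appear in file order, with every one-hot group
    collapsed onto a single dashed axis whose level labels sit at the
    point value each level contributes when active (implicit baseline at
    0 points).  Predictor tick labels are *values*, placed at
    ``value_to_points(value) / p_max`` on the shared horizontal scale.
    """
    options = options or RenderOptions()
    target = options.tick_target
    axes: list[AxisSpec] = []
    row = 0

    pts_vals = generate_ticks(0.0, scales.p_max, target)
    axes.append(AxisSpec(kind="points_ruler", name="Points", style="solid",
                         label_side="up",
                         ticks=tuple((v / scales.p_max, _fmt_value(v))
                                     for v in pts_vals),
                         row=row))
    row += 1

    handled_parents: set[str] = set()
    for i, pred in enumerate(model.predictors):
        parent = pred.nominal_parent
        if parent is not None:
            if parent in handled_parents:
                continue
            handled_parents.add(parent)
            indices = model.nominal_groups[parent]
            ticks: list[tuple[float, str]] = []
            for j in indices:
                pj, sj = model.predictors[j], scales.scales[j]
                x = value_to_points(sj, pj, 1.0) / scales.p_max
                ticks.append((x, pj.level_label))
            if not any(abs(x) < 1e-12 for x, _ in ticks):
                ticks.insert(0, (0.0, "(ref)"))
            ticks.sort(key=lambda t: t[0])
            axes.append(AxisSpec(kind="predictor", name=parent,
                                 style="dashed",
                                 label_side=model.predictors[indices[0]].position,
                                 ticks=tuple(ticks), row=row,
                                 predictor_indices=indices))
            row += 1
            continue

        scale = scales.scales[i]
        if scale.max_points == 0.0:
            # zero-coefficient axis: no spread of points; single tick
            ticks = ((0.0, _fmt_value(pred.min)),)
        else:
            vals, step = _predictor_tick_values(pred, target)
            ticks = tuple(
                (value_to_points(scale, pred, v) / scales.p_max,
                 _fmt_value(v, step))
                for v in vals)
        style = "solid" if pred.dtype == "continuous" else "dashed"
        axes.append(AxisSpec(kind="predictor", name=pred.name, style=style,
                             label_side=pred.position, ticks=ticks, row=row,
                             predictor_indices=(i,)))
        row += 1

    tmax = pm.total_max_points
    tot_vals = generate_ticks(0.0, tmax, target)
    axes.append(AxisSpec(kind="total_ruler", name="Total points",
                         style="solid", label_side="up",
                         ticks=tuple((v / tmax, _fmt_value(v, tot_vals[1] - tot_vals[0]))
                                     for v in tot_vals),
                         row=row))
    row += 1

    p_lo, p_hi = pm.attainable_probabilities
    panel_ticks: list[tuple[float, str]] = []
    if p_hi - p_lo > 1e-12:
        for p in generate_ticks(p_lo, p_hi, max(4, target // 2)):
            x = probability_to_total_points(pm, p) / tmax
            panel_ticks.append((x, f"{p:.2f}"))
    axes.append(AxisSpec(kind="probability_panel", name="Probability",
                         style="solid", label_side="down",
                         ticks=tuple(panel_ticks), row=row))

    curve = probability_curve(pm, options.curve_samples)
    curve_pairs = tuple(zip((curve.totals / tmax).tolist(),
                            curve.probabilities.tolist()))

    threshold_x = None
    if model.threshold is not None:
        try:
            threshold_x = probability_to_total_points(pm, model.threshold) / tmax
        except ValueError:
            warnings.warn(
                f"decision threshold {model.threshold} is not attainable over "
                "the predictor box; marker omitted", stacklevel=2)

    return NomogramGeometry(axes=tuple(axes), curve=curve_pairs,
                            threshold_x=threshold_x,
                            threshold_value=model.threshold,
                            p_max=scales.p_max, total_max_points=tmax,
                            options=options)


# ---------------------------------------------------------------------------
# rendering

_PANEL_SLOTS = 2.5  # the probability panel is taller than a plain axis


def _axis_y(geometry: NomogramGeometry) -> tuple[dict[int, float], float]:
    """Vertical center (chart-normalized y) of each axis row, plus slot height."""
    n_plain = len(geometry.axes) - 1
    total = n_plain + _PANEL_SLOTS
    top, bottom = 0.93, 0.05
    slot = (top - bottom) / total
    return {a.row: top - a.row * slot for a in geometry.axes}, slot


def render(geometry: NomogramGeometry, dest: Union[str, Path],
           format: Optional[str] = None) -> Path:
    """Render a laid-out nomogram to SVG, PNG or PDF.

    The format is inferred from the destination suffix unless given
    explicitly.  Output is deterministic for a fixed geometry and
    library version (SVG hash salt pinned, timestamps stripped).
    """
    dest = Path(dest)
    fmt = (format or dest.suffix.lstrip(".")).lower()
    if fmt not in ("svg", "png", "pdf"):
        raise ValueError(f"unsupported format '{fmt}'")
    opts = geometry.options
    n_axes = len(geometry.axes)
    height = opts.height or max(4.5, 0.8 * (n_axes + _PANEL_SLOTS))

    fig = Figure(figsize=(opts.width, height), dpi=opts.dpi)
    ax = fig.add_axes([0.16, 0.0, 0.80, 1.0])
    ax.set_axis_off()
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.04)

    ys, slot = _axis_y(geometry)
    tick_h = 0.25 * slot
    fs = opts.font_size
    color = opts.axis_color
    pred_counter = 0

    for axis in geometry.axes:
        y = ys[axis.row]
        if axis.kind == "predictor":
            gid = f"predictor-axis-{pred_counter}"
            pred_counter += 1
        elif axis.kind == "points_ruler":
            gid = "points-ruler"
        elif axis.kind == "total_ruler":
            gid = "total-ruler"
        else:
            gid = "probability-panel"

        if axis.kind == "probability_panel":
            _draw_panel(ax, geometry, axis, y, slot, fs, color, gid)
            continue

        xs = [x for x, _ in axis.ticks]
        lo, hi = (min(xs), max(xs)) if xs else (0.0, 1.0)
        linestyle = "--" if axis.style == "dashed" else "-"
        (line,) = ax.plot([lo, hi], [y, y], linestyle=linestyle,
                          color=color, linewidth=1.2)
        line.set_gid(gid)
        ax.text(-0.03, y, axis.name, ha="right", va="center",
                fontsize=fs, color=color)
        up = axis.label_side == "up"
        for x, label in axis.ticks:
            ax.plot([x, x], [y, y + (tick_h if up else -tick_h)],
                    linestyle="-", color=color, linewidth=0.9)
            ax.text(x, y + (tick_h * 1.4 if up else -tick_h * 1.4), label,
                    ha="center", va="bottom" if up else "top",
                    fontsize=fs * 0.85, color=color)

    if geometry.threshold_x is not None:
        total_axis = next(a for a in geometry.axes if a.kind == "total_ruler")
        panel_axis = next(a for a in geometry.axes if a.kind == "probability_panel")
        y_top = ys[total_axis.row] + 0.3 * slot
        y_bot = ys[panel_axis.row] - (_PANEL_SLOTS - 0.5) * slot
        (marker,) = ax.plot([geometry.threshold_x] * 2, [y_bot, y_top],
                            linestyle="--", color="crimson", linewidth=1.0)
        marker.set_gid("threshold-marker")
        ax.text(geometry.threshold_x, y_bot - 0.15 * slot,
                f"θ = {geometry.threshold_value:g}", ha="center",
                va="top", fontsize=fs * 0.85, color="crimson")

    save_kwargs = {}
    if fmt == "svg":
        save_kwargs["metadata"] = {"Date": None}
    elif fmt == "pdf":
        save_kwargs["metadata"] = {"CreationDate": None}
    with matplotlib.rc_context({"svg.hashsalt": "nomolog"}):
        fig.savefig(dest, format=fmt, dpi=opts.dpi, **save_kwargs)
    return dest


def _draw_panel(ax, geometry: NomogramGeometry, axis: AxisSpec, y_top: float,
                slot: float, fs: float, color: str, gid: str) -> None:
    """Probability panel: sigmoid over the total scale, uniform y axis."""
    height = (_PANEL_SLOTS - 0.5) * slot
    y0 = y_top - height  # probability 0 at the bottom of the band
    if geometry.options.show_probability_curve and geometry.curve:
        xs = [x for x, _ in geometry.curve]
        ps = [p for _, p in geometry.curve]
        yy = [y0 + p * height for p in ps]
        (line,) = ax.plot(xs, yy, linestyle="-", color=color, linewidth=1.4)
    else:
        (line,) = ax.plot([0.0, 1.0], [y0, y0], linestyle="-",
                          color=color, linewidth=1.2)
    line.set_gid(gid)
    ax.text(-0.03, y0 + 0.5 * height, axis.name, ha="right", va="center",
            fontsize=fs, color=color)
    # uniform probability axis on the left edge of the band
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        ax.plot([-0.005, 0.0], [y0 + frac * height] * 2, "-",
                color=color, linewidth=0.8)
        ax.text(-0.012, y0 + frac * height, f"{frac:g}", ha="right",
                va="center", fontsize=fs * 0.75, color=color)
    # probability landmarks projected onto the total scale
    for x, label in axis.ticks:
        p = float(label)
        yp = y0 + p * height
        ax.plot([x, x], [yp - 0.06 * height, yp + 0.06 * height], "-",
                color=color, linewidth=0.8)
        ax.text(x, yp + 0.08 * height, label, ha="center", va="bottom",
                fontsize=fs * 0.75, color=color)
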