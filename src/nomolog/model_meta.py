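"""Model metadata: types and template I/O for coefficient-only nomogram input.

A nomogram is built here from a six-column table (``feature, coef, min,
max, type, position``) rather than from training data.  The first two data
rows are reserved: row 1 carries the logistic-regression intercept, row 2
the optional decision threshold on the predicted probability.  Every
remaining row describes one predictor: its coefficient (log-odds per
unit), its clinically plausible value range, its data type (continuous,
discrete, nominal, ordinal) and on which side of the axis tick labels are
drawn.

One-hot encoded levels of a nominal variable are declared by naming the
rows ``parent::level``; such rows must span ``[0, 1]`` and are merged onto
a single nomogram axis at layout time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

__all__ = [
    "PredictorSpec",
    "ModelSpec",
    "ValidationReport",
    "ModelTemplateError",
    "TEMPLATE_COLUMNS",
    "DTYPE_VOCAB",
    "POSITION_VOCAB",
    "NOMINAL_DELIMITER",
    "read_model_template",
    "write_model_template",
    "validate_model",
]

TEMPLATE_COLUMNS = ("feature", "coef", "min", "max", "type", "position")
#: accepted spellings for the coefficient column header
_COEF_ALIASES = {"coef", "family coef"}
DTYPE_VOCAB = ("continuous", "discrete", "nominal", "ordinal")
POSITION_VOCAB = ("up", "down")
NOMINAL_DELIMITER = "::"

_INTERCEPT_ROW = 1
_THRESHOLD_ROW = 2


class ModelTemplateError(ValueError):
    """Raised when a metadata table cannot be turned into a valid model.

    Carries the full :class:`ValidationReport` in :attr:`report` so callers
    can surface every problem at once instead of the first one hit.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"row {r}, column {c}: {m}" for r, c, m in report.errors]
        super().__init__(
            "invalid model template (%d error%s):\n  %s"
            % (len(report.errors), "s" if len(report.errors) != 1 else "",
               "\n  ".join(lines))
        )


@dataclass(frozen=True)
class PredictorSpec:
    """A single predictor of the logistic model.

    Attributes
    ----------
    name : str
        Label as it appears in the template.  Names containing ``::`` are
        interpreted as one-hot levels ``parent::level``.
    coef : float
        Coefficient beta_i (log-odds change per unit of the predictor).
    min, max : float
        Smallest / largest value the predictor can take on the nomogram.
    dtype : str
        One of ``continuous``, ``discrete``, ``nominal``, ``ordinal``.
    position : str
        ``up`` or ``down``: side of the axis on which tick labels sit.
    """

    name: str
    coef: float
    min: float
    max: float
    dtype: str
    position: str

    @property
    def range(self) -> float:
        """Width ``max - min`` of the admissible value interval."""
        return self.max - self.min

    @property
    def nominal_parent(self) -> Optional[str]:
        """Parent variable name for one-hot levels, else ``None``."""
        if NOMINAL_DELIMITER in self.name:
            return self.name.split(NOMINAL_DELIMITER, 1)[0]
        return None

    @property
    def level_label(self) -> str:
        """Level name for one-hot rows; the full name otherwise."""
        if NOMINAL_DELIMITER in self.name:
            return self.name.split(NOMINAL_DELIMITER, 1)[1]
        return self.name


@dataclass(frozen=True)
class ModelSpec:
    """A logistic regression model described by coefficients and ranges.

    The predicted probability is ``sigmoid(intercept + sum_i coef_i * x_i)``
    and, when ``threshold`` is present, a case is called high risk when the
    probability strictly exceeds it.
    Predictor order is the file order and is preserved everywhere
    downstream (initializer tie-breaking, axis layout).
    """

    intercept: float
    threshold: Optional[float]
    predictors: tuple[PredictorSpec, ...]

    @property
    def d(self) -> int:
        """Number of predictor rows (one-hot levels count individually)."""
        return len(self.predictors)

    @property
    def nominal_groups(self) -> dict[str, tuple[int, ...]]:
        """Mapping parent name -> indices of its one-hot level rows.

        Insertion order follows first appearance in the file.
        """
        groups: dict[str, list[int]] = {}
        for i, p in enumerate(self.predictors):
            parent = p.nominal_parent
            if parent is not None:
                groups.setdefault(parent, []).append(i)
        return {k: tuple(v) for k, v in groups.items()}


@dataclass
class ValidationReport:
    """Outcome of validating a raw template table.

    ``errors`` and ``warnings`` are lists of ``(row, column, message)``
    where ``row`` is the 1-based data-row number (intercept row is 1,
    threshold row 2, first predictor row 3) and ``column`` a template
    column name, or ``"*"`` for table-level problems.
    """

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_number(cell) -> Optional[float]:
    """Best-effort float from a cell; None when not numeric."""
    if cell is None:
        return None
    if isinstance(cell, (int, float)):
        if isinstance(cell, float) and math.isnan(cell):
            return None
        return float(cell)
    s = str(cell).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _is_blank(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return str(cell).strip() == ""


def _normalise_frame(df: pd.DataFrame, report: ValidationReport) -> Optional[pd.DataFrame]:
    """Check/normalise headers; return frame with canonical column names."""
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        rename[col] = "coef" if key in _COEF_ALIASES else key
    df = df.rename(columns=rename)
    missing = [c for c in TEMPLATE_COLUMNS if c not in df.columns]
    for c in missing:
        report.errors.append((0, c, f"missing required column '{c}'"))
    if missing:
        return None
    return df[list(TEMPLATE_COLUMNS)]


def validate_model(raw: Union[pd.DataFrame, Sequence[Sequence]],
                   ) -> tuple[Optional[ModelSpec], ValidationReport]:
    """Validate a raw template table and build the model when clean.

    Total over its input: any table yields a report rather than an
    exception, and every rejection names a row/column locus.

    Parameters
    ----------
    raw : pandas.DataFrame or sequence of rows
        The table including the six template columns.  A plain sequence of
        rows is interpreted against the canonical column order.

    Returns
    -------
    (model, report)
        ``model`` is ``None`` unless ``report.ok``.  Degenerate predictors
        with ``coef == 0`` and ``max == min`` are dropped with a warning;
        ``coef == 0`` with a proper range is kept with a warning.
    """
    report = ValidationReport()
    if not isinstance(raw, pd.DataFrame):
        raw = pd.DataFrame(list(raw), columns=list(TEMPLATE_COLUMNS))
    df = _normalise_frame(raw, report)
    if df is None:
        return None, report
    if len(df) < 3:
        report.errors.append(
            (0, "*", "template needs at least 3 data rows "
                     "(intercept, threshold, one predictor)"))
        return None, report

    intercept = _parse_number(df.iloc[0]["coef"])
    if intercept is None:
        report.errors.append((_INTERCEPT_ROW, "coef",
                              "intercept row must carry a numeric coef"))

    thr_cell = df.iloc[1]["coef"]
    threshold: Optional[float] = None
    if not _is_blank(thr_cell):
        threshold = _parse_number(thr_cell)
        if threshold is None:
            report.errors.append((_THRESHOLD_ROW, "coef",
                                  "threshold must be numeric or blank"))
        elif not (0.0 < threshold < 1.0):
            report.errors.append((_THRESHOLD_ROW, "coef",
                                  "threshold must lie strictly in (0, 1)"))
            threshold = None

    predictors: list[PredictorSpec] = []
    seen: dict[str, int] = {}
    for j in range(2, len(df)):
        row = df.iloc[j]
        rownum = j + 1
        name = "" if _is_blank(row["feature"]) else str(row["feature"]).strip()
        row_ok = True
        if not name:
            report.errors.append((rownum, "feature", "predictor name is blank"))
            row_ok = False
        elif name in seen:
            report.errors.append((rownum, "feature",
                                  f"duplicate predictor name '{name}' "
                                  f"(first seen at row {seen[name]})"))
            row_ok = False
        else:
            seen[name] = rownum

        nums = {}
        for col in ("coef", "min", "max"):
            v = _parse_number(row[col])
            if v is None:
                report.errors.append((rownum, col,
                                      f"'{col}' must be numeric on predictor rows"))
                row_ok = False
            nums[col] = v

        dtype = "" if _is_blank(row["type"]) else str(row["type"]).strip().lower()
        if dtype not in DTYPE_VOCAB:
            report.errors.append((rownum, "type",
                                  f"unknown data type '{dtype}'; expected one of "
                                  + ", ".join(DTYPE_VOCAB)))
            row_ok = False
        position = "" if _is_blank(row["position"]) else str(row["position"]).strip().lower()
        if position not in POSITION_VOCAB:
            report.errors.append((rownum, "position",
                                  f"unknown position '{position}'; expected 'up' or 'down'"))
            row_ok = False

        if not row_ok:
            continue

        coef, vmin, vmax = nums["coef"], nums["min"], nums["max"]
        if vmax < vmin:
            report.errors.append((rownum, "max", "max is smaller than min"))
            continue
        if vmax == vmin:
            if coef == 0.0:
                report.warnings.append(
                    (rownum, "feature",
                     f"predictor '{name}' has zero coefficient and zero range; dropped"))
                continue
            # the value->points map divides by the range, so this cannot
            # be laid out as an axis
            report.errors.append((rownum, "max",
                                  "max equals min on a predictor with nonzero "
                                  "coefficient; the axis would be degenerate"))
            continue
        if coef == 0.0:
            report.warnings.append(
                (rownum, "coef",
                 f"predictor '{name}' has zero coefficient; its axis carries no points"))
        if NOMINAL_DELIMITER in name:
            if not (vmin == 0.0 and vmax == 1.0):
                report.errors.append(
                    (rownum, "min",
                     f"one-hot level '{name}' must span [0, 1], got "
                     f"[{vmin}, {vmax}]"))
                continue
            if dtype != "nominal":
                report.warnings.append(
                    (rownum, "type",
                     f"one-hot level '{name}' declared as '{dtype}'; "
                     "treated as nominal"))
        predictors.append(PredictorSpec(name=name, coef=coef, min=vmin,
                                        max=vmax, dtype=dtype, position=position))

    if not predictors and report.ok:
        report.errors.append((0, "*", "template defines no usable predictor"))

    if not report.ok:
        return None, report
    return ModelSpec(intercept=float(intercept), threshold=threshold,
                     predictors=tuple(predictors)), report


def _read_frame(source: Union[str, Path]) -> pd.DataFrame:
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"model template not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=0, dtype=object)
    # delimited text dialect: comma-separated, header row, UTF-8
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_model_template(source: Union[str, Path]) -> ModelSpec:
    """Read a model template (CSV or XLSX first sheet) into a ModelSpec.

    Raises :class:`ModelTemplateError` listing every validation problem
    when the table is not a valid model description.
    """
    model, report = validate_model(_read_frame(source))
    if model is None:
        raise ModelTemplateError(report)
    return model


def _fmt_cell(v: Optional[float]) -> str:
    """Shortest round-tripping decimal form of a float; '' for None."""
    if v is None:
        return ""
    return str(float(v))


def write_model_template(model: ModelSpec, dest: Union[str, Path]) -> None:
    """Write a ModelSpec to a template file (format chosen by suffix).

    CSV output is deterministic: re-writing the model read back from the
    file produces byte-identical text.
    """
    path = Path(dest)
    rows = [
        ("intercept", model.intercept, None, None, "", ""),
        ("threshold", model.threshold, None, None, "", ""),
    ]
    for p in model.predictors:
        rows.append((p.name, p.coef, p.min, p.max, p.dtype, p.position))

    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.DataFrame(rows, columns=list(TEMPLATE_COLUMNS))
        df.to_excel(path, index=False, sheet_name="model")
        return

    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TEMPLATE_COLUMNS)
        for name, coef, vmin, vmax, dtype, position in rows:
            writer.writerow([name, _fmt_cell(coef), _fmt_cell(vmin),
                             _fmt_cell(vmax), dtype, position])
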