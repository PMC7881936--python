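"""Refit pipeline: from an empirical rotation table to the adimensional model.

The derivation proceeds in the order the tables were originally modelled:

1. *Column fits.*  Each width column D holds (d, AVR) pairs; a four-
   coefficient rational curve AVR = (a + b·d)/(1 + c·d + d₂·d²) is fitted
   by nonlinear least squares, initialized from a linearized solve.
2. *Inversion.*  Each fitted column curve is inverted at the rotation grid
   2°, 4°, ..., 60°, giving smoothed d values to five decimal places.
3. *Ratio table.*  Every cell becomes the dimensionless D/d, five decimals.
   In an ideal table all cells of a row are equal.
4. *Row representatives.*  An ordinary least-squares line ratio = α + β·D is
   fitted per row (optionally omitting irregular wide columns, by default
   D = 60 and 70 mm) and read off at the central width D = 45 mm.
5. *Final fit.*  The 30 (ratio, AVR) representative pairs are fitted with
   the five-coefficient rational model, again LM least squares from a
   linearized start.

Every fit returns a :class:`FitStats` bundle (SSE, MSE, residual SD, df,
AICc with small-sample correction, pseudo-R² = 1 - SSE/SST).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import (
    FitFailureError,
    FitInitWarning,
    InsufficientDataError,
    InvalidInputError,
    NonMonotoneDataWarning,
    NoRootError,
    PipelineStageError,
    RowIrregularityWarning,
)
from .model import RationalModel5
from .tables import RaimondiTable, default_avr_grid, round_to_quantum

__all__ = [
    "RationalModel4",
    "FitStats",
    "RatioTable",
    "PipelineResult",
    "fit_column",
    "invert_column",
    "build_ratio_table",
    "row_representative",
    "fit_final",
    "run_pipeline",
    "fit_report",
    "CENTRAL_WIDTH_MM",
    "DEFAULT_OMIT_WIDTHS",
]

#: Central table column (mm) at which row regression lines are read off.
CENTRAL_WIDTH_MM = 45.0

#: Widths whose cells lose regularity in the source tables; omitted from the
#: row regressions by default.
DEFAULT_OMIT_WIDTHS = frozenset({60.0, 70.0})

_LSQ_OPTS = dict(method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)


@dataclass(frozen=True)
class RationalModel4:
    """Per-column model AVR(d) = (a + b·d)/(1 + c·d + d_coef·d²), d in mm.

    ``d_range`` records the span of the data the model was fitted on and
    seeds the inversion bracket.
    """

    a: float
    b: float
    c: float
    d_coef: float
    d_range: tuple[float, float] | None = None

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        return (self.a + self.b * d) / (1.0 + self.c * d + self.d_coef * d * d)

    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d_coef)


@dataclass(frozen=True)
class FitStats:
    """Least-squares goodness-of-fit bundle.

    mse = sse/df, residual_sd = sqrt(mse); aicc uses the small-sample
    correction n·ln(sse/n) + 2k + 2k(k+1)/(n-k-1) with k counting the model
    coefficients plus the residual-variance parameter; pseudo_r2 = 1-SSE/SST.
    """

    sse: float
    mse: float
    residual_sd: float
    df: int
    aicc: float
    pseudo_r2: float


def _fit_stats(residuals: np.ndarray, response: np.ndarray, n_coef: int) -> FitStats:
    n = residuals.size
    df = n - n_coef
    if df <= 0:
        raise InsufficientDataError(f"{n} points cannot support {n_coef} coefficients")
    sse = float(np.dot(residuals, residuals))
    sst = float(np.sum((response - response.mean()) ** 2))
    k = n_coef + 1  # coefficients + residual variance
    if n - k - 1 > 0:
        aicc = (
            (n * math.log(sse / n) if sse > 0 else -math.inf)
            + 2 * k
            + 2 * k * (k + 1) / (n - k - 1)
        )
    else:
        aicc = math.nan
    mse = sse / df
    return FitStats(
        sse=sse,
        mse=mse,
        residual_sd=math.sqrt(mse),
        df=df,
        aicc=aicc,
        pseudo_r2=1.0 - sse / sst if sst > 0 else math.nan,
    )


def _linearized_start(x: np.ndarray, y: np.ndarray, degree5: bool) -> np.ndarray:
    """Initial coefficients from the denominator-cleared linear system.

    Multiplying the rational model through by its denominator gives a system
    linear in the coefficients; its least-squares solution is an excellent
    LM starting point.  A singular/non-finite solve falls back to ones.
    """
    if degree5:
        design = np.column_stack([np.ones_like(x), x, x * x, -x * y, -x * x * y])
    else:
        design = np.column_stack([np.ones_like(x), x, -x * y, -x * x * y])
    try:
        start, *_ = np.linalg.lstsq(design, y, rcond=None)
    except np.linalg.LinAlgError:
        start = None
    if start is None or not np.all(np.isfinite(start)):
        warnings.warn(
            "linearized initialization singular; starting from unit coefficients",
            FitInitWarning,
            stacklevel=3,
        )
        start = np.ones(design.shape[1])
    return start


def _refine(residual_fn, start: np.ndarray) -> np.ndarray:
    result = least_squares(residual_fn, start, **_LSQ_OPTS)
    if not result.success:
        result = least_squares(residual_fn, start, method="trf",
                               xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if not result.success:
        raise FitFailureError(
            f"rational least squares did not converge: {result.message}",
            best_params=tuple(result.x),
        )
    return result.x


def fit_column(d_values, avr_values) -> tuple[RationalModel4, FitStats]:
    """Fit the four-coefficient rational curve to one width column.

    Needs at least five (d, AVR) points; d should increase with rotation
    (violations warn — they indicate noisy or disordered input, but the fit
    can still proceed).
    """
    d = np.asarray(d_values, dtype=float)
    y = np.asarray(avr_values, dtype=float)
    if d.size != y.size:
        raise InvalidInputError("d_values and avr_values must have equal length")
    if d.size < 5:
        raise InsufficientDataError(f"column fit needs >= 5 points, got {d.size}")
    order = np.argsort(y)
    if np.any(np.diff(d[order]) <= 0):
        warnings.warn(
            "column d values are not strictly increasing with rotation",
            NonMonotoneDataWarning,
            stacklevel=2,
        )
    start = _linearized_start(d, y, degree5=False)
    coef = _refine(lambda p: (p[0] + p[1] * d) / (1 + p[2] * d + p[3] * d * d) - y, start)
    model = RationalModel4(*coef, d_range=(float(d.min()), float(d.max())))
    stats = _fit_stats(model(d) - y, y, n_coef=4)
    return model, stats


def invert_column(
    model: RationalModel4,
    avr_grid=None,
    bracket: tuple[float, float] | None = None,
) -> np.ndarray:
    """Invert a fitted column curve at each grid rotation.

    Results are rounded to exactly five decimal places, the precision at
    which table cells are tabulated.  The bracket defaults to the fitted
    data span widened by 60% each way.
    """
    avr_grid = default_avr_grid() if avr_grid is None else np.asarray(avr_grid, dtype=float)
    if bracket is None:
        if model.d_range is None:
            raise InvalidInputError("model has no d_range; pass an explicit bracket")
        lo, hi = model.d_range
        bracket = (0.4 * lo, 1.6 * hi)
    lo, hi = bracket
    out = np.empty(avr_grid.size)
    for i, target in enumerate(avr_grid):
        f_lo = float(model(lo)) - target
        f_hi = float(model(hi)) - target
        if f_lo * f_hi > 0:
            raise NoRootError(
                f"no d in bracket [{lo:g}, {hi:g}] gives AVR = {target:g} deg"
            )
        out[i] = brentq(lambda z: float(model(z)) - target, lo, hi, xtol=1e-13)
    return np.round(out, 5)


@dataclass
class RatioTable:
    """Dimensionless table: rows = AVR, columns = D, cells = D/d (5 decimals)."""

    data: "object"  # pandas DataFrame, same layout as RaimondiTable.data

    @property
    def avr_grid(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def D_grid(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    def row(self, avr: float) -> np.ndarray:
        return self.data.loc[avr].to_numpy(dtype=float)


def build_ratio_table(
    columns: Mapping[float, RationalModel4],
    avr_grid=None,
) -> RatioTable:
    """Assemble the D/d table from fitted column models.

    cell(AVR, D) = D / d̂(AVR) with d̂ the five-decimal inverted value; the
    quotient is itself entered to five decimals.  Rows whose cells spread by
    more than 10% of the row mean trigger :class:`RowIrregularityWarning`.
    """
    import pandas as pd

    avr_grid = default_avr_grid() if avr_grid is None else np.asarray(avr_grid, dtype=float)
    if not columns:
        raise InsufficientDataError("no fitted columns supplied")
    widths = sorted(float(D) for D in columns)
    cells = np.empty((avr_grid.size, len(widths)))
    for j, D in enumerate(widths):
        d_hat = invert_column(columns[D], avr_grid)
        if np.any(d_hat <= 0):
            raise InvalidInputError(f"column D = {D:g} inverted to nonpositive d")
        cells[:, j] = np.round(D / d_hat, 5)
    for i, avr in enumerate(avr_grid):
        row = cells[i]
        if row.max() - row.min() > 0.1 * row.mean():
            warnings.warn(
                f"row AVR = {avr:g} deg cells spread beyond 10% of the row mean",
                RowIrregularityWarning,
                stacklevel=2,
            )
    return RatioTable(data=pd.DataFrame(cells, index=avr_grid, columns=widths))


def row_representative(
    row_ratios,
    D_values,
    omit: Iterable[float] = (),
    at_width: float = CENTRAL_WIDTH_MM,
) -> float:
    """Representative D/d of one rotation row, by OLS line read at D = 45 mm.

    ``omit`` lists column widths (mm) excluded from the regression; at least
    three points must remain.
    """
    ratios = np.asarray(row_ratios, dtype=float)
    widths = np.asarray(D_values, dtype=float)
    if ratios.size != widths.size:
        raise InvalidInputError("row_ratios and D_values must have equal length")
    keep = ~np.isin(widths, np.asarray(list(omit), dtype=float))
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"row regression needs >= 3 non-omitted points, got {int(keep.sum())}"
        )
    slope, intercept = np.polyfit(widths[keep], ratios[keep], 1)
    return float(intercept + slope * at_width)


def fit_final(ratios, avr_values) -> tuple[RationalModel5, FitStats]:
    """Fit the five-coefficient adimensional model to (D/d, AVR) pairs."""
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(avr_values, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("ratios and avr_values must have equal length")
    if x.size < 7:
        raise InsufficientDataError(f"final fit needs >= 7 points, got {x.size}")
    start = _linearized_start(x, y, degree5=True)
    coef = _refine(
        lambda p: (p[0] + p[1] * x + p[2] * x * x)
        / (1 + p[3] * x + p[4] * x * x) - y,
        start,
    )
    model = RationalModel5(*coef)
    stats = _fit_stats(np.asarray(model(x)) - y, y, n_coef=5)
    return model, stats


@dataclass
class PipelineResult:
    """Everything the refit pipeline produces."""

    model: RationalModel5
    stats: FitStats
    ratio_table: RatioTable
    column_models: dict = field(default_factory=dict)
    column_stats: dict = field(default_factory=dict)
    representatives: np.ndarray | None = None


def run_pipeline(
    table: RaimondiTable,
    omit_config: Mapping[float, Iterable[float]] | None = None,
) -> PipelineResult:
    """Run the whole table-to-model derivation on a rotation table.

    ``omit_config`` maps a row's AVR to the column widths excluded from that
    row's regression; by default every row omits D = 60 and 70 mm (where
    present).  Any stage failure is re-raised as
    :class:`PipelineStageError` naming the stage and index.
    """
    avr_grid = table.avr_grid
    widths = table.D_grid
    if widths.size < 3:
        raise InsufficientDataError(
            f"pipeline needs >= 3 width columns for the row regressions, got {widths.size}"
        )
    present = set(widths.tolist())
    default_omit = frozenset(w for w in DEFAULT_OMIT_WIDTHS if w in present)

    column_models: dict[float, RationalModel4] = {}
    column_stats: dict[float, FitStats] = {}
    for D in widths:
        try:
            column_models[float(D)], column_stats[float(D)] = fit_column(
                table.column(D), avr_grid
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError("fit_column", float(D), exc) from exc

    try:
        ratio_table = build_ratio_table(column_models, avr_grid)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("build_ratio_table", None, exc) from exc

    reps = np.empty(avr_grid.size)
    for i, avr in enumerate(avr_grid):
        omit = default_omit if omit_config is None else omit_config.get(float(avr), default_omit)
        try:
            reps[i] = row_representative(ratio_table.row(avr), ratio_table.D_grid, omit=omit)
        except Exception as exc:
            raise PipelineStageError("row_representative", float(avr), exc) from exc

    try:
        model, stats = fit_final(reps, avr_grid)
    except Exception as exc:
        raise PipelineStageError("fit_final", None, exc) from exc

    return PipelineResult(
        model=model,
        stats=stats,
        ratio_table=ratio_table,
        column_models=column_models,
        column_stats=column_stats,
        representatives=reps,
    )


def fit_report(model: RationalModel5, stats: FitStats, ratios, avr_values) -> dict:
    """JSON-serializable report: coefficients, statistics, per-point residuals."""
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(avr_values, dtype=float)
    resid = np.asarray(model(x)) - y
    return {
        "model": {"a": model.a, "b": model.b, "c": model.c,
                  "d": model.d_coef, "e": model.e},
        "stats": {
            "sse": stats.sse, "mse": stats.mse, "residual_sd": stats.residual_sd,
            "df": stats.df, "aicc": stats.aicc, "pseudo_r2": stats.pseudo_r2,
        },
        "residuals": [
            {"ratio": float(xi), "avr": float(yi), "residual": float(ri)}
            for xi, yi, ri in zip(x, y, resid)
        ],
    }
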