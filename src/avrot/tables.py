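"""Discrete Raimondi-style lookup tables: generation, lookup, CSV I/O.

The traditional tables map a (D, d) pair in millimetres to a rotation on a
2° grid: each column holds the pedicle distances d for one vertebral width D
(20-70 mm), each row one rotation (2°-60°).  Here such tables are generated
from a rational model by inverting it per rotation — every column of an
ideal table is proportional, cell(AVR, D) = D / ratio(AVR) — and a
nearest-cell lookup emulates how the printed tables are read by hand.

The millimetre restriction applies to the discrete tables only; the
scale-free measurement path (geometry -> model) never needs physical units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TableFormatError, TableRangeError
from .model import RationalModel5, invert_ratio, validity_interval

__all__ = [
    "RaimondiTable",
    "default_avr_grid",
    "default_D_grid",
    "generate_table",
    "lookup_avr",
    "round_to_quantum",
    "read_table_csv",
    "write_table_csv",
]

#: Physical width range (mm) over which the tables are defined.
D_MIN, D_MAX = 20.0, 70.0


def default_avr_grid() -> np.ndarray:
    """Rotations 2°-60° in 2° steps (30 rows)."""
    return np.arange(2.0, 61.0, 2.0)


def default_D_grid() -> np.ndarray:
    """Vertebral widths 20-70 mm in 1 mm steps (51 columns)."""
    return np.arange(20.0, 71.0, 1.0)


def round_to_quantum(values, quantum: float):
    """Round to a grid of step ``quantum``; quantum 0 means no rounding.

    Power-of-ten quanta round by decimal place so cells carry no floating
    dust (0.1 mm -> one decimal, 1e-5 -> five decimals).
    """
    values = np.asarray(values, dtype=float)
    if quantum < 0:
        raise InvalidInputError(f"quantum must be >= 0, got {quantum}")
    if quantum == 0:
        return values
    decimals = -math.log10(quantum)
    if abs(decimals - round(decimals)) < 1e-9:
        return np.round(values, int(round(decimals)))
    return np.round(values / quantum) * quantum


@dataclass
class RaimondiTable:
    """A rotation table: rows = AVR (degrees), columns = D (mm), cells = d (mm).

    ``data`` is a DataFrame indexed by the AVR grid with float D columns.
    Ideal cells increase down each column (d grows with rotation) and along
    each row (d grows with width); :meth:`validate` asserts both.
    """

    data: pd.DataFrame
    quantum: float = 0.1

    @property
    def avr_grid(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def D_grid(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    def cell(self, avr: float, D: float) -> float:
        return float(self.data.loc[avr, D])

    def column(self, D: float) -> np.ndarray:
        return self.data[D].to_numpy(dtype=float)

    def validate(self) -> None:
        """Check cell monotonicity along both axes; raise on violation."""
        arr = self.data.to_numpy(dtype=float)
        if np.any(np.diff(arr, axis=0) <= 0):
            raise InvalidInputError("table cells must increase with rotation within a column")
        if arr.shape[1] > 1 and np.any(np.diff(arr, axis=1) <= 0):
            raise InvalidInputError("table cells must increase with width within a row")


def generate_table(
    model: RationalModel5,
    D_grid=None,
    quantum: float = 0.1,
    avr_grid=None,
) -> RaimondiTable:
    """Build a discrete table from a rational model.

    cell(AVR, D) = round(D / ratio(AVR), quantum) where ratio(AVR) inverts
    the model.  The default 0.1 mm quantum matches the printed tables; use
    ``quantum=1e-5`` for analytic five-decimal tables or 0 for exact cells.
    """
    D_grid = default_D_grid() if D_grid is None else np.asarray(D_grid, dtype=float)
    avr_grid = default_avr_grid() if avr_grid is None else np.asarray(avr_grid, dtype=float)
    ratios = np.array([invert_ratio(model, t) for t in avr_grid])
    cells = round_to_quantum(np.outer(1.0 / ratios, D_grid), quantum)
    table = RaimondiTable(
        data=pd.DataFrame(cells, index=avr_grid, columns=D_grid),
        quantum=quantum,
    )
    table.validate()
    return table


def lookup_avr(table: RaimondiTable, D: float, d: float) -> float:
    """Manual-style discrete lookup: nearest column in D, nearest cell in d.

    Ties break toward the lower width and the lower rotation.  D must lie in
    the 20-70 mm band the tables cover and d within the selected column's
    span; both in millimetres.
    """
    D, d = float(D), float(d)
    if not (D_MIN <= D <= D_MAX):
        raise TableRangeError(f"D = {D:g} mm outside table range [{D_MIN:g}, {D_MAX:g}] mm")
    cols = table.D_grid
    # nearest column; exact halves go to the lower width
    gaps = np.abs(cols - D)
    best = gaps.min()
    candidates = cols[np.isclose(gaps, best, rtol=0.0, atol=1e-12)]
    col = float(candidates.min())
    cells = table.column(col)
    lo, hi = cells.min(), cells.max()
    if not (lo <= d <= hi):
        raise TableRangeError(
            f"d = {d:g} mm outside column D = {col:g} span [{lo:g}, {hi:g}] mm"
        )
    gaps = np.abs(cells - d)
    best = gaps.min()
    rows = table.avr_grid[np.isclose(gaps, best, rtol=0.0, atol=1e-12)]
    return float(rows.min())


# ---------------------------------------------------------------------------
# CSV dialect: first column "AVR", remaining headers the D values.


def write_table_csv(table: RaimondiTable, path) -> None:
    frame = table.data.copy()
    frame.columns = [
        str(int(c)) if float(c).is_integer() else str(c) for c in frame.columns
    ]
    frame.index = [
        int(i) if float(i).is_integer() else i for i in frame.index
    ]
    frame.index.name = "AVR"
    frame.to_csv(Path(path))


def read_table_csv(path, quantum: float = 0.1) -> RaimondiTable:
    """Read a table CSV, validating the row grid and column range.

    Rows must be a subset of the 2°-60° step-2 grid in ascending order;
    column widths must be ascending and lie within 20-70 mm.  (Printed
    fragments with missing rows/columns are legal.)
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"cannot parse table CSV {path}: {exc}") from exc
    if frame.columns[0] != "AVR":
        raise TableFormatError(f"table CSV {path} must have first column 'AVR'")
    try:
        avr = frame["AVR"].to_numpy(dtype=float)
        cols = np.array([float(c) for c in frame.columns[1:]])
        cells = frame.iloc[:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"non-numeric content in table CSV {path}: {exc}") from exc
    grid = default_avr_grid()
    if not np.all(np.isin(avr, grid)) or np.any(np.diff(avr) <= 0):
        raise TableFormatError(
            f"table CSV {path}: AVR rows must be ascending values of the 2-60 step-2 grid"
        )
    if np.any(cols < D_MIN) or np.any(cols > D_MAX) or np.any(np.diff(cols) <= 0):
        raise TableFormatError(
            f"table CSV {path}: D columns must be ascending and within [{D_MIN:g}, {D_MAX:g}]"
        )
    data = pd.DataFrame(cells, index=avr, columns=cols)
    return RaimondiTable(data=data, quantum=quantum)
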