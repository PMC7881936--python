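"""The adimensional rational model of axial vertebral rotation.

The core object is a degree-(2,2) rational function

    AVR(x) = (a + b*x + c*x**2) / (1 + d*x + e*x**2),     x = D/d,

mapping the dimensionless ratio of vertebral-body width ``D`` to pedicle
offset ``d`` onto an axial vertebral rotation (AVR) in degrees.  Because only
the ratio enters, the measurement is independent of image scale: pixel
coordinates are as good as millimetres.

The published coefficient set (obtained by least squares over the
representative D/d value of each rotation of the Raimondi tables, 2°-60° in
2° steps) is bundled both as Python constants (:func:`published_model`) and
as ``data/published_model.json``.  On its validity interval - the ratio range
spanned by rotations between 2° and 60° - the function is strictly
decreasing, so it can be inverted by bracketed root finding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DomainError,
    InvalidInputError,
    NonMonotoneError,
    NoRootError,
    SingularModelError,
)

__all__ = [
    "RationalModel5",
    "ValidityInterval",
    "AVRResult",
    "published_model",
    "evaluate_avr",
    "invert_ratio",
    "validity_interval",
    "save_model",
    "load_model",
    "AVR_MIN",
    "AVR_MAX",
]

#: AVR range covered by the Raimondi tables, degrees.
AVR_MIN = 2.0
AVR_MAX = 60.0

#: Default ratio bracket over which the model is searched for roots.
SEARCH_BRACKET = (0.5, 20.0)

#: A denominator magnitude below this is treated as a pole.
_DENOM_TOL = 1e-12

# Published coefficients, kept bit-exact as printed.
_PUBLISHED = (20.22483, -330.5077, 33.46082, -3.93825, -1.322272)


@dataclass(frozen=True)
class RationalModel5:
    """Five-coefficient rational model AVR(x) = (a+bx+cx²)/(1+dx+ex²).

    ``d_coef`` is the linear denominator coefficient (named to avoid clashing
    with the pedicle distance ``d``).  All coefficients are dimensionless
    except for the overall scale of the output, which is degrees.
    """

    a: float
    b: float
    c: float
    d_coef: float
    e: float

    def numerator(self, x):
        x = np.asarray(x, dtype=float)
        return self.a + self.b * x + self.c * x * x

    def denominator(self, x):
        x = np.asarray(x, dtype=float)
        return 1.0 + self.d_coef * x + self.e * x * x

    def __call__(self, x):
        """Raw evaluation in degrees; raises near a pole of the denominator."""
        den = self.denominator(x)
        if np.any(np.abs(den) < _DENOM_TOL):
            raise SingularModelError(
                "denominator within 1e-12 of zero at ratio "
                f"{np.asarray(x, dtype=float)[np.abs(den) < _DENOM_TOL] if np.ndim(x) else x}"
            )
        return self.numerator(x) / den

    def coefficients(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d_coef, self.e)


@dataclass(frozen=True)
class ValidityInterval:
    """Ratio interval spanned by rotations from 2° (ratio_hi) to 60° (ratio_lo)."""

    ratio_lo: float
    ratio_hi: float

    def __post_init__(self):
        if not (0.0 < self.ratio_lo < self.ratio_hi):
            raise InvalidInputError(
                f"invalid validity interval [{self.ratio_lo}, {self.ratio_hi}]"
            )

    def __contains__(self, ratio: float) -> bool:
        return self.ratio_lo <= ratio <= self.ratio_hi


@dataclass(frozen=True)
class AVRResult:
    """One AVR evaluation: angle, the ratio it came from, and domain flags."""

    avr_degrees: float
    ratio: float
    in_domain: bool
    clamped: bool = False


def published_model() -> RationalModel5:
    """Return the published coefficient set, exactly as printed."""
    return RationalModel5(*_PUBLISHED)


@lru_cache(maxsize=64)
def _cached_interval(model: RationalModel5) -> ValidityInterval:
    lo = invert_ratio(model, AVR_MAX)
    hi = invert_ratio(model, AVR_MIN)
    return ValidityInterval(ratio_lo=lo, ratio_hi=hi)


def validity_interval(model: RationalModel5) -> ValidityInterval:
    """Ratio interval on which the model maps onto [2°, 60°].

    Computed by numerically inverting the model at the two rotation
    extremes; cached per coefficient set.
    """
    return _cached_interval(model)


def evaluate_avr(
    model: RationalModel5,
    ratio: float,
    out_of_domain: str = "raw",
) -> AVRResult:
    """Evaluate the model at a D/d ratio.

    Parameters
    ----------
    ratio : float
        Positive dimensionless D/d value.
    out_of_domain : {"raw", "clamp", "strict"}
        Policy for ratios outside the validity interval.  ``raw`` (default)
        returns the raw rational-function value flagged ``in_domain=False``;
        ``clamp`` evaluates at the nearest interval endpoint and flags
        ``clamped=True``; ``strict`` raises :class:`DomainError`.  The model
        is a fit over 2°-60° only, so extrapolated values are unvalidated.
    """
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio <= 0.0:
        raise InvalidInputError(f"ratio must be a positive finite number, got {ratio}")
    if out_of_domain not in ("raw", "clamp", "strict"):
        raise InvalidInputError(f"unknown out_of_domain policy {out_of_domain!r}")

    try:
        interval = validity_interval(model)
    except (NoRootError, NonMonotoneError):
        # degenerate or non-monotone model: no validity interval exists
        interval = None
    in_domain = interval is not None and ratio in interval
    clamped = False
    x = ratio
    if not in_domain:
        if out_of_domain == "strict":
            bounds = (
                f"[{interval.ratio_lo:g}, {interval.ratio_hi:g}]"
                if interval is not None
                else "(undefined: model has no 2-60 degree range)"
            )
            raise DomainError(f"ratio {ratio:g} outside validity interval {bounds}")
        if out_of_domain == "clamp" and interval is not None:
            x = min(max(ratio, interval.ratio_lo), interval.ratio_hi)
            clamped = True
    value = float(model(x))
    return AVRResult(avr_degrees=value, ratio=ratio, in_domain=in_domain, clamped=clamped)


def _check_monotone_decreasing(model: RationalModel5, lo: float, hi: float, n: int = 257):
    grid = np.linspace(lo, hi, n)
    vals = model(grid)
    if not np.all(np.diff(vals) < 0.0):
        raise NonMonotoneError(
            f"model is not strictly decreasing over [{lo:g}, {hi:g}]; inversion is ambiguous"
        )


def invert_ratio(
    model: RationalModel5,
    avr: float,
    bracket: tuple[float, float] = SEARCH_BRACKET,
    allow_extrapolation: bool = False,
) -> float:
    """Find the ratio at which the model equals ``avr`` degrees.

    Uses Brent's method on ``bracket``; the model must be strictly monotone
    (decreasing) there, which is verified on a coarse grid.  The root
    satisfies |AVR(root) - avr| below ~1e-9.
    """
    avr = float(avr)
    if not allow_extrapolation and not (AVR_MIN <= avr <= AVR_MAX):
        raise InvalidInputError(
            f"avr {avr:g} outside [{AVR_MIN:g}, {AVR_MAX:g}] "
            "(pass allow_extrapolation=True to relax)"
        )
    lo, hi = float(bracket[0]), float(bracket[1])
    _check_monotone_decreasing(model, lo, hi)
    f_lo = float(model(lo)) - avr
    f_hi = float(model(hi)) - avr
    if f_lo * f_hi > 0.0:
        raise NoRootError(
            f"AVR {avr:g} not attained over bracket [{lo:g}, {hi:g}] "
            f"(model spans [{f_hi + avr:g}, {f_lo + avr:g}])"
        )
    root = brentq(lambda r: float(model(r)) - avr, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(root)


# ---------------------------------------------------------------------------
# JSON serialization


def save_model(model: RationalModel5, path) -> None:
    """Write coefficients plus the computed validity interval as JSON."""
    interval = validity_interval(model)
    payload = {
        "a": model.a,
        "b": model.b,
        "c": model.c,
        "d": model.d_coef,
        "e": model.e,
        "ratio_lo": interval.ratio_lo,
        "ratio_hi": interval.ratio_hi,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path=None) -> RationalModel5:
    """Read a model JSON file; with no path, load the bundled published model.

    If the file records a validity interval the denominator is verified to be
    bounded away from zero across it.
    """
    if path is None:
        text = resources.files("avrot.data").joinpath("published_model.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        payload = json.loads(text)
        model = RationalModel5(
            a=float(payload["a"]),
            b=float(payload["b"]),
            c=float(payload["c"]),
            d_coef=float(payload["d"]),
            e=float(payload["e"]),
        )
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"malformed model JSON: {exc}") from exc
    if "ratio_lo" in payload and "ratio_hi" in payload:
        lo, hi = float(payload["ratio_lo"]), float(payload["ratio_hi"])
        grid = np.linspace(lo, hi, 1001)
        den = model.denominator(grid)
        if np.any(np.abs(den) < _DENOM_TOL) or np.any(den[:-1] * den[1:] < 0.0):
            raise SingularModelError(
                f"denominator vanishes inside stored validity interval [{lo:g}, {hi:g}]"
            )
    return model
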