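"""Landmark geometry: from four digitized points to D, d and an AVR.

On an anteroposterior radiograph the operator marks, per vertebra, the two
closest points of the lateral faces of the vertebral body and the two
opposite edges of the shadow of the pedicle that has migrated toward the
vertebral midline.  From these the vertebral-body width ``D`` and the
pedicle-centre offset ``d`` are derived, and their ratio feeds the rational
model.  All coordinates are in arbitrary consistent units (pixels are fine):
only D/d is ever used, so no image scale is required.

``d`` is measured along the body-width axis: the pedicle centre (midpoint of
the two marked shadow edges) is orthogonally projected onto the line through
the body-edge points, and the distance from that projection to the edge named
by ``reference_side`` is taken.  This makes the measurement exactly invariant
under rigid motions of the image, and robust to vertebral tilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import (
    DegenerateLandmarkError,
    InvalidInputError,
    PedicleOutsideBodyWarning,
    TableFormatError,
)
from .model import AVRResult, RationalModel5, evaluate_avr, published_model

__all__ = [
    "VertebralLandmarks",
    "Measurement",
    "body_width",
    "pedicle_offset",
    "measure",
    "measure_avr",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

Side = Literal["left", "right"]

_LANDMARK_COLUMNS = [
    "id", "xL", "yL", "xR", "yR", "xP1", "yP1", "xP2", "yP2", "reference_side",
]


@dataclass(frozen=True)
class VertebralLandmarks:
    """Four digitized points defining one vertebra's rotation measurement.

    ``reference_side`` names the vertebral-body edge from which the pedicle
    offset d is measured; the operator chooses it (by convention the edge
    the pedicle shadow has migrated away from is informative, but the
    software never guesses).
    """

    body_edge_left: tuple[float, float]
    body_edge_right: tuple[float, float]
    pedicle_edge_1: tuple[float, float]
    pedicle_edge_2: tuple[float, float]
    reference_side: Side = "left"

    def __post_init__(self):
        for name in ("body_edge_left", "body_edge_right", "pedicle_edge_1", "pedicle_edge_2"):
            p = getattr(self, name)
            object.__setattr__(self, name, (float(p[0]), float(p[1])))
        if self.reference_side not in ("left", "right"):
            raise InvalidInputError(
                f"reference_side must be 'left' or 'right', got {self.reference_side!r}"
            )

    def points(self) -> np.ndarray:
        """All four points as a (4, 2) array, body edges first."""
        return np.array(
            [self.body_edge_left, self.body_edge_right,
             self.pedicle_edge_1, self.pedicle_edge_2], dtype=float
        )

    def transformed(self, scale: float = 1.0, rotation_deg: float = 0.0,
                    translation: tuple[float, float] = (0.0, 0.0)) -> "VertebralLandmarks":
        """Similarity-transformed copy (scale, rotate about origin, translate)."""
        theta = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = scale * self.points() @ R.T + np.asarray(translation, dtype=float)
        return VertebralLandmarks(
            tuple(pts[0]), tuple(pts[1]), tuple(pts[2]), tuple(pts[3]),
            self.reference_side,
        )


@dataclass(frozen=True)
class Measurement:
    """Scalar measurements for one vertebra: width D, offset d, ratio D/d."""

    D: float
    d: float
    ratio: float


def _body_axis(landmarks: VertebralLandmarks) -> tuple[np.ndarray, np.ndarray, float]:
    left = np.asarray(landmarks.body_edge_left, dtype=float)
    right = np.asarray(landmarks.body_edge_right, dtype=float)
    span = right - left
    width = float(np.linalg.norm(span))
    scale = max(1.0, np.max(np.abs(np.concatenate([left, right]))))
    if width < 1e-12 * scale:
        raise DegenerateLandmarkError("body-edge points are coincident; width undefined")
    return left, span / width, width


def body_width(landmarks: VertebralLandmarks) -> float:
    """Euclidean distance D between the two vertebral-body edge points."""
    _, _, width = _body_axis(landmarks)
    return width


def pedicle_offset(landmarks: VertebralLandmarks) -> float:
    """Distance d from the reference body edge to the projected pedicle centre.

    The pedicle centre is the midpoint of the two marked shadow edges,
    projected orthogonally onto the body-width axis.  A centre projecting
    outside the body segment by more than 10% of D triggers
    :class:`PedicleOutsideBodyWarning` (likely digitization error).
    """
    left, axis, width = _body_axis(landmarks)
    centre = 0.5 * (
        np.asarray(landmarks.pedicle_edge_1, dtype=float)
        + np.asarray(landmarks.pedicle_edge_2, dtype=float)
    )
    s = float(np.dot(centre - left, axis))  # position along the axis from the left edge
    if s < -0.1 * width or s > 1.1 * width:
        warnings.warn(
            f"pedicle centre projects at {s:.3g} along a body of width {width:.3g}",
            PedicleOutsideBodyWarning,
            stacklevel=2,
        )
    if landmarks.reference_side == "left":
        return abs(s)
    return abs(width - s)


def measure(landmarks: VertebralLandmarks) -> Measurement:
    """Compute (D, d, D/d) for one vertebra."""
    D = body_width(landmarks)
    d = pedicle_offset(landmarks)
    if d == 0.0:
        raise DegenerateLandmarkError("pedicle centre coincides with the reference edge (d = 0)")
    return Measurement(D=D, d=d, ratio=D / d)


def measure_avr(
    landmarks: VertebralLandmarks,
    model: RationalModel5 | None = None,
    out_of_domain: str = "raw",
) -> AVRResult:
    """Full landmark-to-rotation measurement via the rational model.

    Scale-free: any uniform scaling or rigid motion of the four points
    yields the same result.
    """
    if model is None:
        model = published_model()
    m = measure(landmarks)
    return evaluate_avr(model, m.ratio, out_of_domain=out_of_domain)


# ---------------------------------------------------------------------------
# CSV dialect: one vertebra per row, header mandatory, decimal point,
# comma separator: id,xL,yL,xR,yR,xP1,yP1,xP2,yP2,reference_side


def read_landmarks_csv(path) -> list[tuple[str, VertebralLandmarks]]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"cannot parse landmark CSV {path}: {exc}") from exc
    missing = [c for c in _LANDMARK_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"landmark CSV {path} lacks columns {missing}")
    out: list[tuple[str, VertebralLandmarks]] = []
    for _, row in frame.iterrows():
        lm = VertebralLandmarks(
            body_edge_left=(row["xL"], row["yL"]),
            body_edge_right=(row["xR"], row["yR"]),
            pedicle_edge_1=(row["xP1"], row["yP1"]),
            pedicle_edge_2=(row["xP2"], row["yP2"]),
            reference_side=str(row["reference_side"]).strip().lower(),
        )
        out.append((str(row["id"]), lm))
    return out


def write_landmarks_csv(records: list[tuple[str, VertebralLandmarks]], path) -> None:
    rows = []
    for vid, lm in records:
        rows.append({
            "id": vid,
            "xL": lm.body_edge_left[0], "yL": lm.body_edge_left[1],
            "xR": lm.body_edge_right[0], "yR": lm.body_edge_right[1],
            "xP1": lm.pedicle_edge_1[0], "yP1": lm.pedicle_edge_1[1],
            "xP2": lm.pedicle_edge_2[0], "yP2": lm.pedicle_edge_2[1],
            "reference_side": lm.reference_side,
        })
    pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(Path(path), index=False)
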