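"""Synthetic tables and landmark sets with known ground truth.

Everything the measurement and refit code consumes can be generated here by
running the model in reverse: a ground-truth rational model fixes the exact
ratio for each rotation, tables are built as d = D/ratio plus optional
Gaussian cell noise and rounding, and landmark sets place the four
measurement points so that a perfect observer would recover the requested
rotation exactly.  Gaussian coordinate noise and rigid tilt emulate
digitization error and patient positioning; all randomness is driven by an
explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import VertebralLandmarks
from .model import AVR_MAX, AVR_MIN, RationalModel5, invert_ratio, published_model
from .tables import RaimondiTable, default_D_grid, round_to_quantum

__all__ = ["SyntheticSpec", "synth_table", "synth_landmarks", "write_ground_truth"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study: model, grids, noise, seed.

    Defaults mirror the source tables: 51 width columns (20-70 mm), cells
    rounded to 0.1 mm, no noise.  ``noise_sd_d`` is the SD (mm) of Gaussian
    noise added to table cells before rounding; ``landmark_noise_sd`` is the
    per-coordinate SD (pixels) for landmark sets.
    """

    model: RationalModel5 = field(default_factory=published_model)
    D_grid: tuple = tuple(float(v) for v in default_D_grid())
    noise_sd_d: float = 0.0
    quantum: float = 0.1
    seed: int = 0
    landmark_noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd_d < 0 or self.landmark_noise_sd < 0 or self.quantum < 0:
            raise InvalidInputError("noise SDs and quantum must be >= 0")


def synth_table(spec: SyntheticSpec) -> tuple[RaimondiTable, RationalModel5]:
    """Generate a table from the spec's model; returns (table, ground truth).

    cell(AVR, D) = round(D/ratio(AVR) + N(0, noise_sd_d), quantum), with the
    noise drawn from a generator seeded by ``spec.seed`` (deterministic).
    """
    rng = np.random.default_rng(spec.seed)
    avr_grid = np.arange(2.0, 61.0, 2.0)
    D_grid = np.asarray(spec.D_grid, dtype=float)
    ratios = np.array([invert_ratio(spec.model, t) for t in avr_grid])
    cells = np.outer(1.0 / ratios, D_grid)
    if spec.noise_sd_d > 0:
        cells = cells + rng.normal(0.0, spec.noise_sd_d, size=cells.shape)
    cells = round_to_quantum(cells, spec.quantum)
    table = RaimondiTable(
        data=pd.DataFrame(cells, index=avr_grid, columns=D_grid),
        quantum=spec.quantum,
    )
    return table, spec.model


def synth_landmarks(
    avr_true: float,
    D_pixels: float = 450.0,
    model: RationalModel5 | None = None,
    tilt: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_side: str = "left",
) -> tuple[VertebralLandmarks, dict]:
    """Construct a landmark set whose noise-free measurement is ``avr_true``.

    Body edges are placed ``D_pixels`` apart; the pedicle centre sits at
    d = D/ratio(avr_true) from the reference edge along the body axis, with
    a fixed vertical offset and shadow half-width (both irrelevant to the
    projected measurement).  The whole constellation is rigidly rotated by
    ``tilt`` degrees about the body centre, then per-coordinate Gaussian
    noise of SD ``noise_sd`` pixels is added.  Returns the landmarks and a
    ground-truth record.
    """
    if not (AVR_MIN <= avr_true <= AVR_MAX):
        raise InvalidInputError(f"avr_true must lie in [{AVR_MIN:g}, {AVR_MAX:g}] degrees")
    if D_pixels <= 0:
        raise InvalidInputError("D_pixels must be positive")
    model = published_model() if model is None else model
    ratio = invert_ratio(model, avr_true)
    d = D_pixels / ratio

    # Layout in the vertebra frame: x along the body width, origin at the
    # left edge.  Shadow geometry (height, half-width) cancels on projection.
    height = 0.12 * D_pixels
    half_width = 0.04 * D_pixels
    if reference_side == "left":
        centre_x = d
    elif reference_side == "right":
        centre_x = D_pixels - d
    else:
        raise InvalidInputError(f"reference_side must be 'left' or 'right', got {reference_side!r}")
    pts = np.array([
        [0.0, 0.0],
        [D_pixels, 0.0],
        [centre_x - half_width, height],
        [centre_x + half_width, height],
    ])

    theta = np.deg2rad(tilt)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pivot = np.array([D_pixels / 2.0, 0.0])
    pts = (pts - pivot) @ rot.T + pivot

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)

    landmarks = VertebralLandmarks(
        body_edge_left=tuple(pts[0]),
        body_edge_right=tuple(pts[1]),
        pedicle_edge_1=tuple(pts[2]),
        pedicle_edge_2=tuple(pts[3]),
        reference_side=reference_side,
    )
    truth = {
        "avr_deg": float(avr_true),
        "ratio": float(ratio),
        "D": float(D_pixels),
        "d": float(d),
        "tilt_deg": float(tilt),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
        "reference_side": reference_side,
    }
    return landmarks, truth


def write_ground_truth(records: list[dict], path) -> None:
    """Write ground-truth records as a JSON sidecar."""
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
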