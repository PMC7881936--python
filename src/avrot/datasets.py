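"""Bundled reference data: the published representative (D/d, AVR) pairs."""

from __future__ import annotations

from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

__all__ = ["representative_pairs"]


def representative_pairs() -> tuple[np.ndarray, np.ndarray]:
    """The 30 published representative pairs, as (ratios, avr_degrees).

    One pair per rotation 2°-60° step 2; the ratio is the representative
    D/d of that rotation (central column D = 45 mm of the ratio table).
    """
    text = resources.files("avrot.data").joinpath("table4.csv").read_text()
    frame = pd.read_csv(StringIO(text))
    return frame["ratio"].to_numpy(dtype=float), frame["AVR"].to_numpy(dtype=float)
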