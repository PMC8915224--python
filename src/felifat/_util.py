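"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (CT HU values and reported decimals).

    numpy/python round() use banker's rounding; printed clinical values
    round 0.5 up in magnitude.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_half_away_array(x: np.ndarray, decimals: int = 0) -> np.ndarray:
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
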