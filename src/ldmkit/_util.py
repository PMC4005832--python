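"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_up(x):
    """Round to nearest integer with ties going up (0.5 -> 1).

    numpy's ``round`` uses banker's rounding; grid placement and template
    sizing need the deterministic half-up convention instead.
    """
    arr = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    if np.ndim(x) == 0:
        return int(arr)
    return arr
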