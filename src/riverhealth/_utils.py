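"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x, decimals: int = 1):
    """Round half away from zero (the convention used in the reported tables).

    numpy/python round half-to-even, which disagrees on values like 43.75;
    survey-style tables round .5 up.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)
    if out.ndim == 0:
        return float(out)
    return out


def check_rng(random_state) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)
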