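"""Small numeric helpers used by several stages."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to the nearest integer, ties going away from zero.

    Numpy's ``rint`` rounds half to even; reference tables and printed
    percentages use the conventional half-away rule instead.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)
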