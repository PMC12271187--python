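"""Shared low-level filters."""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, edge windows shifted to stay full length.

    The filter is always a true mean of ``window`` observed samples (never
    padded, never shortened), so additive decompositions never invent data
    and a one-period window cancels a periodic component at the edges too.
    Accepts (n,) or (n, k); always returns (n, k).
    """
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    n = x.shape[0]
    window = min(window, n)
    half = window // 2
    c = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    # centred where possible, shifted (not shortened) at the edges: a
    # full-length window keeps a one-period average exactly periodic-free
    lo = np.clip(np.arange(n) - half, 0, n - window)
    hi = lo + window
    return (c[hi] - c[lo]) / float(window)
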