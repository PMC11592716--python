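"""Gray-level discretization of a patch prior to texture analysis.

Fixed-bin-width binning anchored at the patch minimum is the default:
level(x) = floor((x - min) / bin_width) + 1, so a constant patch occupies a
single level and levels are always >= 1. A fixed-bin-count mode is offered
as an alternative.
"""

from __future__ import annotations

import numpy as np

__all__ = ["discretize"]


def discretize(
    values: np.ndarray,
    bin_width: float | None = 25.0,
    bin_count: int | None = None,
) -> np.ndarray:
    """Map intensities to integer gray levels starting at 1.

    Parameters
    ----------
    values : array-like
        Patch intensities (any shape, nonempty).
    bin_width : float, optional
        Width of one gray-level bin in intensity units (default 25).
        Ignored when ``bin_count`` is given.
    bin_count : int, optional
        Discretize into exactly this many equal-width bins spanning the
        patch range instead of using a fixed width.

    Returns
    -------
    ndarray of int64, same shape as ``values``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty patch")
    lo = x.min()
    if bin_count is not None:
        if bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        rng = x.max() - lo
        if rng == 0:
            return np.ones(x.shape, dtype=np.int64)
        levels = np.floor((x - lo) / (rng / bin_count)).astype(np.int64) + 1
        return np.clip(levels, 1, bin_count)
    if bin_width is None or bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return np.floor((x - lo) / bin_width).astype(np.int64) + 1
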