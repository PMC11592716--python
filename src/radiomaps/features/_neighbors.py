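"""Lattice neighborhoods for texture-matrix construction.

All texture families operate on the same neighborhood: unit Chebyshev
distance on the voxel lattice of a patch. Offsets along singleton axes are
dropped, so a single-slice patch automatically degenerates to the in-plane
2D neighborhood (4 unique offset directions, 8 neighbors).
"""

from __future__ import annotations

import itertools

import numpy as np

_ALL_26 = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


def unique_offsets(shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Offsets with Chebyshev distance 1, unique up to sign, that fit ``shape``.

    An offset "fits" when it can connect at least one voxel pair, i.e. no
    component moves along an axis of extent 1. 13 directions in full 3D,
    4 for a single-slice patch, 1 for a 1D patch.
    """
    offs = []
    for off in _ALL_26:
        if any(o != 0 and shape[d] < 2 for d, o in enumerate(off)):
            continue
        first_nonzero = next(o for o in off if o != 0)
        if first_nonzero > 0:
            offs.append(off)
    return offs


def full_offsets(shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """All 26-neighborhood offsets (both signs) that fit ``shape``."""
    return [
        off
        for off in _ALL_26
        if not any(o != 0 and shape[d] < 2 for d, o in enumerate(off))
    ]


def shifted_slices(off: tuple[int, int, int], shape: tuple[int, int, int]):
    """Slice pair (center, neighbor) so a[center] and a[neighbor] align.

    ``a[center][i]`` and ``a[neighbor][i]`` are voxel v and voxel v+off.
    """
    center, neighbor = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            center.append(slice(0, n - o))
            neighbor.append(slice(o, n))
        else:
            center.append(slice(-o, n))
            neighbor.append(slice(0, n + o))
    return tuple(center), tuple(neighbor)


def neighbor_count_map(shape: tuple[int, int, int]) -> np.ndarray:
    """Number of in-patch Chebyshev-1 neighbors of each voxel."""
    counts = np.zeros(shape, dtype=np.int64)
    ones = np.ones(shape, dtype=np.int64)
    for off in full_offsets(shape):
        c, n = shifted_slices(off, shape)
        counts[c] += ones[n]
    return counts
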