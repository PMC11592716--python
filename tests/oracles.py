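"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, BFS flood fill,
exhaustive enumeration) kept independent of the package's vectorized
code paths.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque

import numpy as np


def inbounds(idx, shape) -> bool:
    return all(0 <= idx[a] < shape[a] for a in range(3))


def oracle_glcm_counts(levels: np.ndarray, offset) -> Counter:
    """Symmetric co-occurrence counts via direct pair enumeration."""
    lv = np.atleast_3d(levels)
    counts: Counter = Counter()
    for idx in np.ndindex(lv.shape):
        nb = tuple(idx[a] + offset[a] for a in range(3))
        if inbounds(nb, lv.shape):
            a, b = int(lv[idx]), int(lv[nb])
            counts[(a, b)] += 1
            counts[(b, a)] += 1
    return counts


def oracle_runs(levels: np.ndarray, direction) -> Counter:
    """Multiset of (gray, run_length) via explicit line walking."""
    lv = np.atleast_3d(levels)
    shape = lv.shape
    runs: Counter = Counter()
    for start in np.ndindex(shape):
        prev = tuple(start[a] - direction[a] for a in range(3))
        if inbounds(prev, shape):
            continue
        line = []
        pos = start
        while inbounds(pos, shape):
            line.append(int(lv[pos]))
            pos = tuple(pos[a] + direction[a] for a in range(3))
        for g, grp in itertools.groupby(line):
            runs[(g, len(list(grp)))] += 1
    return runs


def oracle_zones(levels: np.ndarray) -> Counter:
    """Multiset of (gray, zone_size) via BFS flood fill, 26-connectivity."""
    lv = np.atleast_3d(levels)
    shape = lv.shape
    seen = np.zeros(shape, dtype=bool)
    zones: Counter = Counter()
    neigh = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for start in np.ndindex(shape):
        if seen[start]:
            continue
        g = int(lv[start])
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for off in neigh:
                nb = tuple(cur[a] + off[a] for a in range(3))
                if inbounds(nb, shape) and not seen[nb] and int(lv[nb]) == g:
                    seen[nb] = True
                    queue.append(nb)
        zones[(g, size)] += 1
    return zones


def oracle_dependence(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Per-voxel dependent-neighbor count via explicit neighbor loops."""
    lv = np.atleast_3d(levels)
    shape = lv.shape
    out = np.zeros(shape, dtype=int)
    neigh = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for idx in np.ndindex(shape):
        c = 0
        for off in neigh:
            nb = tuple(idx[a] + off[a] for a in range(3))
            if inbounds(nb, shape) and abs(int(lv[nb]) - int(lv[idx])) <= alpha:
                c += 1
        out[idx] = c
    return out


def oracle_ngtdm(levels: np.ndarray):
    """(n_i, s_i) per occupied gray level via per-voxel neighbor means."""
    lv = np.atleast_3d(levels)
    shape = lv.shape
    neigh = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    n: Counter = Counter()
    s: dict[int, float] = {}
    for idx in np.ndindex(shape):
        g = int(lv[idx])
        vals = [
            int(lv[tuple(idx[a] + off[a] for a in range(3))])
            for off in neigh
            if inbounds(tuple(idx[a] + off[a] for a in range(3)), shape)
        ]
        n[g] += 1
        if vals:
            s[g] = s.get(g, 0.0) + abs(g - sum(vals) / len(vals))
        else:
            s.setdefault(g, 0.0)
    return n, s


def oracle_mwu_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size

    def u_stat(group_a_idx):
        ga = pooled[list(group_a_idx)]
        gb = np.delete(pooled, list(group_a_idx))
        u = 0.0
        for x in ga:
            for y in gb:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(range(pooled.size), n1)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def oracle_block_means(volume: np.ndarray, starts) -> np.ndarray:
    """Cell-wise mean by direct block slicing."""
    shape = tuple(len(s) - 1 for s in starts)
    out = np.empty(shape)
    for idx in np.ndindex(shape):
        sl = tuple(
            slice(int(starts[a][idx[a]]), int(starts[a][idx[a] + 1])) for a in range(3)
        )
        out[idx] = volume[sl].mean()
    return out
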