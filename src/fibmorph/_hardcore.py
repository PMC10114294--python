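"""Greedy hard-core thinning of a candidate point cloud.

Candidates are visited in a caller-supplied (shuffled) order; a candidate is
accepted iff it lies at least ``h`` from every previously accepted point.
The spatial hash is a dense grid of cell size ``h`` with per-cell linked
lists, so each test touches at most 27 cells.  A numba-compiled kernel is
used when available (numba is an optional accelerator, not a requirement);
the pure-Python fallback is identical in output.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _greedy_py(pts, order, h, n_target, cell_idx, grid_dims):
    h2 = h * h
    strides = (grid_dims[1] * grid_dims[2], grid_dims[2], 1)
    head = np.full(grid_dims[0] * grid_dims[1] * grid_dims[2], -1, dtype=np.int64)
    nxt = np.full(len(pts), -1, dtype=np.int64)
    accepted = np.empty(min(n_target, len(pts)), dtype=np.int64)
    count = 0
    for i in order:
        cx, cy, cz = cell_idx[i]
        ok = True
        for dx in (-1, 0, 1):
            x = cx + dx
            if x < 0 or x >= grid_dims[0]:
                continue
            for dy in (-1, 0, 1):
                y = cy + dy
                if y < 0 or y >= grid_dims[1]:
                    continue
                for dz in (-1, 0, 1):
                    z = cz + dz
                    if z < 0 or z >= grid_dims[2]:
                        continue
                    j = head[x * strides[0] + y * strides[1] + z]
                    while j >= 0:
                        d = pts[i] - pts[j]
                        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] < h2:
                            ok = False
                            break
                        j = nxt[j]
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            key = cx * strides[0] + cy * strides[1] + cz
            nxt[i] = head[key]
            head[key] = i
            accepted[count] = i
            count += 1
            if count == n_target:
                break
    return accepted[:count]


if _HAVE_NUMBA:
    _greedy_nb = njit(cache=False)(_greedy_py)


def greedy_hardcore(
    pts: np.ndarray, order: np.ndarray, h: float, n_target: int
) -> np.ndarray:
    """Indices (into ``pts``) of accepted points, in acceptance order."""
    pts = np.ascontiguousarray(pts, dtype=np.float64)
    order = np.ascontiguousarray(order, dtype=np.int64)
    lo = pts.min(axis=0)
    cell_idx = np.floor((pts - lo) / h).astype(np.int64)
    grid_dims = cell_idx.max(axis=0) + 1
    kernel = _greedy_nb if _HAVE_NUMBA else _greedy_py
    return np.asarray(
        kernel(pts, order, float(h), int(n_target), cell_idx, np.ascontiguousarray(grid_dims))
    )
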