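"""Shared geometry helpers and independent oracles for the test suite.

Everything here is deliberately naive (flood fill, O(n^2) scans, full-volume
distance evaluation, closed-form calculus) so it stays independent of the
implementation paths it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.integrate import quad


def digitized_ball(radius_vox: float, margin: int = 4, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean ball: voxel centers within ``radius_vox`` of the center voxel."""
    n = int(2 * radius_vox) + 2 * margin + 1
    c = n // 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return (
        (zz - c - offset[0]) ** 2 + (yy - c - offset[1]) ** 2 + (xx - c - offset[2]) ** 2
        <= radius_vox**2
    )


def digitized_box(a: int, b: int, c: int, margin: int = 3) -> np.ndarray:
    m = np.zeros((a + 2 * margin, b + 2 * margin, c + 2 * margin), dtype=bool)
    m[margin : margin + a, margin : margin + b, margin : margin + c] = True
    return m


def digitized_ellipsoid(semi_axes_vox, margin: int = 4) -> np.ndarray:
    """Axis-aligned ellipsoid, semi-axes in voxels as (z, y, x)."""
    az, ay, ax = semi_axes_vox
    nz, ny, nx = (int(2 * a) + 2 * margin + 1 for a in (az, ay, ax))
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    zz, yy, xx = np.mgrid[:nz, :ny, :nx]
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS connected-component labelling (the oracle)."""
    assert connectivity in (6, 26)
    nz, ny, nx = mask.shape
    if connectivity == 6:
        offs = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    else:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    comp = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if comp[start]:
            continue
        current += 1
        comp[start] = current
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                q = (z + dz, y + dy, x + dx)
                if 0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx:
                    if mask[q] and not comp[q]:
                        comp[q] = current
                        queue.append(q)
    return comp


def canonical_labels(comp: np.ndarray) -> np.ndarray:
    """Relabel components by first occurrence in scan order, for comparison."""
    flat = comp.ravel()
    out = np.zeros_like(flat)
    mapping: dict[int, int] = {}
    nxt = 1
    for i in np.nonzero(flat)[0]:
        v = flat[i]
        if v not in mapping:
            mapping[v] = nxt
            nxt += 1
        out[i] = mapping[v]
    return out.reshape(comp.shape)


def brute_force_nn(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """O(n^2) nearest-neighbour distances and partner indices."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    idx = d.argmin(axis=1)
    return d[np.arange(len(points)), idx], idx


def spheroid_surface_area(a: float, b: float) -> float:
    """Surface area of a spheroid with polar semi-axis a and equatorial b,
    by numerical surface-of-revolution integration (independent oracle)."""

    def integrand(x):
        # y(x) = b sqrt(1 - x^2/a^2); dA = 2 pi y sqrt(1 + y'^2) dx
        y2 = max(1.0 - x * x / (a * a), 0.0)
        y = b * np.sqrt(y2)
        if y2 < 1e-14:
            return 0.0
        dy = -b * x / (a * a * np.sqrt(y2))
        return 2 * np.pi * y * np.sqrt(1 + dy * dy)

    val, _ = quad(integrand, -a, a, limit=200)
    return val


def density_node_oracle(occ, spacing_um, node_xyz_um, radius_um):
    """Direct full-volume voxel count for one density node (the oracle)."""
    nz, ny, nx = occ.shape
    sz, sy, sx = spacing_um
    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    X, Y, Z = node_xyz_um
    d2 = (
        (zc - Z)[:, None, None] ** 2
        + (yc - Y)[None, :, None] ** 2
        + (xc - X)[None, None, :] ** 2
    )
    inside = d2 <= radius_um**2
    n_in = int(inside.sum())
    n_occ = int((inside & occ).sum())
    return n_occ, n_in
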