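"""Voxel surface-area estimators.

Three estimators, selected by method id in :func:`fibmorph.instances.measure_surface_area`:

``config`` (default)
    Local 2x2x2 configuration weighting.  Every 2x2x2 cell of voxel centers
    contributes a weight that equals the *expected* area of a randomly
    oriented plane cutting the cell, conditional on the cell's 8-bit
    inside/outside pattern.  The classical isotropic weight tables are a
    special case; here the weights are derived numerically for the actual
    voxel cell box (so anisotropic grids, such as twice-binned 15x15x20 nm
    FIB-SEM data at 30x30x40 nm, are handled without resampling).  The
    derivation is deterministic (fixed internal seed) and cached per cell
    shape.  Unbiased for planar surfaces by construction; ball error well
    under 1% at radius >= 10 voxels.

``mesh``
    Marching cubes on the binary mask at the 0.5 isolevel in physical
    coordinates.  The raw staircase mesh systematically overestimates smooth
    surfaces by ~8-9%; kept as a cross-check, not the default.

``face``
    Naive exposed-face counting.  Overestimates smooth surfaces by a factor
    of exactly 3/2 in the continuum limit (the mean of |n_x|+|n_y|+|n_z| over
    the sphere); provided as a flagged diagnostic / negative control only.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import ConfigurationError

__all__ = ["surface_area", "SURFACE_METHODS", "derive_config_weights"]

SURFACE_METHODS = ("config", "mesh", "face")

_WEIGHT_CACHE: dict[tuple[float, float, float], np.ndarray] = {}
_WEIGHT_SEED = 12345
_N_NORMALS = 200_000
_N_OFFSETS = 16


def _cell_symmetry_perms(spacing_zyx: tuple[float, float, float]) -> list[np.ndarray]:
    """Corner permutations of the cell box: all mirror flips, plus axis
    permutations that map the cell onto itself (only between equal spacings)."""
    perms = []
    for axes in itertools.permutations(range(3)):  # axis index: 0=x,1=y,2=z
        if not all(spacing_zyx[2 - axes[i]] == spacing_zyx[2 - i] for i in range(3)):
            continue
        for flips in itertools.product((0, 1), repeat=3):
            perm = np.empty(8, dtype=np.int64)
            for b in range(8):
                xyz = [(b >> i) & 1 for i in range(3)]
                xyz = [xyz[a] for a in axes]
                xyz = [v ^ f for v, f in zip(xyz, flips)]
                perm[b] = xyz[0] | (xyz[1] << 1) | (xyz[2] << 2)
            perms.append(perm)
    return perms


def derive_config_weights(spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    """256-entry weight table for a voxel cell of the given physical shape.

    ``weights[p]`` is the Monte-Carlo estimate of E[cut area | pattern p] for
    isotropically oriented planes with uniform offset, in squared physical
    units of ``spacing_zyx``.  Patterns unreachable by a plane (all-in /
    all-out) get weight 0.  Deterministic; cached on the spacing *ratio*
    (weights scale as length^2, so only the shape matters).
    """
    spacing_zyx = tuple(float(s) for s in spacing_zyx)
    scale = spacing_zyx[0]
    key = tuple(round(s / scale, 12) for s in spacing_zyx)
    if key in _WEIGHT_CACHE:
        return _WEIGHT_CACHE[key] * scale**2

    sz, sy, sx = key
    rng = np.random.default_rng(_WEIGHT_SEED)
    # corner b of the cell box: (x=(b&1)*sx, y=((b>>1)&1)*sy, z=((b>>2)&1)*sz)
    corners = np.array([[(b & 1) * sx, ((b >> 1) & 1) * sy, ((b >> 2) & 1) * sz] for b in range(8)])
    n = rng.standard_normal((_N_NORMALS, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    proj = n @ corners.T  # (N, 8)
    lo, hi = proj.min(1), proj.max(1)
    span = hi - lo  # a plane with normal n hits the cell with probability ∝ span
    d = lo[:, None] + rng.random((_N_NORMALS, _N_OFFSETS)) * span[:, None]
    pattern = ((proj[:, None, :] > d[:, :, None]) << np.arange(8)).sum(-1)

    # Exact cut area: derivative w.r.t. offset of the halfspace∩box volume
    # V(d) = sum_corners (-1)^{popcount} (d - n·corner)_+^3 / (6 n_x n_y n_z),
    # evaluated with |n| after reflecting the offset into the positive octant.
    m = np.abs(n)
    shift = np.where(n < 0, n, 0.0) @ np.array([sx, sy, sz])
    t = (d - shift[:, None])[:, :, None] - (m @ corners.T)[:, None, :]
    t = np.where(t > 0, t, 0.0)
    sign = np.array([(-1) ** bin(b).count("1") for b in range(8)])
    area = (sign * t * t).sum(-1) / (2 * np.clip(m.prod(1), 1e-12, None))[:, None]

    w_area = np.bincount(pattern.ravel(), weights=(span[:, None] * area).ravel(), minlength=256)
    w_hits = np.bincount(pattern.ravel(), weights=np.broadcast_to(span[:, None], pattern.shape).ravel(), minlength=256)

    # average over the cell's symmetry orbit (and inside/outside complement)
    perms = _cell_symmetry_perms((sz, sy, sx))
    weights = np.zeros(256)
    done = np.zeros(256, dtype=bool)
    for p0 in range(256):
        if done[p0]:
            continue
        orbit = set()
        for perm in perms:
            q = 0
            for b in range(8):
                if p0 >> b & 1:
                    q |= 1 << int(perm[b])
            orbit.add(q)
            orbit.add(q ^ 0xFF)
        total_a = sum(w_area[q] for q in orbit)
        total_h = sum(w_hits[q] for q in orbit)
        w = total_a / total_h if total_h > 0 else 0.0
        for q in orbit:
            weights[q] = w
            done[q] = True
    weights[0] = weights[255] = 0.0
    _WEIGHT_CACHE[key] = weights
    return weights * scale**2


def _pattern_volume(mask: np.ndarray) -> np.ndarray:
    """8-bit corner pattern of every 2x2x2 cell of the zero-padded mask."""
    m = np.pad(mask.astype(np.uint8), 1)
    shape = tuple(s - 1 for s in m.shape)
    pat = np.zeros(shape, dtype=np.int32)
    for b in range(8):
        dx, dy, dz = b & 1, (b >> 1) & 1, (b >> 2) & 1
        pat |= m[dz : dz + shape[0], dy : dy + shape[1], dx : dx + shape[2]].astype(np.int32) << b
    return pat


def _area_config(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> float:
    weights = derive_config_weights(spacing_zyx)
    return float(weights[_pattern_volume(mask)].sum())


def _area_mesh(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> float:
    padded = np.pad(mask, 1).astype(np.uint8)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, 0.5, spacing=spacing_zyx)
    return float(skmeasure.mesh_surface_area(verts, faces))


def _area_face(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> float:
    sz, sy, sx = spacing_zyx
    face_areas = (sy * sx, sz * sx, sz * sy)  # faces normal to z, y, x
    m = np.pad(mask, 1)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(m.astype(np.int8), axis=axis)
        total += fa * np.abs(diff).sum()
    return float(total)


_DISPATCH = {"config": _area_config, "mesh": _area_mesh, "face": _area_face}


def surface_area(mask: np.ndarray, spacing_zyx: tuple[float, float, float], method: str = "config") -> float:
    """Estimate the surface area of a binary 3D mask in physical units.

    ``spacing_zyx`` in any length unit; result in that unit squared.
    """
    if method not in _DISPATCH:
        raise ConfigurationError(f"unknown surface-area method {method!r}; choose from {SURFACE_METHODS}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    # crop to the bounding box (plus the pad added inside each estimator)
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    return _DISPATCH[method](mask[sl], tuple(float(s) for s in spacing_zyx))
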