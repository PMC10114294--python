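"""Instance extraction ("multi-ROI" splitting) and per-object morphometrics.

A semantic label volume (one integer per structure class, or a binary mask)
is split into individual 3D objects by connected components; each object then
gets its voxel count, physical volume V_p, centroid, surface area A_p and
Wadell sphericity

    psi = (6 * sqrt(pi) * V_p)^(2/3) / A_p,

which is 1 for a mathematical sphere and < 1 for any other shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._surface import SURFACE_METHODS, surface_area
from .errors import DomainError, InsufficientDataError, ValidationError
from .volume import LabeledVolume

__all__ = [
    "InstanceSet",
    "split_instances",
    "measure_basic",
    "measure_surface_area",
    "sphericity",
    "flag_volume_outliers",
    "volume_fraction",
]

#: documented tolerance of the surface estimator: psi may exceed 1 by at most this
SPHERICITY_ESTIMATOR_TOL = 0.05


@dataclass
class InstanceSet:
    """Objects split out of one semantic volume, with per-object measurements.

    Attributes
    ----------
    volume
        Instance-labeled volume (same grid as the source; voxel value = object
        id, 0 = background).
    table
        One row per object.  Always present: ``id``, ``class_name``,
        ``voxel_count``, ``border`` (touches the volume face), ``semantic_label``.
        After :func:`measure_basic`: ``volume_um3``, ``centroid_x_um``,
        ``centroid_y_um``, ``centroid_z_um``.  After
        :func:`measure_surface_area`: ``area_um2``, ``sphericity``,
        ``surface_method``.
    """

    volume: LabeledVolume
    table: pd.DataFrame
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def centroids_um(self) -> np.ndarray:
        """(n, 3) centroids as (x, y, z) in micrometres."""
        cols = ["centroid_x_um", "centroid_y_um", "centroid_z_um"]
        if not set(cols) <= set(self.table.columns):
            raise ValidationError("centroids not measured yet; call measure_basic first")
        return self.table[cols].to_numpy(dtype=np.float64)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


def split_instances(vol: LabeledVolume, connectivity: int = 26) -> InstanceSet:
    """Split a semantic volume into maximal connected components.

    Components are computed separately within each semantic label value, so
    touching objects of *different* classes never merge.  Instance ids are
    assigned in (semantic label, scan order) and are stable across re-runs.
    An empty volume yields an empty set.
    """
    structure = _structure(connectivity)
    labels = vol.labels
    out = np.zeros(labels.shape, dtype=np.uint32)
    rows: list[tuple[int, int, int, bool]] = []  # id, semantic, count, border
    next_id = 1
    for semantic in np.unique(labels):
        if semantic == 0:
            continue
        mask = labels == semantic
        comp, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        comp32 = comp.astype(np.uint32)
        out[mask] = comp32[mask] + np.uint32(next_id - 1)
        counts = np.bincount(comp32[mask], minlength=n + 1)[1:]
        border = np.zeros(n + 1, dtype=bool)
        for face in (
            comp32[0], comp32[-1], comp32[:, 0], comp32[:, -1], comp32[:, :, 0], comp32[:, :, -1],
        ):
            border[np.unique(face)] = True
        for k in range(n):
            rows.append((next_id + k, int(semantic), int(counts[k]), bool(border[k + 1])))
        next_id += n
    table = pd.DataFrame(rows, columns=["id", "semantic_label", "voxel_count", "border"])
    table.insert(1, "class_name", vol.class_name)
    inst_vol = LabeledVolume(out, vol.spacing_nm, class_name=vol.class_name)
    return InstanceSet(inst_vol, table, connectivity=connectivity)


def measure_basic(instances: InstanceSet) -> InstanceSet:
    """Attach exact physical volume and centroid to every object.

    ``V_p = voxel_count * voxel_volume`` exactly; the centroid is the
    unweighted mean of member voxel centers, reported as (x, y, z) in um.
    """
    vol = instances.volume
    table = instances.table.copy()
    n = len(table)
    table["volume_um3"] = table["voxel_count"] * vol.voxel_volume_um3
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    cz = np.full(n, np.nan)
    if n:
        zz, yy, xx = np.nonzero(vol.labels)
        ids = vol.labels[zz, yy, xx]
        m = int(ids.max()) + 1
        counts = np.bincount(ids, minlength=m)
        sz, sy, sx = vol.spacing_um
        mean_z = np.bincount(ids, weights=zz, minlength=m)
        mean_y = np.bincount(ids, weights=yy, minlength=m)
        mean_x = np.bincount(ids, weights=xx, minlength=m)
        with np.errstate(invalid="ignore"):
            mean_z = mean_z / counts
            mean_y = mean_y / counts
            mean_x = mean_x / counts
        idx = table["id"].to_numpy()
        cx = (mean_x[idx] + 0.5) * sx
        cy = (mean_y[idx] + 0.5) * sy
        cz = (mean_z[idx] + 0.5) * sz
    table["centroid_x_um"] = cx
    table["centroid_y_um"] = cy
    table["centroid_z_um"] = cz
    return InstanceSet(vol, table, connectivity=instances.connectivity)


def measure_surface_area(instances: InstanceSet, method: str = "config") -> InstanceSet:
    """Attach surface area A_p (um^2) and sphericity to every object.

    ``method`` is one of ``config`` (default), ``mesh`` or ``face`` — see
    :mod:`fibmorph._surface`.  Requires :func:`measure_basic` first (for V_p).
    """
    if method not in SURFACE_METHODS:
        # delegate for the error message
        surface_area(np.zeros((1, 1, 1), bool), (1, 1, 1), method=method)
    table = instances.table.copy()
    if "volume_um3" not in table.columns:
        instances = measure_basic(instances)
        table = instances.table.copy()
    vol = instances.volume
    spacing_um = vol.spacing_um
    areas = np.zeros(len(table))
    slices = ndimage.find_objects(vol.labels.astype(np.int64))
    for row, obj_id in enumerate(table["id"]):
        sl = slices[obj_id - 1]
        mask = vol.labels[sl] == obj_id
        areas[row] = surface_area(mask, spacing_um, method=method)
    table["area_um2"] = areas
    table["sphericity"] = sphericity(table["volume_um3"].to_numpy(), areas)
    table["surface_method"] = method
    return InstanceSet(vol, table, connectivity=instances.connectivity)


def sphericity(volume, area):
    """Wadell sphericity ``(6 sqrt(pi) V)^(2/3) / A``; 1 for a sphere.

    Accepts scalars or arrays; volume in um^3, area in um^2 (any consistent
    unit pair works — the ratio is dimensionless).
    """
    v = np.asarray(volume, dtype=np.float64)
    a = np.asarray(area, dtype=np.float64)
    if np.any(v <= 0) or np.any(a <= 0):
        raise DomainError("sphericity requires V_p > 0 and A_p > 0")
    out = (6.0 * np.sqrt(np.pi) * v) ** (2.0 / 3.0) / a
    return float(out) if np.isscalar(volume) or np.ndim(volume) == 0 else out


def flag_volume_outliers(instances: InstanceSet, factor: float = 100.0) -> np.ndarray:
    """Ids of objects whose volume is >= ``factor`` times the median volume.

    The default factor of 100 flags "two orders of magnitude" outliers — the
    giant mitochondria regime.  Requires at least 3 measured objects.
    """
    table = instances.table
    if "volume_um3" not in table.columns:
        table = measure_basic(instances).table
    if len(table) < 3:
        raise InsufficientDataError(f"outlier flagging needs >= 3 objects, got {len(table)}")
    volumes = table["volume_um3"].to_numpy()
    median = float(np.median(volumes))
    return table.loc[volumes >= factor * median, "id"].to_numpy()


def volume_fraction(child: InstanceSet | LabeledVolume, parents: LabeledVolume) -> pd.DataFrame:
    """Per-parent-cell volume fraction occupied by a child structure class.

    For every parent label: ``fraction = (child voxels inside the parent) /
    (parent voxels)``, in [0, 1] (child and parent share the grid, so voxel
    volumes cancel).  Child voxels lying outside every parent are *reported*,
    not dropped: they appear in a ``parent_id = 0`` row.

    Returns a DataFrame with ``parent_id, parent_voxels, child_voxels,
    fraction`` (fraction is NaN on the orphan row).
    """
    child_vol = child.volume if isinstance(child, InstanceSet) else child
    if not child_vol.same_grid(parents):
        raise ValidationError("child and parent volumes must share shape and spacing")
    child_mask = child_vol.labels > 0
    parent_labels = parents.labels
    m = int(parent_labels.max()) + 1
    parent_counts = np.bincount(parent_labels.ravel(), minlength=m)
    child_counts = np.bincount(parent_labels[child_mask].ravel(), minlength=m)
    rows = []
    n_orphan = int(child_counts[0])
    for pid in range(1, m):
        if parent_counts[pid] == 0:
            continue
        rows.append(
            (pid, int(parent_counts[pid]), int(child_counts[pid]), child_counts[pid] / parent_counts[pid])
        )
    if n_orphan:
        rows.append((0, 0, n_orphan, np.nan))
    return pd.DataFrame(rows, columns=["parent_id", "parent_voxels", "child_voxels", "fraction"])
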