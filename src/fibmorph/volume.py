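"""Label volumes with physical voxel spacing.

The package's substrate is a 3D integer grid in ``(z, y, x)`` axis order with
the voxel spacing, in nanometres, stored in the same order.  Physical
*coordinates* reported to the user (centroids, nearest-neighbour distances,
density-map nodes) are always ``(x, y, z)`` in micrometres, matching the
conventional FIB-SEM acquisition notation (e.g. 15 x 15 x 20 nm in x, y, z).

Voxel ``(k, j, i)`` (z, y, x indices, 0-based) has its *center* at physical
position ``((i + 0.5) s_x, (j + 0.5) s_y, (k + 0.5) s_z)``; the centroid of a
single-voxel object is therefore the voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

NM_PER_UM = 1000.0

__all__ = ["LabeledVolume", "NM_PER_UM"]


@dataclass
class LabeledVolume:
    """A 3D non-negative integer label grid with physical voxel spacing.

    Parameters
    ----------
    labels
        Integer array of shape ``(n_z, n_y, n_x)``; 0 is background.
    spacing_nm
        Voxel spacing ``(s_z, s_y, s_x)`` in nanometres, all > 0.
    class_name
        Free-text name of the structure class (``"nuclei"``, ``"cell
        junctions"``, ...).
    """

    labels: np.ndarray
    spacing_nm: tuple[float, float, float]
    class_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError(f"labels must be 3D (z, y, x); got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.bool_):
                arr = arr.astype(np.uint8)
            else:
                raise ValidationError(f"labels must be integer-valued; got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ValidationError("labels must be >= 0 (0 = background)")
        if arr.size and arr.max() > np.iinfo(np.uint32).max:
            raise ValidationError("labels above 32-bit range are not supported")
        self.labels = arr
        spacing = tuple(float(s) for s in self.spacing_nm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing_nm must be 3 positive values (z, y, x); got {self.spacing_nm}")
        self.spacing_nm = spacing  # type: ignore[assignment]
        if any(n < 1 for n in arr.shape):
            raise ValidationError(f"all shape components must be >= 1; got {arr.shape}")

    # -- derived physical quantities -------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        """Spacing (z, y, x) in micrometres."""
        return tuple(s / NM_PER_UM for s in self.spacing_nm)  # type: ignore[return-value]

    @property
    def voxel_volume_nm3(self) -> float:
        """Physical volume of one voxel in nm^3."""
        sz, sy, sx = self.spacing_nm
        return sz * sy * sx

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_volume_nm3 / NM_PER_UM**3

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) of the grid in micrometres."""
        nz, ny, nx = self.shape
        sz, sy, sx = self.spacing_um
        return (nx * sx, ny * sy, nz * sz)

    # -- coordinate transforms -------------------------------------------

    def voxel_centers_um(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) centers in um for an (n, 3) array of (z, y, x) indices."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=np.float64))
        sz, sy, sx = self.spacing_um
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5) * sx
        out[:, 1] = (idx[:, 1] + 0.5) * sy
        out[:, 2] = (idx[:, 0] + 0.5) * sz
        return out

    def foreground_mask(self) -> np.ndarray:
        return self.labels > 0

    def same_grid(self, other: "LabeledVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_nm, other.spacing_nm)

    def __eq__(self, other: object) -> bool:  # identity on labels + spacing
        if not isinstance(other, LabeledVolume):
            return NotImplemented
        return self.same_grid(other) and bool(np.array_equal(self.labels, other.labels))
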