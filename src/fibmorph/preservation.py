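"""Ultrastructural-preservation statistics from manually scored TEM tiles.

High-pressure freezing quality varies across a 3D culture; each organoid is
surveyed as a montage of TEM tiles and every tile is scored damaged/intact by
eye.  Per organoid the *preserved fraction* is intact tiles over total tiles;
*packing density* is the organoid's cross-sectional area divided by its cell
count (approximated by counting nuclei) — lower area per cell means denser
packing.  Groups are summarized with median / quartiles / min / max box
statistics, and the packing-preservation relationship with the Pearson
product-moment correlation.

Quartiles use linear interpolation between order statistics throughout the
package (the same rule as the nearest-neighbour summaries).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError
from .tables import TileScoreTable

__all__ = [
    "preservation_fraction",
    "packing_density",
    "group_box_stats",
    "pearson_r",
    "summarize_preservation",
]


def preservation_fraction(table: TileScoreTable) -> pd.DataFrame:
    """Per-organoid fraction of intact tiles.

    Returns a DataFrame ``sample_group, organoid_id, n_tiles, n_damaged,
    preserved_fraction``; invariant to tile order and to how the scoring CSV
    was split across files.
    """
    tiles = table.tiles
    if tiles.empty:
        raise ValidationError("tile table is empty")
    grouped = (
        tiles.groupby(["sample_group", "organoid_id"], sort=True)["damaged"]
        .agg(n_tiles="count", n_damaged="sum")
        .reset_index()
    )
    grouped["preserved_fraction"] = 1.0 - grouped["n_damaged"] / grouped["n_tiles"]
    return grouped


def packing_density(area_um2: float, n_cells: int) -> float:
    """Organoid cross-sectional area per cell, in um^2/cell."""
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    if area_um2 <= 0:
        raise DomainError("organoid area must be > 0")
    return float(area_um2) / float(n_cells)


def group_box_stats(values) -> dict:
    """Median, 25-75% interval, min and max — the box-plot summary."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise InsufficientDataError("no values to summarize")
    return {
        "median": float(np.percentile(v, 50)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InsufficientDataError("Pearson correlation needs >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def summarize_preservation(table: TileScoreTable) -> dict:
    """Full preservation summary for one scored dataset.

    Per-organoid preserved fractions and (when area/cell counts are present)
    packing densities; per-group box statistics; and the Pearson R between
    packing density and preserved fraction across organoids.
    """
    per_org = preservation_fraction(table)
    out: dict = {"per_organoid": per_org, "groups": {}, "pearson_r": None}
    for group, sub in per_org.groupby("sample_group"):
        out["groups"][group] = group_box_stats(sub["preserved_fraction"])
    if table.organoids is not None:
        merged = per_org.merge(table.organoids, on="organoid_id", how="inner")
        merged["packing_density_um2_per_cell"] = [
            packing_density(a, n) for a, n in zip(merged["organoid_area_um2"], merged["n_cells"])
        ]
        out["per_organoid"] = merged
        if len(merged) >= 3 and merged["preserved_fraction"].std() > 0 and merged["packing_density_um2_per_cell"].std() > 0:
            out["pearson_r"] = pearson_r(
                merged["packing_density_um2_per_cell"], merged["preserved_fraction"]
            )
    return out
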