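"""Tabular inputs: manual tile-scoring tables for preservation statistics.

Tile scores are an *input* to this package — in the source studies they come
from visual inspection of TEM tile montages (a tile is marked damaged when it
shows evident freeze-damage artifacts).  No automated damage detection is
attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import SchemaError, ValidationError

TILE_COLUMNS = ("sample_group", "organoid_id", "tile_id", "damaged")
ORGANOID_COLUMNS = ("organoid_id", "organoid_area_um2", "n_cells")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a damaged flag (use 0/1, true/false, yes/no)")


@dataclass
class TileScoreTable:
    """Per-tile freeze-damage scores, optionally with per-organoid area/cell counts.

    Attributes
    ----------
    tiles
        DataFrame with columns ``sample_group, organoid_id, tile_id, damaged``;
        one row per examined TEM tile, ``damaged`` boolean.
    organoids
        Optional DataFrame with ``organoid_id, organoid_area_um2, n_cells`` —
        the cross-sectional area (um^2) and nucleus count used for packing
        density.
    """

    tiles: pd.DataFrame
    organoids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TILE_COLUMNS if c not in self.tiles.columns]
        if missing:
            raise SchemaError(f"tile table missing required columns: {missing}")
        tiles = self.tiles.loc[:, list(TILE_COLUMNS)].copy()
        tiles["damaged"] = tiles["damaged"].map(_parse_bool)
        dup = tiles.duplicated(subset=["organoid_id", "tile_id"])
        if dup.any():
            pairs = tiles.loc[dup, ["organoid_id", "tile_id"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (organoid_id, tile_id) pairs: {pairs[:5]}")
        self.tiles = tiles.reset_index(drop=True)

        if self.organoids is not None:
            missing = [c for c in ORGANOID_COLUMNS if c not in self.organoids.columns]
            if missing:
                raise SchemaError(f"organoid table missing required columns: {missing}")
            org = self.organoids.loc[:, list(ORGANOID_COLUMNS)].copy()
            org["organoid_area_um2"] = org["organoid_area_um2"].astype(float)
            org["n_cells"] = org["n_cells"].astype(int)
            if (org["n_cells"] < 1).any():
                raise ValidationError("n_cells must be >= 1 for every organoid")
            if (org["organoid_area_um2"] <= 0).any():
                raise ValidationError("organoid_area_um2 must be > 0")
            self.organoids = org.reset_index(drop=True)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def concat(self, other: "TileScoreTable") -> "TileScoreTable":
        """Merge two score tables (e.g. CSVs split per session) into one."""
        org = None
        parts = [t for t in (self.organoids, other.organoids) if t is not None]
        if parts:
            org = pd.concat(parts, ignore_index=True).drop_duplicates(subset="organoid_id")
        return TileScoreTable(pd.concat([self.tiles, other.tiles], ignore_index=True), org)
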