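"""Categorical land-cover grids: ingest, area tabulation and change accounting.

Areas are derived purely from cell counts (count x cell_size^2 / 10^4 hm^2),
never from polygonization, so a class area is exact for any grid. The seven
canonical landscape classes of a high-groundwater mining subsidence area are
listed in :data:`CANONICAL_CLASSES`; legends may use any subset or other
names, but the water-change aggregate is only computed when the canonical
water class names are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, read_ascii_grid, write_ascii_grid

__all__ = [
    "CANONICAL_CLASSES",
    "LandCoverGrid",
    "LandscapeAreaTable",
    "AreaChangeTable",
    "read_landcover_grid",
    "write_landcover_grid",
    "read_legend",
    "tabulate_areas",
    "area_change",
    "round_half_up",
]

#: Landscape classes used throughout: farmland plus the classes created or
#: destroyed by mining subsidence and reclamation. ``subsided_water`` is the
#: ponded subsidence water body; ``natural_water`` covers rivers, ponds and
#: the reclaimed lake wetland.
CANONICAL_CLASSES = (
    "cultivated",
    "woodland",
    "grassland",
    "transportation",
    "natural_water",
    "built_up",
    "subsided_water",
)

SQM_PER_HECTARE = 10_000.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LandCoverGrid:
    """A georeferenced categorical grid of integer class codes.

    ``values`` holds class codes; ``nodata`` cells are excluded from all
    accounting. Every non-nodata code must appear in ``legend``.
    """

    values: np.ndarray
    grid: GridSpec
    legend: dict[int, str]
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("land-cover values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int, self.values):
                raise ValueError("land-cover codes must be integers")
            self.values = as_int
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid geometry")
        codes = np.unique(self.values)
        unknown = [int(c) for c in codes if c != self.nodata and int(c) not in self.legend]
        if unknown:
            raise ValueError(f"class codes not in legend: {unknown}")

    @property
    def cell_size(self) -> float:
        return self.grid.cell_size

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.values != self.nodata))


@dataclass
class LandscapeAreaTable:
    """Per-class areas (hm^2) and shares of the total landscape."""

    areas: dict[str, float]
    cell_size: float

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def percents(self) -> dict[str, float]:
        tot = self.total
        return {k: (100.0 * v / tot if tot > 0 else 0.0) for k, v in self.areas.items()}

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        rows = [
            {"class": k, "area_hm2": round_half_up(v, ndigits),
             "percent": round_half_up(self.percents[k], ndigits)}
            for k, v in self.areas.items()
        ]
        rows.append({"class": "total", "area_hm2": round_half_up(self.total, ndigits),
                     "percent": 100.0})
        return pd.DataFrame(rows)


@dataclass
class AreaChangeTable:
    """Before/after class areas with absolute (hm^2) and relative (%) change."""

    before: dict[str, float]
    after: dict[str, float]
    #: named aggregates, e.g. total_water -> (absolute change, relative change %)
    aggregates: dict[str, tuple[float, float | None]] = field(default_factory=dict)

    @property
    def absolute(self) -> dict[str, float]:
        return {k: self.after[k] - self.before[k] for k in self.before}

    @property
    def relative(self) -> dict[str, float | None]:
        """Percent change; None when the before-area is zero (undefined)."""
        out: dict[str, float | None] = {}
        for k, b in self.before.items():
            out[k] = None if b == 0 else (self.after[k] - b) / b * 100.0
        return out

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        rel = self.relative
        return pd.DataFrame(
            [
                {
                    "class": k,
                    "before_hm2": round_half_up(self.before[k], ndigits),
                    "after_hm2": round_half_up(self.after[k], ndigits),
                    "change_hm2": round_half_up(self.absolute[k], ndigits),
                    "change_pct": None if rel[k] is None else round_half_up(rel[k], ndigits),
                }
                for k in self.before
            ]
        )


def read_legend(path: str | Path) -> dict[int, str]:
    """Read a legend mapping class code -> class name from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return {int(k): str(v) for k, v in raw.items()}


def read_landcover_grid(
    path: str | Path, legend: dict[int, str] | str | Path, nodata: int = -9999
) -> LandCoverGrid:
    """Read a single-band integer raster (ESRI ASCII grid) with its legend."""
    if not isinstance(legend, dict):
        legend = read_legend(legend)
    values, grid, file_nodata = read_ascii_grid(path)
    as_int = values.astype(np.int64)
    if not np.array_equal(as_int, values):
        raise ValueError(f"{path}: land-cover band contains non-integer codes")
    return LandCoverGrid(values=as_int, grid=grid, legend=legend, nodata=int(file_nodata))


def write_landcover_grid(path: str | Path, lc: LandCoverGrid) -> None:
    write_ascii_grid(path, lc.values, lc.grid, nodata=lc.nodata, fmt="%d")


def tabulate_areas(grid: LandCoverGrid) -> LandscapeAreaTable:
    """Tabulate per-class areas in hm^2 and their shares of the landscape.

    Every legend class is reported, including zero-area ones, so before/after
    tables over the same legend share a class universe.
    """
    valid = grid.values[grid.values != grid.nodata]
    if valid.size == 0:
        raise ValueError("grid contains only nodata cells")
    cell_hm2 = grid.grid.cell_area / SQM_PER_HECTARE
    codes, counts = np.unique(valid, return_counts=True)
    count_by_code = dict(zip((int(c) for c in codes), (int(n) for n in counts)))
    areas = {name: count_by_code.get(code, 0) * cell_hm2 for code, name in grid.legend.items()}
    return LandscapeAreaTable(areas=areas, cell_size=grid.cell_size)


def area_change(
    before: LandscapeAreaTable,
    after: LandscapeAreaTable,
    total_tol_hm2: float = 0.01,
) -> AreaChangeTable:
    """Structural change between two epochs covering the same extent.

    The ``total_water`` aggregate — the net water-surface change when the
    subsided water body is reclaimed into a lake wetland — is
    natural_water_after - (natural_water_before + subsided_water_before),
    with the relative change taken against the combined before-water area.
    """
    if set(before.areas) != set(after.areas):
        raise ValueError("before/after tables have different class universes")
    if abs(before.total - after.total) > total_tol_hm2:
        raise ValueError(
            f"total areas differ ({before.total:.2f} vs {after.total:.2f} hm^2); "
            "grids must cover the same extent"
        )
    aggregates: dict[str, tuple[float, float | None]] = {}
    if {"natural_water", "subsided_water"} <= set(before.areas):
        water_before = before.areas["natural_water"] + before.areas["subsided_water"]
        water_after = after.areas["natural_water"] + after.areas["subsided_water"]
        delta = water_after - water_before
        rel = None if water_before == 0 else delta / water_before * 100.0
        aggregates["total_water"] = (delta, rel)
    return AreaChangeTable(before=dict(before.areas), after=dict(after.areas),
                           aggregates=aggregates)
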