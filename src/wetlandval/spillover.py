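"""Land-price spillover of an ecological-restoration site on planned land.

Three-step procedure on two kriged price surfaces (before/after epochs):

1. the regional average price rise r = (mean_after - mean_before)/mean_before
   removes market-wide inflation and shared location effects;
2. the excess surface Lp_after - Lp_before * (1 + r) isolates price growth
   beyond the regional trend; its positive part is the spillover's impact
   range (mask);
3. the spillover effect value SEV integrates the positive excess over the
   planned plots: SEV = sum over plots of sum_{cells in plot & mask}
   excess * cell_area (yuan).

Negative excess cells are retained in the grid for inspection but excluded
from the valuation (the impact range is defined as where excess > 0), so
SEV >= 0 by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .geostat import (
    DEFAULT_FAMILIES,
    PricePointSet,
    PriceSurface,
    empirical_semivariogram,
    fit_variogram,
    loo_cross_validate,
    morans_i,
    normality_test,
    ordinary_kriging,
)
from .grid import GridSpec
from .landcover import SQM_PER_HECTARE

logger = logging.getLogger("wetlandval.spillover")

__all__ = [
    "PlannedPlotSet",
    "ExcessField",
    "SpilloverResult",
    "PipelineConfig",
    "average_rise",
    "excess_surface",
    "compute_sev",
    "plot_total_value",
    "run_spillover_pipeline",
    "format_wanyuan",
    "format_yiyuan",
]


def format_wanyuan(yuan: float) -> str:
    return f"{yuan / 1e4:,.2f} 万元"


def format_yiyuan(yuan: float) -> str:
    return f"{yuan / 1e8:,.4f} 亿元"


# ---------------------------------------------------------------------------
# planned plots


@dataclass
class PlannedPlotSet:
    """Planned-land plot polygons with ids, land-use type and areas (m^2)."""

    plot_ids: list[str]
    landuse: list[str]
    geometries: list[shapely.Geometry]
    areas_m2: np.ndarray

    def __post_init__(self) -> None:
        self.areas_m2 = np.asarray(self.areas_m2, dtype=np.float64)
        n = len(self.plot_ids)
        if not (len(self.landuse) == len(self.geometries) == self.areas_m2.size == n):
            raise ValueError("plot attribute lengths differ")
        for pid, geom, area in zip(self.plot_ids, self.geometries, self.areas_m2):
            if not geom.is_valid:
                raise ValueError(f"plot {pid!r}: invalid (self-intersecting?) polygon")
            if area <= 0:
                raise ValueError(f"plot {pid!r}: non-positive area")
            if abs(area - geom.area) > 0.01 * max(area, geom.area):
                raise ValueError(
                    f"plot {pid!r}: declared area {area:.1f} m^2 differs from "
                    f"geometric area {geom.area:.1f} m^2 by more than 1%"
                )

    @property
    def n(self) -> int:
        return len(self.plot_ids)

    @property
    def total_area_m2(self) -> float:
        return float(self.areas_m2.sum())

    @classmethod
    def from_polygons(
        cls,
        geometries: list[shapely.Geometry],
        plot_ids: list[str] | None = None,
        landuse: str | list[str] = "residential",
    ) -> "PlannedPlotSet":
        n = len(geometries)
        if plot_ids is None:
            plot_ids = [f"plot_{i:03d}" for i in range(n)]
        if isinstance(landuse, str):
            landuse = [landuse] * n
        areas = np.array([g.area for g in geometries])
        return cls(plot_ids=list(plot_ids), landuse=list(landuse),
                   geometries=list(geometries), areas_m2=areas)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PlannedPlotSet":
        data = json.loads(Path(path).read_text())
        feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
        ids, uses, geoms, areas = [], [], [], []
        for i, feat in enumerate(feats):
            props = feat.get("properties") or {}
            geom = shape(feat["geometry"])
            ids.append(str(props.get("plot_id", f"plot_{i:03d}")))
            uses.append(str(props.get("landuse", "residential")))
            geoms.append(geom)
            areas.append(float(props.get("area_m2", geom.area)))
        return cls(plot_ids=ids, landuse=uses, geometries=geoms,
                   areas_m2=np.asarray(areas))

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"plot_id": pid, "landuse": use, "area_m2": float(area)},
                "geometry": mapping(geom),
            }
            for pid, use, geom, area in zip(
                self.plot_ids, self.landuse, self.geometries, self.areas_m2
            )
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )


# ---------------------------------------------------------------------------
# surface algebra


def _check_geometry(before: PriceSurface, after: PriceSurface) -> None:
    if not before.grid.same_geometry(after.grid):
        raise ValueError("price surfaces do not share grid geometry")


def average_rise(
    before: PriceSurface,
    after: PriceSurface,
    region_mask: np.ndarray | None = None,
) -> float:
    """Regional average price rise r as a dimensionless fraction.

    Computed as the ratio of region-mean surface values (raster semantics:
    the averaging region is the full valid study-area grid unless a
    narrower ``region_mask`` is given).
    """
    _check_geometry(before, after)
    mask = before.mask & after.mask
    if region_mask is not None:
        if region_mask.shape != mask.shape:
            raise ValueError("region mask shape does not match surfaces")
        mask &= region_mask.astype(bool)
    if not mask.any():
        raise ValueError("no valid cells in the averaging region")
    mean_b = float(before.values[mask].mean())
    mean_a = float(after.values[mask].mean())
    if mean_b <= 0:
        raise ValueError(f"non-positive mean before-price ({mean_b:.3f})")
    r = (mean_a - mean_b) / mean_b
    logger.info("average regional price rise: %.2f%%", 100.0 * r)
    return r


@dataclass
class ExcessField:
    """Cellwise excess price Lp_after - Lp_before*(1+r) and its positive mask."""

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    r: float


def excess_surface(before: PriceSurface, after: PriceSurface, r: float) -> ExcessField:
    """Excess-price grid above the regional trend; mask = excess > 0."""
    _check_geometry(before, after)
    if r <= -1:
        raise ValueError(f"average rise must exceed -1, got {r}")
    valid = before.mask & after.mask
    excess = np.where(valid, after.values - before.values * (1.0 + r), np.nan)
    mask = valid & (excess > 0)
    return ExcessField(values=excess, mask=mask, grid=before.grid, r=r)


# ---------------------------------------------------------------------------
# zonal valuation


@dataclass
class SpilloverResult:
    """Spillover valuation bundle (yuan; areas in hm^2)."""

    r: float
    excess: ExcessField
    per_plot_value: dict[str, float]
    sev: float
    max_impact: float
    mean_impact: float
    affected_area_hm2: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "average_rise_pct": 100.0 * self.r,
            "sev_yuan": self.sev,
            "max_impact_yuan_m2": self.max_impact,
            "mean_impact_yuan_m2": self.mean_impact,
            "affected_area_hm2": self.affected_area_hm2,
            "per_plot_value_yuan": self.per_plot_value,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _plot_cell_membership(grid: GridSpec, plots: PlannedPlotSet) -> list[np.ndarray]:
    """Cell-center-in-polygon membership per plot (raster-calculator semantics)."""
    X, Y = grid.cell_centers()
    xs, ys = X.ravel(), Y.ravel()
    members = []
    for geom in plots.geometries:
        shapely.prepare(geom)
        xmin, ymin, xmax, ymax = geom.bounds
        cand = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
        inside = np.zeros(xs.shape, dtype=bool)
        if cand.any():
            inside[cand] = shapely.contains_xy(geom, xs[cand], ys[cand])
        members.append(inside.reshape(grid.shape))
    return members


def compute_sev(
    excess: ExcessField,
    plots: PlannedPlotSet,
    provenance: dict | None = None,
) -> SpilloverResult:
    """Integrate the positive excess over planned plots.

    Per-plot value = sum of masked excess cells inside the plot x cell
    area; SEV is their sum. Impact statistics (max/mean, yuan/m^2) are
    taken over mask-and-plot cells; affected area is the total area of
    plots that intersect the mask.
    """
    members = _plot_cell_membership(excess.grid, plots)
    cell_area = excess.grid.cell_area
    per_plot: dict[str, float] = {}
    affected = 0.0
    impact_cells: list[np.ndarray] = []
    any_overlap = False
    for pid, area, inside in zip(plots.plot_ids, plots.areas_m2, members):
        if inside.any():
            any_overlap = True
        hit = inside & excess.mask
        per_plot[pid] = float(excess.values[hit].sum() * cell_area) if hit.any() else 0.0
        if hit.any():
            affected += float(area)
            impact_cells.append(excess.values[hit])
    if not any_overlap:
        logger.warning("planned plots do not overlap the analysis grid; SEV = 0")
    sev = float(sum(per_plot.values()))
    if impact_cells:
        allv = np.concatenate(impact_cells)
        max_imp, mean_imp = float(allv.max()), float(allv.mean())
    else:
        max_imp = mean_imp = 0.0
    return SpilloverResult(
        r=excess.r, excess=excess, per_plot_value=per_plot, sev=sev,
        max_impact=max_imp, mean_impact=mean_imp,
        affected_area_hm2=affected / SQM_PER_HECTARE,
        provenance=provenance or {},
    )


def plot_total_value(surface: PriceSurface, plots: PlannedPlotSet) -> float:
    """Total market value (yuan) of the plots at the surface's prices.

    Mean valid price within each plot x declared plot area; used as the
    denominator of relative spillover shares.
    """
    members = _plot_cell_membership(surface.grid, plots)
    total = 0.0
    for area, inside in zip(plots.areas_m2, members):
        hit = inside & surface.mask
        if hit.any():
            total += float(surface.values[hit].mean()) * float(area)
    return total


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end spillover analysis."""

    n_bins: int = 12
    max_lag: float | None = None
    families: tuple[str, ...] = DEFAULT_FAMILIES
    max_neighbors: int = 32
    permutations: int = 999
    seed: int = 0
    abort_on_screen_fail: bool = False
    region_mask: np.ndarray | None = None
    cross_validate: bool = True


def _screen(points: PricePointSet, cfg: PipelineConfig, label: str) -> dict:
    norm = normality_test(points.price)
    mor = morans_i(points, permutations=cfg.permutations, seed=cfg.seed)
    info = {
        "normality_W": norm.statistic, "normality_p": norm.p_value,
        "normality_pass": norm.passed,
        "morans_I": mor.I, "morans_p": mor.p_value,
        "morans_significant": mor.significant,
    }
    if not norm.passed:
        logger.warning("%s: %s", label, norm.recommendation)
    if not mor.significant:
        logger.warning("%s: no significant positive spatial autocorrelation "
                       "(I=%.3f, p=%.3f)", label, mor.I, mor.p_value)
    if cfg.abort_on_screen_fail and not (norm.passed and mor.significant):
        raise RuntimeError(f"{label}: sample screening failed")
    return info


def _fit_epoch(points: PricePointSet, cfg: PipelineConfig, label: str):
    emp = empirical_semivariogram(points, n_bins=cfg.n_bins, max_lag=cfg.max_lag)
    models = fit_variogram(emp, families=cfg.families)
    if cfg.cross_validate and points.n >= 10 and len(models) > 1:
        models = loo_cross_validate(points, models, max_neighbors=cfg.max_neighbors)
    best = models[0]
    logger.info("%s: selected %s variogram (nugget=%.1f, sill=%.1f, range=%.0f m, "
                "LOO-RMSE=%s)", label, best.family, best.nugget, best.sill,
                best.range_, f"{best.loo_rmse:.2f}" if best.loo_rmse else "n/a")
    return best, models


def run_spillover_pipeline(
    points_before: PricePointSet,
    points_after: PricePointSet,
    grid_spec: GridSpec,
    plots: PlannedPlotSet,
    config: PipelineConfig | None = None,
) -> SpilloverResult:
    """Screen -> variogram fit + CV per epoch -> krige both epochs -> r ->
    excess/mask -> SEV. Screening failures are advisory unless
    ``config.abort_on_screen_fail``."""
    cfg = config or PipelineConfig()
    prov: dict = {"config": {
        "n_bins": cfg.n_bins, "max_lag": cfg.max_lag, "families": list(cfg.families),
        "max_neighbors": cfg.max_neighbors, "seed": cfg.seed,
        "cell_size": grid_spec.cell_size,
    }}
    prov["screen_before"] = _screen(points_before, cfg, "before-epoch samples")
    prov["screen_after"] = _screen(points_after, cfg, "after-epoch samples")
    best_b, models_b = _fit_epoch(points_before, cfg, "before epoch")
    best_a, models_a = _fit_epoch(points_after, cfg, "after epoch")
    prov["variogram_before"] = [
        {"family": m.family, "nugget": m.nugget, "psill": m.psill, "range": m.range_,
         "loo_rmse": m.loo_rmse} for m in models_b
    ]
    prov["variogram_after"] = [
        {"family": m.family, "nugget": m.nugget, "psill": m.psill, "range": m.range_,
         "loo_rmse": m.loo_rmse} for m in models_a
    ]
    surf_b = ordinary_kriging(points_before, best_b, grid_spec,
                              max_neighbors=cfg.max_neighbors)
    surf_a = ordinary_kriging(points_after, best_a, grid_spec,
                              max_neighbors=cfg.max_neighbors)
    r = average_rise(surf_b, surf_a, region_mask=cfg.region_mask)
    excess = excess_surface(surf_b, surf_a, r)
    return compute_sev(excess, plots, provenance=prov)
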