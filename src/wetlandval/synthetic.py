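"""Synthetic inputs with known ground truth.

Two generators cover everything the assessment pipeline consumes:

* :func:`generate_landcover` builds spatially clustered categorical grids
  whose class areas hit prescribed hm^2 targets *exactly* (multi-source
  seeded region growth, areas from cell counts), standing in for
  classified satellite imagery;
* :func:`generate_price_field` builds a two-epoch land-price scenario —
  smooth baseline x epoch growth + a spatially correlated residual drawn
  from a stated variogram (circulant-embedding Gaussian random field) + a
  localized conical spillover kernel of known integrated value — so the
  true spillover value SEV_true is known and recovery can be scored.

:func:`make_panan_fixture` bundles the published Pan'an Lake study-area
structure into on-disk rasters plus legend/coefficients/expectations files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import box

from . import panan
from .esv import builtin_coefficients
from .geostat import PricePointSet, PriceSurface, VariogramModel
from .grid import GridSpec
from .landcover import LandCoverGrid, write_landcover_grid
from .spillover import PlannedPlotSet

logger = logging.getLogger("wetlandval.synthetic")

__all__ = [
    "ScenarioSpec",
    "SyntheticPriceData",
    "generate_landcover",
    "gaussian_random_field",
    "generate_price_field",
    "default_ring_plots",
    "integrate_kernel_over_plots",
    "make_panan_fixture",
]


# ---------------------------------------------------------------------------
# land cover


def _grow_regions(
    counts: dict[int, int], shape: tuple[int, int], rng: np.random.Generator,
    nodata: int,
) -> np.ndarray:
    """Assign exactly ``counts[code]`` cells per class by interleaved seeded
    region growth; unclaimed cells stay nodata."""
    nr, nc = shape
    n_cells = nr * nc
    labels = np.full(n_cells, nodata, dtype=np.int64)
    remaining = {code: cnt for code, cnt in counts.items() if cnt > 0}
    frontiers: dict[int, list[int]] = {code: [] for code in remaining}
    scan = rng.permutation(n_cells)
    scan_pos = 0

    def next_free() -> int:
        nonlocal scan_pos
        while labels[scan[scan_pos]] != nodata:
            scan_pos += 1
        return int(scan[scan_pos])

    def claim(code: int, cell: int) -> None:
        labels[cell] = code
        fr = frontiers[code]
        r, c = divmod(cell, nc)
        if r > 0 and labels[cell - nc] == nodata:
            fr.append(cell - nc)
        if r < nr - 1 and labels[cell + nc] == nodata:
            fr.append(cell + nc)
        if c > 0 and labels[cell - 1] == nodata:
            fr.append(cell - 1)
        if c < nc - 1 and labels[cell + 1] == nodata:
            fr.append(cell + 1)

    for code in remaining:
        claim(code, next_free())
        remaining[code] -= 1

    active = [code for code, left in remaining.items() if left > 0]
    batch = 64
    while active:
        for code in list(active):
            take = min(batch, remaining[code])
            fr = frontiers[code]
            done = 0
            while done < take:
                cell = -1
                while fr:
                    i = int(rng.integers(len(fr)))
                    cell = fr[i]
                    fr[i] = fr[-1]
                    fr.pop()
                    if labels[cell] == nodata:
                        break
                    cell = -1
                if cell < 0:
                    cell = next_free()  # region enclosed: respawn a new seed
                claim(code, cell)
                done += 1
            remaining[code] -= take
            if remaining[code] == 0:
                active.remove(code)
    return labels.reshape(shape)


def generate_landcover(
    targets: dict[str, float],
    cell_size: float = 10.0,
    seed: int = 0,
    legend: dict[int, str] | None = None,
    origin: tuple[float, float] | None = None,
    nodata: int = -9999,
) -> LandCoverGrid:
    """Spatially clustered categorical grid hitting hm^2 targets exactly.

    Each target must be an exact multiple of cell_size^2/10^4 hm^2 (at the
    10 m default, any 2-decimal hm^2 value qualifies). The grid is the
    smallest square holding all cells; leftover cells are nodata. The same
    seed reproduces the identical layout; a different seed permutes the
    layout but never the areas.
    """
    cell_hm2 = cell_size * cell_size / 10_000.0
    counts: dict[str, int] = {}
    for cls, area in targets.items():
        n = area / cell_hm2
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"class {cls!r}: target {area} hm^2 is not a whole number of "
                f"{cell_size} m cells ({cell_hm2} hm^2 each)"
            )
        counts[cls] = int(round(n))
    if legend is None:
        legend = {i + 1: cls for i, cls in enumerate(targets)}
    name_to_code = {v: k for k, v in legend.items()}
    missing = [cls for cls in targets if cls not in name_to_code]
    if missing:
        raise ValueError(f"legend lacks codes for classes: {missing}")
    total_cells = sum(counts.values())
    if total_cells == 0:
        raise ValueError("all class targets are zero")
    side = int(np.ceil(np.sqrt(total_cells)))
    rng = np.random.default_rng(seed)
    labels = _grow_regions(
        {name_to_code[cls]: cnt for cls, cnt in counts.items()},
        (side, side), rng, nodata,
    )
    if origin is None:
        origin = (0.0, side * cell_size)
    grid = GridSpec(origin_x=origin[0], origin_y=origin[1], cell_size=cell_size,
                    nrows=side, ncols=side)
    return LandCoverGrid(values=labels, grid=grid, legend=dict(legend), nodata=nodata)


# ---------------------------------------------------------------------------
# Gaussian random fields


def _next_pow2(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(n, 2))))


def gaussian_random_field(
    grid: GridSpec, model: VariogramModel, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean stationary field with the model's continuous covariance.

    Circulant embedding on a padded torus with FFT synthesis; slightly
    negative embedding eigenvalues (possible for the spherical family) are
    clipped to zero, a standard approximation that perturbs the target
    covariance negligibly at these padding sizes. The nugget is *not*
    synthesized into the field — it is sampling-scale noise, added to point
    observations instead.
    """
    m, n = grid.shape
    cs = grid.cell_size
    pad = int(np.ceil(model.range_ / cs)) + 1
    M, N = _next_pow2(2 * (m + pad)), _next_pow2(2 * (n + pad))
    dx = np.minimum(np.arange(N), N - np.arange(N)) * cs
    dy = np.minimum(np.arange(M), M - np.arange(M)) * cs
    h = np.hypot(dx[None, :], dy[:, None])
    cov = model.covariance(h)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    xi = rng.standard_normal((M, N)) + 1j * rng.standard_normal((M, N))
    f = np.fft.fft2(np.sqrt(lam) * xi) / np.sqrt(M * N)
    return np.ascontiguousarray(f.real[:m, :n])


# ---------------------------------------------------------------------------
# two-epoch price scenario


@dataclass
class ScenarioSpec:
    """Conditions of a synthetic two-epoch land-price study.

    Defaults emulate a county-scale mining-subsidence study area: a 6 km
    square analysed on the 15 m pricing grid, residential price level a few
    hundred yuan/m^2 with mild west-east drift, the regional price rise of
    a fast-urbanizing decade (g = 1.7681, i.e. +176.81%), a spherical
    residual variogram, a conical value-uplift kernel centred on the
    restored wetland, and the two epochs' survey sizes (47 and 61).
    """

    width: float = 6000.0
    height: float = 6000.0
    cell_size: float = 15.0
    family: str = "spherical"
    nugget: float = 50.0
    sill: float = 600.0
    range_: float = 1200.0
    baseline: float = 350.0
    gradient_frac: float = 0.05
    growth: float = 1.7681
    amplitude: float = 350.0
    radius: float = 900.0
    center: tuple[float, float] | None = None
    n_before: int = 47
    n_after: int = 61
    innovation_frac: float = 0.05
    #: share of samples drawn near the restoration site (land-price surveys
    #: concentrate where residential land actually exists, i.e. the
    #: urbanizing fringe around the wetland park); the rest are uniform.
    focus_frac: float = 0.4
    focus_radius: float = 1200.0
    clustered_sampling: bool = False
    n_clusters: int = 6
    seed: int = 0
    plots: PlannedPlotSet | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("kernel amplitude must be >= 0")
        if self.radius <= 0:
            raise ValueError("kernel radius must be positive")
        if self.n_before < 10 or self.n_after < 10:
            raise ValueError("sample sizes must be >= 10")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")
        if self.center is None:
            self.center = (self.width / 2.0, self.height / 2.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=0.0, origin_y=self.height, cell_size=self.cell_size,
            nrows=int(round(self.height / self.cell_size)),
            ncols=int(round(self.width / self.cell_size)),
        )

    @property
    def variogram(self) -> VariogramModel:
        return VariogramModel(self.family, nugget=self.nugget,
                              psill=self.sill - self.nugget, range_=self.range_)


@dataclass
class SyntheticPriceData:
    """Scenario realization: truth surfaces, samples, plots, known SEV."""

    truth_before: PriceSurface
    truth_after: PriceSurface
    points_before: PricePointSet
    points_after: PricePointSet
    plots: PlannedPlotSet
    sev_true: float
    spec: ScenarioSpec = field(repr=False, default=None)


def default_ring_plots(
    center: tuple[float, float],
    plot_side: float = 300.0,
    near_radius: float = 450.0,
    n_near: int = 12,
    far_radius: float = 2000.0,
    n_far: int = 0,
) -> PlannedPlotSet:
    """Square planned plots ringing the restoration site.

    The default is the planned-residential ring hugging the wetland park —
    the land that planning actually designates around a restored lake.
    ``n_far`` > 0 adds control plots well outside the influence zone
    (useful for mask-confinement checks; they receive no kernel value, so
    any spillover attributed to them is estimation noise).
    """
    geoms = []
    half = plot_side / 2.0
    for radius, count in ((near_radius, n_near), (far_radius, n_far)):
        for i in range(count):
            ang = 2.0 * np.pi * i / count
            cx = center[0] + radius * np.cos(ang)
            cy = center[1] + radius * np.sin(ang)
            geoms.append(box(cx - half, cy - half, cx + half, cy + half))
    return PlannedPlotSet.from_polygons(geoms)


def integrate_kernel_over_plots(
    amplitude: float,
    radius: float,
    center: tuple[float, float],
    plots: PlannedPlotSet,
    fine_cell: float = 2.5,
) -> float:
    """Zonal integral (yuan) of the cone A*max(0, 1 - d/R) over the plots,
    evaluated numerically on a fine subgrid of each plot."""
    total = 0.0
    for geom in plots.geometries:
        shapely.prepare(geom)
        xmin, ymin, xmax, ymax = geom.bounds
        xs = np.arange(xmin + fine_cell / 2, xmax, fine_cell)
        ys = np.arange(ymin + fine_cell / 2, ymax, fine_cell)
        X, Y = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel())
        d = np.hypot(X.ravel()[inside] - center[0], Y.ravel()[inside] - center[1])
        k = amplitude * np.clip(1.0 - d / radius, 0.0, None)
        total += float(k.sum() * fine_cell * fine_cell)
    return total


def _sample_locations(spec: ScenarioSpec, n: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    if not spec.clustered_sampling:
        n_focus = int(round(spec.focus_frac * n))
        xs, ys = [], []
        while len(xs) < n_focus:  # uniform on the focus disk, rejection-sampled
            cand_x = rng.uniform(spec.center[0] - spec.focus_radius,
                                 spec.center[0] + spec.focus_radius)
            cand_y = rng.uniform(spec.center[1] - spec.focus_radius,
                                 spec.center[1] + spec.focus_radius)
            if (np.hypot(cand_x - spec.center[0], cand_y - spec.center[1])
                    <= spec.focus_radius
                    and 0 <= cand_x <= spec.width and 0 <= cand_y <= spec.height):
                xs.append(cand_x)
                ys.append(cand_y)
        x = np.concatenate([np.asarray(xs), rng.uniform(0, spec.width, n - n_focus)])
        y = np.concatenate([np.asarray(ys), rng.uniform(0, spec.height, n - n_focus)])
        return x, y
    centers = np.column_stack([
        rng.uniform(0, spec.width, spec.n_clusters),
        rng.uniform(0, spec.height, spec.n_clusters),
    ])
    which = rng.integers(spec.n_clusters, size=n)
    sd = min(spec.width, spec.height) / 12.0
    x = np.clip(centers[which, 0] + rng.normal(0, sd, n), 0, spec.width)
    y = np.clip(centers[which, 1] + rng.normal(0, sd, n), 0, spec.height)
    return x, y


def _sample_surface(surface: np.ndarray, grid: GridSpec, x: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (grid.y_centers[::-1], grid.x_centers), surface[::-1, :],
        bounds_error=False, fill_value=None,
    )
    return interp(np.column_stack([y, x]))


def generate_price_field(spec: ScenarioSpec) -> SyntheticPriceData:
    """Realize the two-epoch price scenario.

    epoch-1 surface = baseline trend + correlated residual; epoch-2 =
    epoch-1 x (1 + g) + innovation field + spillover kernel. Point samples
    fall at seeded uniform-random (or optionally clustered) locations and
    carry nugget-consistent observation noise. SEV_true is the kernel's
    zonal integral over the plot set.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    X, Y = grid.cell_centers()
    base = spec.baseline * (
        1.0 + spec.gradient_frac * (X - spec.width / 2.0) / (spec.width / 2.0)
    )
    model = spec.variogram
    for attempt in range(20):
        res1 = gaussian_random_field(grid, model, rng)
        surf1 = base + res1
        if surf1.min() > 0:
            break
        logger.warning("epoch-1 surface non-positive (attempt %d); resampling", attempt)
    else:
        raise RuntimeError("could not realize a positive epoch-1 price surface")

    innov_model = VariogramModel(
        spec.family, nugget=0.0,
        psill=spec.innovation_frac * model.psill * (1.0 + spec.growth) ** 2,
        range_=spec.range_,
    )
    d_center = np.hypot(X - spec.center[0], Y - spec.center[1])
    kernel = spec.amplitude * np.clip(1.0 - d_center / spec.radius, 0.0, None)
    for attempt in range(20):
        innov = gaussian_random_field(grid, innov_model, rng) if innov_model.psill > 0 \
            else np.zeros(grid.shape)
        surf2 = (1.0 + spec.growth) * surf1 + innov + kernel
        if surf2.min() > 0:
            break
        logger.warning("epoch-2 surface non-positive (attempt %d); resampling", attempt)
    else:
        raise RuntimeError("could not realize a positive epoch-2 price surface")

    noise_sd = np.sqrt(spec.nugget)
    pts = []
    for label, n, surf in (("before", spec.n_before, surf1),
                           ("after", spec.n_after, surf2)):
        x, y = _sample_locations(spec, n, rng)
        vals = _sample_surface(surf, grid, x, y) + rng.normal(0.0, noise_sd, n)
        for _ in range(20):
            bad = vals <= 0
            if not bad.any():
                break
            logger.warning("%s epoch: redrawing %d non-positive sampled price(s)",
                           label, int(bad.sum()))
            vals[bad] = _sample_surface(surf, grid, x[bad], y[bad]) \
                + rng.normal(0.0, noise_sd, int(bad.sum()))
        else:
            raise RuntimeError("could not draw positive sample prices")
        pts.append(PricePointSet(x=x, y=y, price=vals, epoch=label))

    plots = spec.plots if spec.plots is not None else default_ring_plots(spec.center)
    sev_true = (0.0 if spec.amplitude == 0 else integrate_kernel_over_plots(
        spec.amplitude, spec.radius, spec.center, plots))
    zeros = np.zeros(grid.shape)
    return SyntheticPriceData(
        truth_before=PriceSurface(values=surf1, variance=zeros.copy(), grid=grid,
                                  epoch="before"),
        truth_after=PriceSurface(values=surf2, variance=zeros.copy(), grid=grid,
                                 epoch="after"),
        points_before=pts[0],
        points_after=pts[1],
        plots=plots,
        sev_true=sev_true,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Pan'an fixture


def make_panan_fixture(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the Pan'an Lake study-area fixture bundle.

    Both epoch land-cover rasters (10 m cells so every published 2-decimal
    hm^2 area is an exact cell count), the legend, the coefficient table,
    and an expectations JSON carrying the published per-class values used
    in validation. Re-running with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, areas, sub_seed in (("2008", panan.AREAS_2008, seed),
                                   ("2017", panan.AREAS_2017, seed + 1)):
        lc = generate_landcover(areas, cell_size=10.0, seed=sub_seed,
                                legend=panan.LEGEND)
        p = out / f"landcover_{label}.asc"
        write_landcover_grid(p, lc)
        paths[f"landcover_{label}"] = p
    legend_path = out / "legend.json"
    legend_path.write_text(json.dumps(panan.LEGEND, indent=2, sort_keys=True))
    paths["legend"] = legend_path
    coef_path = out / "coefficients.csv"
    builtin_coefficients().to_frame().to_csv(coef_path, index=False)
    paths["coefficients"] = coef_path
    expectations = {
        "areas_2008_hm2": panan.AREAS_2008,
        "areas_2017_hm2": panan.AREAS_2017,
        "total_area_hm2": panan.TOTAL_AREA_HM2,
        "esv_2008_wanyuan": panan.ESV_2008,
        "esv_2017_wanyuan": panan.ESV_2017,
        "esv_total_2008_wanyuan": panan.ESV_TOTAL_2008,
        "esv_total_2017_wanyuan": panan.ESV_TOTAL_2017,
        "consistent_2017_classes": list(panan.CONSISTENT_2017_CLASSES),
        "ess_2008_wanyuan_per_hm2": panan.ESS_2008,
        "ess_2017_wanyuan_per_hm2": panan.ESS_2017,
        "ess_conversion_quantity": panan.ESS_CONVERSION_QUANTITY,
        "ess_conversion_percent": panan.ESS_CONVERSION_PERCENT,
        "study_years": panan.STUDY_YEARS,
    }
    exp_path = out / "expectations.json"
    exp_path.write_text(json.dumps(expectations, indent=2, sort_keys=True))
    paths["expectations"] = exp_path
    return paths
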