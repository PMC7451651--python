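"""Geostatistics for land-price point samples.

Sample screening (Shapiro-Wilk normality, Moran's I with a permutation
test), empirical semivariography, weighted least-squares fitting of the
classical isotropic variogram families, leave-one-out cross-validated model
selection, and ordinary kriging onto a regular grid.

Conventions
-----------
* gamma(0) = 0 exactly; the nugget is the limit of gamma from above, so a
  nugget-0 model is an exact interpolator at the sample sites.
* ``range_`` is the practical range for all families: the spherical model
  reaches its sill there, the exponential and Gaussian models reach 95% of
  it (the 1 - exp(-3h/a) parameterization).
* Ordinary-kriging weights are constrained to sum to one (unbiasedness);
  the kriging variance is sum(lambda_i * gamma_i) + mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .grid import GridSpec

logger = logging.getLogger("wetlandval.geostat")

__all__ = [
    "PricePointSet",
    "NormalityResult",
    "MoransResult",
    "EmpiricalVariogram",
    "VariogramModel",
    "PriceSurface",
    "normality_test",
    "morans_i",
    "empirical_semivariogram",
    "fit_variogram",
    "loo_cross_validate",
    "ordinary_kriging",
    "DEFAULT_FAMILIES",
]

DEFAULT_FAMILIES = ("spherical", "exponential", "gaussian")
_FAMILY_ORDER = {"spherical": 0, "exponential": 1, "gaussian": 2, "pure_nugget": 3}


# ---------------------------------------------------------------------------
# point samples


@dataclass
class PricePointSet:
    """Epoch-tagged land-price samples: (x, y) in metres, price in yuan/m^2.

    Duplicate coordinates are averaged on construction (a kriging system
    with coincident points is singular); the averaging is logged.
    """

    x: np.ndarray
    y: np.ndarray
    price: np.ndarray
    epoch: str = ""
    landuse: str = "residential"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.price = np.asarray(self.price, dtype=np.float64)
        if not (self.x.shape == self.y.shape == self.price.shape) or self.x.ndim != 1:
            raise ValueError("x, y, price must be equal-length 1-D arrays")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if not np.isfinite(self.price).all() or (self.price <= 0).any():
            raise ValueError("prices must be finite and positive")
        coords = np.column_stack([self.x, self.y])
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        if uniq.shape[0] < coords.shape[0]:
            n_dup = coords.shape[0] - uniq.shape[0]
            logger.warning("averaging %d duplicate-coordinate sample(s)", n_dup)
            sums = np.zeros(uniq.shape[0])
            counts = np.zeros(uniq.shape[0])
            np.add.at(sums, inverse, self.price)
            np.add.at(counts, inverse, 1.0)
            self.x, self.y = uniq[:, 0], uniq[:, 1]
            self.price = sums / counts

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch: str | None = None,
                   landuse: str | None = None) -> "PricePointSet":
        sub = df
        if epoch is not None and "epoch" in df.columns:
            sub = sub[sub["epoch"].astype(str) == str(epoch)]
        return cls(
            x=sub["x"].to_numpy(),
            y=sub["y"].to_numpy(),
            price=sub["price_yuan_m2"].to_numpy(),
            epoch=str(epoch) if epoch is not None else str(sub.get("epoch", pd.Series([""])).iloc[0]),
            landuse=landuse or (str(sub["landuse"].iloc[0]) if "landuse" in sub.columns else "residential"),
        )

    @classmethod
    def from_csv(cls, path: str | Path, epoch: str | None = None) -> "PricePointSet":
        return cls.from_frame(pd.read_csv(path), epoch=epoch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x, "y": self.y, "price_yuan_m2": self.price,
            "epoch": self.epoch, "landuse": self.landuse,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# screening


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool
    recommendation: str | None = None


def normality_test(prices: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk test of the price distribution.

    Failure does not auto-transform the data; a log-transform
    recommendation is attached instead, since back-transform bias is the
    analyst's call.
    """
    prices = np.asarray(prices, dtype=np.float64)
    if prices.size < 3:
        raise ValueError(f"need at least 3 prices, got {prices.size}")
    if np.ptp(prices) == 0:
        raise ValueError("constant prices: normality statistic undefined")
    stat, p = stats.shapiro(prices)
    passed = bool(p >= alpha)
    rec = None
    if not passed:
        rec = ("price distribution departs from normality; consider a log "
               "transform before variography")
    return NormalityResult(statistic=float(stat), p_value=float(p), passed=passed,
                           recommendation=rec)


@dataclass(frozen=True)
class MoransResult:
    I: float
    expected_I: float
    p_value: float
    permutations: int
    significant: bool


def morans_i(
    points: PricePointSet,
    power: float = 1.0,
    max_distance: float | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> MoransResult:
    """Global Moran's I with row-standardized inverse-distance weights.

    The p-value is a one-sided (greater) pseudo p from ``permutations``
    seeded random relabellings — the spatial-clustering alternative that
    screening for kriging suitability asks about.
    """
    n = points.n
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    z = points.price - points.price.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero-variance prices: Moran's I undefined")
    D = squareform(pdist(points.coords))
    with np.errstate(divide="ignore"):
        W = 1.0 / np.power(D, power)
    np.fill_diagonal(W, 0.0)
    if max_distance is not None:
        W[D > max_distance] = 0.0
    row_sums = W.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("some points have no neighbors under the weighting scheme")
    W = W / row_sums[:, None]

    def moran(v: np.ndarray) -> float:
        # row-standardized: S0 = n, so I = v' W v / v' v
        return float(v @ (W @ v) / (v @ v))

    I_obs = moran(z)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(permutations):
        if moran(rng.permutation(z)) >= I_obs:
            count_ge += 1
    p = (1 + count_ge) / (permutations + 1)
    return MoransResult(I=I_obs, expected_I=-1.0 / (n - 1), p_value=p,
                        permutations=permutations, significant=bool(p <= 0.05))


# ---------------------------------------------------------------------------
# variography


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram estimate."""

    lags: np.ndarray          # mean pair distance per retained bin (m)
    semivariance: np.ndarray  # gamma-hat per bin
    counts: np.ndarray        # pair count per bin
    max_lag: float
    n_bins: int

    def __post_init__(self) -> None:
        if (self.semivariance < 0).any():
            raise ValueError("semivariances must be non-negative")
        if (self.counts < 1).any():
            raise ValueError("retained bins must contain at least one pair")
        if not np.all(np.diff(self.lags) > 0):
            raise ValueError("lag bins must be sorted ascending")


def empirical_semivariogram(
    points: PricePointSet,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """gamma-hat(h_k) = (1/2N_k) sum over pairs in bin k of (z_i - z_j)^2.

    Default ``max_lag`` is half the maximum pairwise distance; bins with no
    pairs are dropped. Bin abscissae are the mean pair distance in the bin.
    """
    if points.n < 3:
        raise ValueError(f"need at least 3 points, got {points.n}")
    d = pdist(points.coords)
    if d.max() == 0:
        raise ValueError("all points coincident")
    if max_lag is None:
        max_lag = d.max() / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = pdist(points.price[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= max_lag)
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    lags, gammas, counts = [], [], []
    for k in range(n_bins):
        m = which == k
        nk = int(m.sum())
        if nk == 0:
            continue
        lags.append(float(d[m].mean()))
        gammas.append(float(sq[m].mean() / 2.0))
        counts.append(nk)
    return EmpiricalVariogram(
        lags=np.asarray(lags), semivariance=np.asarray(gammas),
        counts=np.asarray(counts, dtype=np.int64), max_lag=float(max_lag),
        n_bins=n_bins,
    )


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram: gamma(h) = nugget + psill * g(h / range)."""

    family: str
    nugget: float
    psill: float
    range_: float
    wsse: float | None = None
    loo_rmse: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_ORDER:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial sill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    @property
    def n_params(self) -> int:
        return 1 if self.family == "pure_nugget" else 3

    def gamma(self, h: np.ndarray | float) -> np.ndarray:
        """Semivariance at lag h; gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=np.float64)
        hr = h / self.range_
        if self.family == "spherical":
            g = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * hr)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-3.0 * hr**2)
        else:  # pure nugget
            g = np.zeros_like(h)
        out = self.nugget + self.psill * g
        return np.where(h == 0.0, 0.0, out)

    def covariance(self, h: np.ndarray | float) -> np.ndarray:
        """Stationary covariance sill - gamma(h) of the *continuous* part.

        The nugget is microscale/measurement variance and is excluded, so
        C(0) = psill.
        """
        h = np.asarray(h, dtype=np.float64)
        return self.psill - np.where(h == 0.0, 0.0, self.gamma(h) - self.nugget)


def _fit_one_family(
    family: str, lags: np.ndarray, gam: np.ndarray, w: np.ndarray, max_lag: float
) -> VariogramModel:
    if family == "pure_nugget":
        nug = float(np.sum(w * gam) / np.sum(w))
        wsse = float(np.sum(w * (gam - nug) ** 2))
        return VariogramModel("pure_nugget", nugget=nug, psill=0.0, range_=max_lag,
                              wsse=wsse)

    sw = np.sqrt(w)
    gmax = float(gam.max())
    psill0 = max(gmax - gam.min(), 1e-12 + 0.1 * gmax)
    nug0 = max(float(gam.min()), 0.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        m = VariogramModel(family, nugget=theta[0], psill=theta[1], range_=theta[2])
        return sw * (m.gamma(lags) - gam)

    lo = [0.0, 0.0, 1e-9]
    hi = [np.inf, np.inf, 2.0 * max_lag]
    best = None
    # multi-start over the range axis: WLS variogram objectives are multimodal
    for a0 in np.geomspace(max_lag / 20.0, 2.0 * max_lag, 8):
        try:
            sol = least_squares(resid, x0=[nug0, psill0, a0], bounds=(lo, hi))
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"variogram fit failed for family {family!r}")
    nug, ps, rng_ = (float(v) for v in best.x)
    wsse = float(np.sum(best.fun**2))
    return VariogramModel(family, nugget=nug, psill=ps, range_=max(rng_, 1e-9), wsse=wsse)


def fit_variogram(
    emp: EmpiricalVariogram,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> list[VariogramModel]:
    """Pair-count-weighted least-squares fit of each requested family.

    Multi-start bounded optimization over (nugget, partial sill, range);
    returns one fitted model per family in canonical family order.
    """
    if emp.lags.size < 3:
        raise ValueError(f"need at least 3 variogram bins, got {emp.lags.size}")
    w = emp.counts.astype(np.float64)
    fams = sorted(set(families), key=_FAMILY_ORDER.__getitem__)
    return [_fit_one_family(f, emp.lags, emp.semivariance, w, emp.max_lag) for f in fams]


# ---------------------------------------------------------------------------
# kriging


@dataclass
class PriceSurface:
    """Kriged price grid (yuan/m^2) with per-cell kriging variance."""

    values: np.ndarray
    variance: np.ndarray
    grid: GridSpec
    epoch: str = ""
    mask: np.ndarray | None = None  # True where the prediction is valid

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("surface shape does not match grid geometry")
        if (self.variance[self.mask] < 0).any():
            raise ValueError("kriging variance must be non-negative")


def _sample_gamma_matrix(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Dense gamma(d_ij) between all samples (zero diagonal)."""
    return model.gamma(squareform(pdist(coords)))


def _solve_ok_batch(
    G: np.ndarray,           # (n, n) sample-to-sample gamma matrix
    idx: np.ndarray,         # (c, k) neighbor indices into the samples
    nb_values: np.ndarray,   # (c, k)
    t_dists: np.ndarray,     # (c, k) neighbor-to-target distances
    model: VariogramModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Solve a batch of ordinary-kriging systems.

    Returns (predictions, variances, weight_sums, ok_flags); cells whose
    system is singular come back flagged False.
    """
    c, k = idx.shape
    A = np.empty((c, k + 1, k + 1))
    A[:, :k, :k] = G[idx[:, :, None], idx[:, None, :]]
    A[:, k, :k] = 1.0
    A[:, :k, k] = 1.0
    A[:, k, k] = 0.0
    b = np.empty((c, k + 1))
    b[:, :k] = model.gamma(t_dists)
    b[:, k] = 1.0
    ok = np.ones(c, dtype=bool)
    try:
        sol = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        sol = np.full((c, k + 1), np.nan)
        for i in range(c):
            try:
                sol[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                ok[i] = False
    lam = sol[:, :k]
    mu = sol[:, k]
    pred = (lam * nb_values).sum(axis=1)
    var = (lam * b[:, :k]).sum(axis=1) + mu
    bad = ~np.isfinite(pred)
    ok &= ~bad
    return pred, np.maximum(var, 0.0), lam.sum(axis=1), ok


def ordinary_kriging(
    points: PricePointSet,
    model: VariogramModel,
    grid_spec: GridSpec,
    max_neighbors: int = 32,
    chunk: int = 4096,
    epoch: str | None = None,
) -> PriceSurface:
    """Krige point samples onto a regular grid (cell-center prediction).

    Each cell is predicted from its ``max_neighbors`` nearest samples by
    solving the ordinary-kriging system with a Lagrange multiplier; the
    weights sum to one by construction and predictions at sample
    coordinates reproduce the observations when the nugget is zero.
    Singular cells (none, after duplicate-averaging at ingest) are masked
    with a warning.
    """
    if points.n < 2:
        raise ValueError(f"need at least 2 points to krige, got {points.n}")
    coords = points.coords
    values = points.price
    k = min(max_neighbors, points.n)
    tree = cKDTree(coords)
    X, Y = grid_spec.cell_centers()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    m = targets.shape[0]
    G = _sample_gamma_matrix(coords, model)
    pred = np.empty(m)
    var = np.empty(m)
    valid = np.ones(m, dtype=bool)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        t_dists, idx = tree.query(targets[sl], k=k)
        if k == 1:
            t_dists, idx = t_dists[:, None], idx[:, None]
        p, v, wsum, ok = _solve_ok_batch(G, idx, values[idx], t_dists, model)
        pred[sl], var[sl] = p, v
        valid[sl] = ok
        if ok.any() and np.abs(wsum[ok] - 1.0).max() > 1e-6:
            logger.warning("kriging weight sums deviate from 1 by up to %.2e",
                           np.abs(wsum[ok] - 1.0).max())
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d grid cell(s) had singular kriging systems and were masked",
                       n_bad)
        pred[~valid] = np.nan
        var[~valid] = np.nan
    return PriceSurface(
        values=pred.reshape(grid_spec.shape),
        variance=var.reshape(grid_spec.shape),
        grid=grid_spec,
        epoch=epoch if epoch is not None else points.epoch,
        mask=valid.reshape(grid_spec.shape),
    )


def loo_cross_validate(
    points: PricePointSet,
    candidates: list[VariogramModel],
    max_neighbors: int = 32,
    max_skip_frac: float = 0.1,
) -> list[VariogramModel]:
    """Rank candidate variograms by leave-one-out kriging RMSE.

    Each sample is predicted from its nearest neighbors among the others;
    ties are broken by fewer parameters, then by the canonical family order
    (spherical < exponential < gaussian < pure nugget). Points with
    singular systems are skipped with a warning; more than
    ``max_skip_frac`` skipped is an error.
    """
    n = points.n
    if n < 10:
        raise ValueError(f"need at least 10 points for cross-validation, got {n}")
    coords, values = points.coords, points.price
    k = min(max_neighbors, n - 1)
    tree = cKDTree(coords)
    dists, idx = tree.query(coords, k=k + 1)
    # drop each point from its own neighborhood
    nb_idx = np.where(idx[:, :1] == np.arange(n)[:, None], idx[:, 1:], idx[:, :-1])
    nb_d = np.where(idx[:, :1] == np.arange(n)[:, None], dists[:, 1:], dists[:, :-1])
    ranked: list[VariogramModel] = []
    for cand in candidates:
        G = _sample_gamma_matrix(coords, cand)
        pred, _, _, ok = _solve_ok_batch(G, nb_idx, values[nb_idx], nb_d, cand)
        n_skip = int((~ok).sum())
        if n_skip:
            logger.warning("LOO: skipped %d point(s) with singular systems", n_skip)
        if n_skip > max_skip_frac * n:
            raise RuntimeError(
                f"{n_skip}/{n} leave-one-out systems singular; data unsuitable"
            )
        rmse = float(np.sqrt(np.mean((pred[ok] - values[ok]) ** 2)))
        ranked.append(replace(cand, loo_rmse=rmse))
    ranked.sort(key=lambda m: (m.loo_rmse, m.n_params, _FAMILY_ORDER[m.family]))
    return ranked
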